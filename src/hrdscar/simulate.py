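"""Synthetic fixtures: genomes, planted variants, gene events, cohorts.

Everything the pipeline consumes can be generated here deterministically
from a seed, so the full stack is exercisable without any external data:

* random reference genomes (FASTA-writable);
* small-variant and SV sets *planted* so that context extraction recovers a
  prescribed count per context key, with a planting log for round-trip
  checks;
* copy-number profiles and annotated variants realising a chosen biallelic
  gene event (deep deletion, LOH + variant, variant pair, benign-only);
* labelled three-class cohorts whose feature structure mirrors the HRD
  biology: both deficient classes are dominated by microhomology deletions
  with >=2 bp homology, and the BRCA1-type class additionally carries an
  excess of 1-100 kb tandem duplications.

Planting uses rejection sampling: a candidate placement is accepted only
when the context classifier assigns exactly the intended key, so flanking
sequence can never smuggle in unintended homology.  Candidate acceptance
rates are lowest for long exact-homology targets (about ``2 * 4**-k`` for
k bases of microhomology); the retry bound of 5000 candidates per variant
makes failures on >=10 kb genomes vanishingly rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .biallelic import (
    AnnotatedVariant,
    CopyNumberSegment,
    GeneRegion,
)
from .config import Thresholds, DEFAULT_THRESHOLDS
from .contexts import (
    ALL_CONTEXTS,
    INDEL_CONTEXTS,
    InMemoryGenome,
    MutationContextProfile,
    SNV_CONTEXTS,
    SV_CONTEXTS,
    SV_LENGTH_BINS,
    SmallVariant,
    StructuralVariant,
    classify_indel_context,
    classify_snv_context,
    classify_sv_context,
    reverse_complement,
)
from .features import build_scar_features

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Fixture genomes
# ---------------------------------------------------------------------------


def make_fixture_genome(
    length: int,
    gc: float = 0.41,
    seed: int = 0,
    contig: str = "chr1",
) -> InMemoryGenome:
    """A deterministic random genome with the requested GC content."""
    if length < 1000:
        raise ValueError("fixture genomes must be >= 1 kb")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return InMemoryGenome({contig: seq})


def write_genome_fasta(genome: InMemoryGenome, path) -> str:
    """Write the genome as FASTA and build a pyfaidx index next to it."""
    import pyfaidx

    path = str(path)
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pyfaidx.Faidx(path)  # writes <path>.fai
    return path


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


@dataclass
class PlantingLog:
    """What was planted where; the ground truth for round-trip checks."""

    records: list = field(default_factory=list)  # (intended_key, variant)

    def intended_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for key, _ in self.records:
            counts[key] = counts.get(key, 0) + 1
        return counts


_MAX_TRIES = 5000


def _plant_snv(
    key: str, genome: InMemoryGenome, contig: str, rng, used: set
) -> SmallVariant:
    f5, ref, _, alt, f3 = key[0], key[2], key[3], key[4], key[6]
    want_fwd = f5 + ref + f3
    want_rev = reverse_complement(want_fwd)
    seq = genome.contigs[contig]
    for _ in range(_MAX_TRIES):
        p = int(rng.integers(1, len(seq) - 1))  # 0-based
        if any(abs(p - u) < 2 for u in used):
            continue
        tri = seq[p - 1 : p + 2]
        if tri == want_fwd:
            v = SmallVariant(contig, p + 1, ref, alt)
        elif tri == want_rev:
            v = SmallVariant(
                contig, p + 1, reverse_complement(ref), reverse_complement(alt)
            )
        else:
            continue
        if classify_snv_context(v, genome) == key:
            used.add(p)
            return v
    raise ValueError(f"could not place an SNV for {key} (genome too short?)")


def _indel_lengths_for_key(key: str) -> list[int]:
    """Candidate indel lengths compatible with a context key."""
    kind_type, bin_kind, b = key.rsplit(".", 2)
    b = int(b)
    if bin_kind == "len":
        return [b] if b < 5 else [5, 6, 7]
    # microhomology bins: the homology length must be shorter than the
    # indel (else the placement is a full-copy repeat), and rule (iii)
    # requires length >= 3 when only 1 bp matches
    if b == 1:
        return [3, 4, 5]
    return [b + 1, b + 2, b + 3]


def _plant_indel(
    key: str, genome: InMemoryGenome, contig: str, rng, used: set
) -> SmallVariant:
    seq = genome.contigs[contig]
    lengths = _indel_lengths_for_key(key)
    is_del = key.startswith("del")
    for _ in range(_MAX_TRIES):
        L = int(rng.choice(lengths))
        p = int(rng.integers(2 * L + 1, len(seq) - 2 * L - 1))
        if any(abs(p - u) < 4 * L + 10 for u in used):
            continue
        if is_del:
            ref = seq[p - 1 : p + L]
            alt = seq[p - 1]
        else:
            ins = "".join(rng.choice(_BASES, size=L))
            ref = seq[p - 1]
            alt = ref + ins
        v = SmallVariant(contig, p, ref, alt)
        try:
            got = classify_indel_context(v, genome)
        except Exception:
            continue
        if got == key:
            used.add(p)
            return v
    raise ValueError(f"could not place an indel for {key} (genome too short?)")


def _plant_sv(key: str, rng) -> StructuralVariant:
    if key == "TRA":
        return StructuralVariant("TRA")
    sv_type, rest = key.split("_", 1)
    for lo, hi, label in SV_LENGTH_BINS:
        if rest == label:
            upper = min(hi, 5e7)
            length = int(rng.integers(int(lo), int(upper)))
            return StructuralVariant(sv_type, length)
    raise KeyError(key)


def plant_variants(
    genome: InMemoryGenome,
    spec: Mapping[str, int],
    seed: int = 0,
) -> tuple[list[SmallVariant], list[StructuralVariant], PlantingLog]:
    """Engineer variants so ``extract_profile`` returns exactly ``spec``.

    ``spec`` maps context keys (any of the 142) to desired counts.  Raises
    ``ValueError`` when the genome cannot host the requested placements.
    """
    unknown = set(spec) - set(ALL_CONTEXTS)
    if unknown:
        raise KeyError(f"unknown context keys: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    contig = next(iter(genome.contigs))
    used: set[int] = set()
    log = PlantingLog()
    small: list[SmallVariant] = []
    svs: list[StructuralVariant] = []
    for key in ALL_CONTEXTS:  # fixed iteration order for determinism
        for _ in range(int(spec.get(key, 0))):
            if key in SNV_CONTEXTS:
                v = _plant_snv(key, genome, contig, rng, used)
                small.append(v)
            elif key in INDEL_CONTEXTS:
                v = _plant_indel(key, genome, contig, rng, used)
                small.append(v)
            else:
                v = _plant_sv(key, rng)
                svs.append(v)
            log.records.append((key, v))
    return small, svs, log


# ---------------------------------------------------------------------------
# Gene-event planting
# ---------------------------------------------------------------------------


@dataclass
class PlantedGeneEvent:
    segments: list[CopyNumberSegment]
    variants: list[AnnotatedVariant]
    expected_event: str
    expected_bp: int


def plant_gene_events(
    gene: GeneRegion,
    event: str,
    seed: int = 0,
    chrom_length: int = 10_000_000,
) -> PlantedGeneEvent:
    """Copy-number segments + annotated variants realising one biallelic
    event type in ``gene``: ``deep_deletion``, ``loh_germline_pathogenic``,
    ``loh_somatic_vus``, ``variant_pair`` or ``benign_only``."""
    rng = np.random.default_rng(seed)
    pos = int(rng.integers(gene.start + 1, gene.end))

    def seg(total, minor):
        return [
            CopyNumberSegment(gene.chrom, 0, gene.start, 2.0, 1.0),
            CopyNumberSegment(gene.chrom, gene.start, gene.end, total, minor),
            CopyNumberSegment(gene.chrom, gene.end, chrom_length, 2.0, 1.0),
        ]

    def var(origin, clinvar=None, effect=None):
        return AnnotatedVariant(
            SmallVariant(gene.chrom, pos, "A", "T", origin=origin),
            clinvar_class=clinvar,
            effect_class=effect,
        )

    if event == "deep_deletion":
        return PlantedGeneEvent(seg(0.1, 0.0), [], "deep_deletion", 10)
    if event == "loh_germline_pathogenic":
        # copy-neutral LOH + pathogenic germline hit: BP 5 + 5
        return PlantedGeneEvent(
            seg(2.0, 0.0), [var("germline", clinvar="pathogenic")], "loh", 10
        )
    if event == "loh_somatic_vus":
        return PlantedGeneEvent(
            seg(1.0, 0.0), [var("somatic", effect="missense")], "loh", 8
        )
    if event == "variant_pair":
        v1 = var("germline", clinvar="pathogenic")
        v2 = AnnotatedVariant(
            SmallVariant(gene.chrom, pos + 5, "C", "G", origin="somatic"),
            effect_class="frameshift_oof",
        )
        return PlantedGeneEvent(seg(2.0, 1.0), [v1, v2], "variant_pair", 10)
    if event == "benign_only":
        return PlantedGeneEvent(
            seg(2.0, 1.0), [var("germline", clinvar="benign")], "none", 1
        )
    raise ValueError(f"unknown event type {event!r}")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortEffects:
    """Class-level generative parameters of the synthetic cohort.

    Loads are Poisson means per sample; fractions are expected relative
    contributions within a mutation class; ``concentration`` controls the
    per-sample Dirichlet spread around the class means (higher = tighter).
    Defaults emulate whole-genome somatic loads of a metastatic pan-cancer
    cohort at the order of magnitude the classifier sees in practice.
    """

    snv_load: float = 5_000.0
    indel_load_none: float = 300.0
    indel_load_hrd: float = 600.0
    sv_load_none: float = 100.0
    sv_load_b2: float = 150.0
    sv_load_b1: float = 250.0
    del_mh_frac_none: float = 0.08
    del_mh_frac_hrd: float = 0.45
    bimh2_frac_none: float = 0.40
    bimh2_frac_hrd: float = 0.85
    dup_small_frac_none: float = 0.05
    dup_small_frac_b1: float = 0.40
    concentration: float = 150.0

    @classmethod
    def null(cls) -> "CohortEffects":
        """No class differences at all (negative-control cohort)."""
        return cls(
            indel_load_hrd=300.0,
            sv_load_b2=100.0,
            sv_load_b1=100.0,
            del_mh_frac_hrd=0.08,
            bimh2_frac_hrd=0.40,
            dup_small_frac_b1=0.05,
        )


def _indel_probs(del_mh_frac: float, bimh2_frac: float) -> np.ndarray:
    """Expected proportions over the 30 indel context keys.

    ``bimh2_frac`` is the mass of microhomology deletions with >= 2 bp of
    flanking identity; in HRD samples the MMEJ footprint concentrates there.
    """
    p7 = {
        "del.mh": del_mh_frac,
        "ins.mh": 0.02,
    }
    rest = 1.0 - del_mh_frac - 0.02
    p7.update(
        {
            "del.rep": 0.30 * rest,
            "ins.rep": 0.25 * rest,
            "del.none": 0.25 * rest,
            "ins.none": 0.20 * rest,
        }
    )
    tail = np.array([0.47, 0.29, 0.14, 0.10])  # shape across bimh 2..>=5
    bimh_split = np.concatenate(
        [[1.0 - bimh2_frac], bimh2_frac * tail / tail.sum()]
    )
    len_split = np.array([0.50, 0.25, 0.13, 0.08, 0.04])
    out = np.zeros(len(INDEL_CONTEXTS))
    for i, key in enumerate(INDEL_CONTEXTS):
        t, _, b = key.rsplit(".", 2)
        split = bimh_split if t.endswith(".mh") else len_split
        out[i] = p7[t] * split[int(b) - 1]
    return out / out.sum()


def _sv_probs(dup_small_frac: float) -> np.ndarray:
    """Expected proportions over the 16 SV context keys.

    ``dup_small_frac`` is the expected fraction of SVs falling in the two
    1-100 kb duplication bins — the tandem-duplicator footprint that marks
    BRCA1-type HRD; large duplications stay at a small constant share.
    """
    dup_large = 0.05
    rest = 1.0 - dup_small_frac - dup_large
    type_mass = {"DEL": 0.45 * rest, "INV": 0.33 * rest, "TRA": 0.22 * rest}
    len_bins = np.array([0.35, 0.30, 0.20, 0.10, 0.05])
    dup_bins = np.concatenate(
        [
            dup_small_frac * np.array([0.60, 0.40]),
            dup_large * np.array([0.50, 0.30, 0.20]),
        ]
    )
    out = np.zeros(len(SV_CONTEXTS))
    for i, key in enumerate(SV_CONTEXTS):
        if key == "TRA":
            out[i] = type_mass["TRA"]
            continue
        t, rest_key = key.split("_", 1)
        j = next(
            k for k, (_, _, lab) in enumerate(SV_LENGTH_BINS) if lab == rest_key
        )
        out[i] = dup_bins[j] if t == "DUP" else type_mass[t] * len_bins[j]
    return out / out.sum()


def _class_params(label: str, effects: CohortEffects):
    hrd_like = label in ("BRCA1", "BRCA2")
    indel_load = effects.indel_load_hrd if hrd_like else effects.indel_load_none
    sv_load = {
        "BRCA1": effects.sv_load_b1,
        "BRCA2": effects.sv_load_b2,
        "none": effects.sv_load_none,
    }[label]
    del_mh = effects.del_mh_frac_hrd if hrd_like else effects.del_mh_frac_none
    bimh2 = effects.bimh2_frac_hrd if hrd_like else effects.bimh2_frac_none
    dup_small = (
        effects.dup_small_frac_b1 if label == "BRCA1" else effects.dup_small_frac_none
    )
    snv_p = np.full(len(SNV_CONTEXTS), 1.0 / len(SNV_CONTEXTS))
    return (
        (effects.snv_load, snv_p),
        (indel_load, _indel_probs(del_mh, bimh2)),
        (sv_load, _sv_probs(dup_small)),
    )


def _draw_block(rng, load: float, probs: np.ndarray, conc: float) -> np.ndarray:
    n = rng.poisson(load)
    if n == 0:
        return np.zeros(len(probs), dtype=int)
    alpha = np.clip(probs * conc, 1e-6, None)
    p = rng.dirichlet(alpha)
    return rng.multinomial(n, p)


def simulate_cohort(
    n_b1: int = 50,
    n_b2: int = 50,
    n_none: int = 200,
    effects: CohortEffects | None = None,
    seed: int = 0,
    return_profiles: bool = False,
):
    """Simulate a labelled three-class cohort of context profiles.

    Returns ``(features, labels)`` — a samples x 29 feature table and the
    class labels — or ``(features, labels, profiles)`` with the underlying
    :class:`MutationContextProfile` objects when ``return_profiles``.
    """
    if min(n_b1, n_b2, n_none) < 0:
        raise ValueError("sample counts must be non-negative")
    effects = effects or CohortEffects()
    rng = np.random.default_rng(seed)
    profiles: dict[str, MutationContextProfile] = {}
    labels: dict[str, str] = {}
    specs = [("BRCA1", n_b1), ("BRCA2", n_b2), ("none", n_none)]
    for label, n in specs:
        params = _class_params(label, effects)
        for i in range(n):
            name = f"{label}_{i:03d}"
            blocks = [
                _draw_block(rng, load, probs, effects.concentration)
                for load, probs in params
            ]
            counts = dict(
                zip(ALL_CONTEXTS, np.concatenate(blocks).astype(int))
            )
            profiles[name] = MutationContextProfile(counts=counts)
            labels[name] = label
    features = pd.DataFrame(
        {name: build_scar_features(p) for name, p in profiles.items()}
    ).T
    label_series = pd.Series(labels).reindex(features.index)
    if return_profiles:
        return features, label_series, profiles
    return features, label_series
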