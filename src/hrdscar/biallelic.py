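"""Per-gene biallelic inactivation scoring.

Each allele-level event carries a pathogenicity score (P-score, 0-5):
loss-of-heterozygosity counts as 5; annotated small variants score 1-5 from
their clinical-significance class (benign=1 ... pathogenic=5), falling back
to the predicted effect class when no clinical annotation exists
(out-of-frame frameshift=5; nonsense/splice=4; missense/essential-splice/
in-frame=3; other=2); high-frequency germline variants are pre-marked
benign (0).  The two highest-impact allelic events are summed into a
biallelic pathogenicity score (BP-score, max 10); a complete somatic
copy-number loss (deep deletion, minimum total copy number < 0.3) scores 10
outright.  A gene is considered biallelically inactivated ("deficient")
when its BP-score reaches 10.

Two rule sets consume these scores:

* *training labels* — strict: deficiency requires BP = 10 (MSI samples
  excluded), proficiency requires no deep deletion, no LOH, and every
  variant at P <= 3;
* *HRD-cause calling* — looser: deep deletion; LOH + germline variant with
  P >= 4; LOH + somatic variant with P >= 3; or two variants (germline +
  somatic, or two somatic) both at P = 5.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .config import Thresholds, DEFAULT_THRESHOLDS
from .contexts import SmallVariant

CLINVAR_P_SCORES = {
    "pathogenic": 5,
    "likely_pathogenic": 4,
    "VUS": 3,
    "likely_benign": 2,
    "benign": 1,
}
EFFECT_P_SCORES = {
    "frameshift_oof": 5,
    "nonsense": 4,
    "splice": 4,
    "missense": 3,
    "essential_splice": 3,
    "inframe": 3,
    "other": 2,
}


@dataclass(frozen=True)
class GeneRegion:
    gene: str
    chrom: str
    start: int  # 0-based half-open transcript span
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene}: start must be < end")


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    total_cn: float
    minor_cn: float

    def __post_init__(self) -> None:
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        # small tolerance for caller noise in minor vs total
        if self.minor_cn > self.total_cn + 0.1:
            raise ValueError("minor_cn exceeds total_cn beyond tolerance")

    def overlaps(self, region: GeneRegion) -> bool:
        return (
            self.chrom == region.chrom
            and self.start < region.end
            and self.end > region.start
        )


@dataclass(frozen=True)
class AnnotatedVariant:
    """A small variant with pathogenicity annotation attached; at least one
    of ``clinvar_class`` / ``effect_class`` must be present."""

    variant: SmallVariant
    clinvar_class: Optional[str] = None  # pathogenic .. benign, or None/absent
    effect_class: Optional[str] = None
    high_freq_germline: bool = False

    @property
    def origin(self) -> str:
        return self.variant.origin

    def is_frameshift(self) -> bool:
        return self.effect_class == "frameshift_oof"


@dataclass(frozen=True)
class GeneEvent:
    """One allele-level event contributing to a biallelic pair."""

    kind: str  # deep_deletion | loh | variant
    p_score: int
    variant: Optional[AnnotatedVariant] = None


@dataclass
class GeneStatusCall:
    """Biallelic status of one gene in one sample."""

    gene: str
    event_a: Optional[GeneEvent]
    event_b: Optional[GeneEvent]
    bp_score: int
    deficient: bool
    has_deep_deletion: bool
    has_loh: bool
    max_variant_p: int

    @property
    def p_a(self) -> int:
        return self.event_a.p_score if self.event_a else 0

    @property
    def p_b(self) -> int:
        return self.event_b.p_score if self.event_b else 0


# ---------------------------------------------------------------------------
# Scoring primitives
# ---------------------------------------------------------------------------


def assign_p_score(v: AnnotatedVariant) -> int:
    """P-score of one annotated variant (0-5); the clinical-significance
    class takes precedence over the predicted effect class."""
    if v.high_freq_germline:
        return 0
    if v.clinvar_class and v.clinvar_class != "absent":
        try:
            return CLINVAR_P_SCORES[v.clinvar_class]
        except KeyError:
            raise ValueError(f"unknown clinical class {v.clinvar_class!r}")
    if v.effect_class:
        try:
            return EFFECT_P_SCORES[v.effect_class]
        except KeyError:
            raise ValueError(f"unknown effect class {v.effect_class!r}")
    raise ValueError("variant has neither clinical nor effect annotation")


def _gene_segments(
    gene: GeneRegion, segments: Iterable[CopyNumberSegment]
) -> list[CopyNumberSegment]:
    overlapping = [s for s in segments if s.overlaps(gene)]
    if not overlapping:
        raise ValueError(f"no copy-number segment covers {gene.gene}")
    return overlapping


def detect_deep_deletion(
    gene: GeneRegion,
    segments: Iterable[CopyNumberSegment],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Complete somatic loss: minimum total copy number over segments
    overlapping the gene strictly below the cutoff (default 0.3)."""
    return (
        min(s.total_cn for s in _gene_segments(gene, segments))
        < thresholds.deep_deletion_cn
    )


def detect_loh(
    gene: GeneRegion,
    segments: Iterable[CopyNumberSegment],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Loss of heterozygosity: minimum minor-allele copy number over the
    gene strictly below the cutoff (default 0.2); covers copy-neutral LOH."""
    return (
        min(s.minor_cn for s in _gene_segments(gene, segments))
        < thresholds.loh_minor_cn
    )


# ---------------------------------------------------------------------------
# Biallelic pair selection
# ---------------------------------------------------------------------------

LOH_P_SCORE = 5


def _variant_pairs(
    variants: Sequence[tuple[AnnotatedVariant, int]]
) -> list[tuple[tuple[AnnotatedVariant, int], tuple[AnnotatedVariant, int]]]:
    """Eligible two-variant combinations: germline+somatic or two somatic
    (two germline hits sit on the same haplotype often enough that they are
    not treated as biallelic)."""
    pairs = []
    for i in range(len(variants)):
        for j in range(i + 1, len(variants)):
            a, b = variants[i], variants[j]
            origins = {a[0].origin, b[0].origin}
            if origins == {"germline"}:
                continue
            pairs.append((a, b))
    return pairs


def determine_biallelic_status(
    gene: GeneRegion,
    segments: Iterable[CopyNumberSegment],
    variants: Iterable[AnnotatedVariant] = (),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> GeneStatusCall:
    """Score the best biallelic event pair for one gene in one sample.

    A deep deletion wins outright (BP = 10).  Otherwise every eligible
    event pair — LOH with a variant, or two variants — is scored as the sum
    of its P-scores and the highest-scoring pair is taken, with ties broken
    greedily in the order LOH+frameshift > LOH+other variant > variant
    pairs (and by descending variant P-score within each group)."""
    segments = list(segments)
    variants = list(variants)
    scored = [(v, assign_p_score(v)) for v in variants]
    max_variant_p = max((p for _, p in scored), default=0)
    deep = detect_deep_deletion(gene, segments, thresholds)
    loh = detect_loh(gene, segments, thresholds)

    if deep:
        ev = GeneEvent("deep_deletion", LOH_P_SCORE)
        return GeneStatusCall(
            gene=gene.gene,
            event_a=ev,
            event_b=ev,
            bp_score=10,
            deficient=True,
            has_deep_deletion=True,
            has_loh=loh,
            max_variant_p=max_variant_p,
        )

    # candidate pairs in greedy tie-break order
    candidates: list[tuple[GeneEvent, GeneEvent]] = []
    if loh:
        loh_ev = GeneEvent("loh", LOH_P_SCORE)
        ordered = sorted(
            scored, key=lambda vp: (not vp[0].is_frameshift(), -vp[1])
        )
        for v, p in ordered:
            candidates.append((loh_ev, GeneEvent("variant", p, v)))
    for (va, pa), (vb, pb) in sorted(
        _variant_pairs(scored), key=lambda ab: -(ab[0][1] + ab[1][1])
    ):
        candidates.append(
            (GeneEvent("variant", pa, va), GeneEvent("variant", pb, vb))
        )

    best: tuple[Optional[GeneEvent], Optional[GeneEvent]] = (None, None)
    best_score = -1
    for a, b in candidates:
        score = a.p_score + b.p_score
        if score > best_score:
            best, best_score = (a, b), score

    if best_score < 0:
        # no pair available: report the single strongest event, if any
        if loh:
            best, best_score = (GeneEvent("loh", LOH_P_SCORE), None), LOH_P_SCORE
        elif scored:
            v, p = max(scored, key=lambda vp: vp[1])
            best, best_score = (GeneEvent("variant", p, v), None), p
        else:
            best_score = 0

    return GeneStatusCall(
        gene=gene.gene,
        event_a=best[0],
        event_b=best[1],
        bp_score=max(best_score, 0),
        deficient=best_score >= 10,
        has_deep_deletion=False,
        has_loh=loh,
        max_variant_p=max_variant_p,
    )


# ---------------------------------------------------------------------------
# Training labels
# ---------------------------------------------------------------------------


def label_training_samples(
    brca1_calls: Mapping[str, GeneStatusCall],
    brca2_calls: Mapping[str, GeneStatusCall],
    msi_flags: Mapping[str, bool],
) -> dict[str, Optional[str]]:
    """Assign BRCA1 / BRCA2 / none training labels per sample.

    Deficiency (BP = 10 in either gene) labels the sample by the deficient
    gene, unless the sample is MSI (repeat-indel hypermutation masks the
    deletion features), in which case it is left unlabeled.  Proficiency
    ("none") requires, in both genes, no deep deletion, no LOH, and no
    variant above P = 3.  Everything else is unlabeled (``None``) and
    excluded from training.  If both genes score BP = 10 the label goes to
    BRCA2, by far the larger deficiency class.
    """
    labels: dict[str, Optional[str]] = {}
    for sample in brca1_calls:
        b1, b2 = brca1_calls[sample], brca2_calls[sample]
        msi = bool(msi_flags.get(sample, False))
        if b1.deficient or b2.deficient:
            labels[sample] = None if msi else ("BRCA2" if b2.deficient else "BRCA1")
            continue
        proficient = all(
            not c.has_deep_deletion and not c.has_loh and c.max_variant_p <= 3
            for c in (b1, b2)
        )
        labels[sample] = "none" if proficient else None
    return labels


# ---------------------------------------------------------------------------
# HRD-cause calling (looser thresholds than training)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CauseCall:
    """A biallelic-loss call under the cause-calling rule set."""

    gene: str
    rule: str  # deep_deletion | loh_germline | loh_somatic | variant_pair
    events: tuple


def call_hrd_cause(
    gene: GeneRegion,
    segments: Iterable[CopyNumberSegment],
    variants: Iterable[AnnotatedVariant] = (),
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Optional[CauseCall]:
    """Flag biallelic loss of one gene under the cause-calling rules:
    (i) deep deletion; (ii) LOH + germline variant with P >= 4; (iii) LOH +
    somatic variant with P >= 3; (iv) two variants (germline + somatic or
    two somatic) both with P = 5.  Returns ``None`` when no rule fires."""
    segments = list(segments)
    scored = [(v, assign_p_score(v)) for v in variants]
    if detect_deep_deletion(gene, segments, thresholds):
        ev = GeneEvent("deep_deletion", LOH_P_SCORE)
        return CauseCall(gene.gene, "deep_deletion", (ev, ev))
    if detect_loh(gene, segments, thresholds):
        loh_ev = GeneEvent("loh", LOH_P_SCORE)
        germ = [
            (v, p) for v, p in scored if v.origin == "germline" and p >= 4
        ]
        if germ:
            v, p = max(germ, key=lambda vp: vp[1])
            return CauseCall(
                gene.gene, "loh_germline", (loh_ev, GeneEvent("variant", p, v))
            )
        som = [(v, p) for v, p in scored if v.origin == "somatic" and p >= 3]
        if som:
            v, p = max(som, key=lambda vp: vp[1])
            return CauseCall(
                gene.gene, "loh_somatic", (loh_ev, GeneEvent("variant", p, v))
            )
    p5 = [(v, p) for v, p in scored if p == 5]
    for (va, pa), (vb, pb) in _variant_pairs(p5):
        return CauseCall(
            gene.gene,
            "variant_pair",
            (GeneEvent("variant", pa, va), GeneEvent("variant", pb, vb)),
        )
    return None


def mark_high_frequency_germline(
    cohort_variants: Mapping[str, Sequence[AnnotatedVariant]],
    freq_threshold: float = DEFAULT_THRESHOLDS.germline_benign_freq,
) -> dict[str, list[AnnotatedVariant]]:
    """Pre-mark germline variants seen in more than ``freq_threshold`` of
    cohort germlines as benign (P-score 0); returns updated per-sample
    variant lists."""
    n_samples = len(cohort_variants)
    counts: Counter = Counter()
    for vs in cohort_variants.values():
        seen = set()
        for av in vs:
            if av.origin == "germline":
                v = av.variant
                seen.add((v.chrom, v.pos, v.ref, v.alt))
        counts.update(seen)
    frequent = {
        k for k, c in counts.items() if n_samples and c / n_samples > freq_threshold
    }
    out: dict[str, list[AnnotatedVariant]] = {}
    for sample, vs in cohort_variants.items():
        updated = []
        for av in vs:
            v = av.variant
            if av.origin == "germline" and (v.chrom, v.pos, v.ref, v.alt) in frequent:
                av = replace(av, high_freq_germline=True)
            updated.append(av)
        out[sample] = updated
    return out
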