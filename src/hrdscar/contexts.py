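"""Mutation-context classification.

Somatic variants are binned into 142 context categories that together form a
per-sample mutational profile:

* 96 SNV contexts — the six pyrimidine-referenced base substitutions
  (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the immediate 5' and 3'
  flanking bases;
* 30 indel contexts — deletions/insertions in tandem repeats (``del.rep``,
  ``ins.rep``), with flanking microhomology (``del.mh``, ``ins.mh``) or with
  neither (``del.none``, ``ins.none``), stratified by indel length or by the
  number of bases in microhomology (1, 2, 3, 4, >=5);
* 16 SV contexts — deletion/duplication/inversion crossed with five length
  bins (1-10 kb, 10-100 kb, 100 kb-1 Mb, 1-10 Mb, >10 Mb) plus translocation.

Classification rules
--------------------
An indel sits in a *repeat* region when at least one full copy of the indel
sequence immediately follows the breakpoint (3' direction) and the indel is
shorter than 50 bp.  *Microhomology* is present when (i) a full copy of the
indel sequence flanks the breakpoint for indels >=50 bp, (ii) >=2 bp of the
indel sequence is found identically up- or downstream, or (iii) >=1 bp is,
for indels >=3 bp; the flank searched on each side spans as many bases as
the indel itself.  Repeat classification takes precedence over microhomology
for sub-50 bp indels, since a full downstream copy satisfies both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Protocol, Sequence

import pandas as pd

from .config import Thresholds, DEFAULT_THRESHOLDS

# ---------------------------------------------------------------------------
# Context key enumerations (fixed order; feature construction relies on it)
# ---------------------------------------------------------------------------

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

SNV_CONTEXTS: tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_TYPES
    for f5 in _BASES
    for f3 in _BASES
)

INDEL_TYPES = ("del.mh", "ins.mh", "del.rep", "ins.rep", "del.none", "ins.none")

INDEL_CONTEXTS: tuple[str, ...] = tuple(
    f"{t}.{'bimh' if t.endswith('.mh') else 'len'}.{b}"
    for t in INDEL_TYPES
    for b in (1, 2, 3, 4, 5)
)

SV_TYPES = ("DEL", "DUP", "INV")
SV_LENGTH_BINS: tuple[tuple[float, float, str], ...] = (
    (1e3, 1e4, "1e03_1e04_bp"),
    (1e4, 1e5, "1e04_1e05_bp"),
    (1e5, 1e6, "1e05_1e06_bp"),
    (1e6, 1e7, "1e06_1e07_bp"),
    (1e7, float("inf"), "1e07_Inf_bp"),
)

SV_CONTEXTS: tuple[str, ...] = tuple(
    f"{t}_{label}" for t in SV_TYPES for _, _, label in SV_LENGTH_BINS
) + ("TRA",)

ALL_CONTEXTS: tuple[str, ...] = SNV_CONTEXTS + INDEL_CONTEXTS + SV_CONTEXTS

assert len(SNV_CONTEXTS) == 96
assert len(INDEL_CONTEXTS) == 30
assert len(SV_CONTEXTS) == 16

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class InvalidVariantError(ValueError):
    """The record violates the variant contract (e.g. REF == ALT)."""


class SkippedVariant(Exception):
    """Raised internally when a record cannot be classified (e.g. N in the
    relevant sequence); callers count these rather than failing the batch."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmallVariant:
    """A somatic or germline SNV/indel in VCF convention (1-based ``pos``,
    REF/ALT possibly sharing a padding base)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str = "somatic"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise InvalidVariantError("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise InvalidVariantError("REF == ALT is not a variant")


@dataclass(frozen=True)
class StructuralVariant:
    """A somatic SV reduced to type + length (length absent for TRA)."""

    sv_type: str
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sv_type not in ("DEL", "DUP", "INV", "TRA"):
            raise InvalidVariantError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type == "TRA":
            if self.length is not None:
                raise InvalidVariantError("TRA carries no length")
        elif self.length is not None and self.length <= 0:
            raise InvalidVariantError("SV length must be positive")


class ReferenceSequenceStore(Protocol):
    """Anything that can serve uppercase reference substrings.

    ``substring(chrom, start, end)`` uses 0-based half-open coordinates and
    may return fewer than ``end - start`` bases at contig boundaries.
    """

    def substring(self, chrom: str, start: int, end: int) -> str: ...


class InMemoryGenome:
    """Dict-backed reference store; the workhorse for tests and simulation."""

    def __init__(self, contigs: Mapping[str, str]):
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}

    def substring(self, chrom: str, start: int, end: int) -> str:
        seq = self.contigs[chrom]
        return seq[max(start, 0) : max(end, 0)]

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass
class MutationContextProfile:
    """Integer counts over the 142 context categories for one sample."""

    counts: Dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in ALL_CONTEXTS}
    )
    n_skipped: int = 0

    def __post_init__(self) -> None:
        full = {k: 0 for k in ALL_CONTEXTS}
        for k, v in self.counts.items():
            if k not in full:
                raise KeyError(f"unknown context key {k!r}")
            if v < 0 or int(v) != v:
                raise ValueError(f"count for {k!r} must be a non-negative int")
            full[k] = int(v)
        self.counts = full

    # -- views -------------------------------------------------------------
    @property
    def snv_96(self) -> Dict[str, int]:
        return {k: self.counts[k] for k in SNV_CONTEXTS}

    @property
    def indel_30(self) -> Dict[str, int]:
        return {k: self.counts[k] for k in INDEL_CONTEXTS}

    @property
    def sv_16(self) -> Dict[str, int]:
        return {k: self.counts[k] for k in SV_CONTEXTS}

    def total(self) -> int:
        return sum(self.counts.values())

    def n_indels(self) -> int:
        return sum(self.indel_30.values())

    def n_svs(self) -> int:
        return sum(self.sv_16.values())

    def repeat_indel_total(self) -> int:
        return sum(
            v for k, v in self.counts.items()
            if k.startswith(("del.rep", "ins.rep"))
        )

    def to_series(self, name: str | None = None) -> pd.Series:
        return pd.Series(self.counts, index=list(ALL_CONTEXTS), name=name)

    @classmethod
    def from_series(cls, s: pd.Series) -> "MutationContextProfile":
        return cls(counts={k: int(s[k]) for k in ALL_CONTEXTS})


# ---------------------------------------------------------------------------
# Variant normalisation (internal 0-based half-open coordinates)
# ---------------------------------------------------------------------------


def _strip_padding(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Trim shared suffix then prefix; returns (ref, alt, 0-based pos)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    start = pos - 1
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    return ref, alt, start


def _left_align(
    chrom: str, start: int, seq: str, genome: ReferenceSequenceStore
) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement."""
    while start > 0:
        prev = genome.substring(chrom, start - 1, start)
        if prev != seq[-1]:
            break
        seq = prev + seq[:-1]
        start -= 1
    return start, seq


def normalize_indel(
    variant: SmallVariant, genome: ReferenceSequenceStore
) -> tuple[str, int, str]:
    """Reduce a VCF-style record to (``'del'``/``'ins'``, 0-based start of the
    deleted segment or insertion point, indel sequence), left-aligned.

    Raises :class:`InvalidVariantError` for records that are neither a pure
    insertion nor a pure deletion after padding removal.
    """
    ref, alt, start = _strip_padding(variant.ref, variant.alt, variant.pos)
    if ref and alt:
        raise InvalidVariantError(
            f"{variant.ref}>{variant.alt} is a substitution/complex allele, "
            "not a pure indel"
        )
    if ref:
        start, seq = _left_align(variant.chrom, start, ref, genome)
        return "del", start, seq
    start, seq = _left_align(variant.chrom, start, alt, genome)
    return "ins", start, seq


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_snv_context(
    variant: SmallVariant, genome: ReferenceSequenceStore
) -> str:
    """Return the trinucleotide context key (e.g. ``"A[C>T]G"``).

    Purine reference bases are reverse-complemented together with both
    flanks, so the reference base of the key is always C or T.
    """
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise InvalidVariantError("not a single-base substitution")
    ref, alt = variant.ref.upper(), variant.alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise SkippedVariant("non-ACGT allele")
    pos0 = variant.pos - 1
    f5 = genome.substring(variant.chrom, pos0 - 1, pos0)
    f3 = genome.substring(variant.chrom, pos0 + 1, pos0 + 2)
    if len(f5) != 1 or len(f3) != 1:
        raise SkippedVariant("variant at contig boundary")
    if ref in "AG":  # purine: flip strand
        ref, alt = reverse_complement(ref), reverse_complement(alt)
        f5, f3 = reverse_complement(f3), reverse_complement(f5)
    if "N" in f5 + f3 + ref + alt:
        raise SkippedVariant("N in context")
    return f"{f5}[{ref}>{alt}]{f3}"


def _longest_common_prefix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def classify_indel_context(
    variant: SmallVariant, genome: ReferenceSequenceStore
) -> str:
    """Classify an indel into one of the 30 indel context keys.

    See the module docstring for the repeat/microhomology rules; the
    homology search window on each side equals the indel length, and the
    number of bases in microhomology (bimh) is the larger of the downstream
    prefix match and the upstream suffix match.
    """
    kind, start, seq = normalize_indel(variant, genome)
    if "N" in seq:
        raise SkippedVariant("N in indel sequence")
    length = len(seq)
    chrom = variant.chrom
    # For deletions the breakpoint flanks exclude the deleted bases; for
    # insertions both flanks meet at the insertion point.
    down_start = start + length if kind == "del" else start
    down = genome.substring(chrom, down_start, down_start + length)
    up = genome.substring(chrom, start - length, start)

    if length < 50 and down == seq:
        return f"{kind}.rep.len.{min(length, 5)}"

    if length >= 50 and (down == seq or up.endswith(seq)):
        return f"{kind}.mh.bimh.5"

    bimh = max(
        _longest_common_prefix(seq, down),
        _longest_common_prefix(seq[::-1], up[::-1]),
    )
    if bimh >= 2 or (bimh >= 1 and length >= 3):
        return f"{kind}.mh.bimh.{min(bimh, 5)}"
    return f"{kind}.none.len.{min(length, 5)}"


def classify_sv_context(
    sv: StructuralVariant, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map an SV to one of the 16 type x length-bin keys.

    Translocations are a type-only bin; SVs below the smallest length bin
    (default 1 kb) are not counted and raise :class:`SkippedVariant`.
    """
    if sv.sv_type == "TRA":
        return "TRA"
    if sv.length is None:
        raise InvalidVariantError(f"{sv.sv_type} without a length")
    if sv.length < thresholds.sv_min_length:
        raise SkippedVariant("SV below the smallest context bin")
    for lo, hi, label in SV_LENGTH_BINS:
        if lo <= sv.length < hi:
            return f"{sv.sv_type}_{label}"
    raise AssertionError("unreachable: bins cover [1e3, inf)")


def extract_profile(
    small_variants: Iterable[SmallVariant],
    svs: Iterable[StructuralVariant] = (),
    genome: ReferenceSequenceStore | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> MutationContextProfile:
    """Accumulate the 142-key context profile for one sample.

    Each accepted variant increments exactly one key.  Records that cannot
    be classified (complex alleles, N-containing context, sub-1 kb SVs) are
    skipped individually and tallied in ``profile.n_skipped``; the batch
    never fails on a single record.
    """
    profile = MutationContextProfile()
    for v in small_variants:
        try:
            ref, alt, start = _strip_padding(v.ref, v.alt, v.pos)
            if len(ref) == 1 and len(alt) == 1:
                stripped = SmallVariant(v.chrom, start + 1, ref, alt, v.origin)
                key = classify_snv_context(stripped, genome)
            else:
                key = classify_indel_context(v, genome)
            profile.counts[key] += 1
        except (SkippedVariant, InvalidVariantError):
            profile.n_skipped += 1
    for sv in svs:
        try:
            profile.counts[classify_sv_context(sv, thresholds)] += 1
        except (SkippedVariant, InvalidVariantError):
            profile.n_skipped += 1
    return profile


def detect_msi(
    profile: MutationContextProfile,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """MSI flag: strictly more repeat-region indels than the threshold.

    Microsatellite-instable samples drown the microhomology-deletion signal
    in repeat indels and are excluded from HRD training/calling.
    """
    return profile.repeat_indel_total() > thresholds.msi_repeat_indels
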