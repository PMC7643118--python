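"""Readers and writers for the standard formats around the pipeline.

VCF coordinates are 1-based; everything internal is 0-based half-open, and
the conversion happens only here.  Small-variant VCFs are consumed through
pysam; SV VCFs may use symbolic ALTs (``<DEL>``/``<DUP>``/``<INV>`` with
INFO END or SVLEN) or breakend (BND) mate pairs, in which case
intra-chromosomal pairs are typed from the breakend orientation and
inter-chromosomal pairs become translocations.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam
import pyfaidx

from .biallelic import CopyNumberSegment, GeneRegion
from .contexts import (
    ALL_CONTEXTS,
    InvalidVariantError,
    MutationContextProfile,
    SmallVariant,
    StructuralVariant,
)


class FastaReferenceStore:
    """Reference substrings from an indexed FASTA (0-based half-open)."""

    def __init__(self, path):
        self.fasta = pyfaidx.Fasta(str(path), sequence_always_upper=True)

    def substring(self, chrom: str, start: int, end: int) -> str:
        if end <= 0:
            return ""
        return str(self.fasta[chrom][max(start, 0) : end])


# ---------------------------------------------------------------------------
# Small-variant VCF
# ---------------------------------------------------------------------------


def read_small_variant_vcf(
    path, origin: str = "somatic"
) -> tuple[list[SmallVariant], int]:
    """Stream SNVs/indels from a VCF; multi-allelic records are decomposed
    per ALT allele.  Returns ``(variants, n_skipped)`` — records whose
    alleles violate the variant contract are counted and skipped, never
    fatal; a malformed header is."""
    variants: list[SmallVariant] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if not alts:
                n_skipped += 1
                continue
            for alt in alts:
                try:
                    if alt is None or not re.fullmatch(r"[ACGTacgt]+", alt or ""):
                        raise InvalidVariantError("non-sequence ALT")
                    if not re.fullmatch(r"[ACGTacgt]+", rec.ref or ""):
                        raise InvalidVariantError("non-sequence REF")
                    variants.append(
                        SmallVariant(
                            rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), origin
                        )
                    )
                except InvalidVariantError:
                    n_skipped += 1
    return variants, n_skipped


def _vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    return header


def write_small_variant_vcf(
    variants: Iterable[SmallVariant], path, contigs: Mapping[str, int]
) -> None:
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            out.write(rec)


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?P<leading>[ACGTNacgtn]*)"
    r"(?P<open>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P<close>[\[\]])"
    r"(?P<trailing>[ACGTNacgtn]*)$"
)


def _type_bnd_pair(
    chrom1: str, pos1: int, alt1: str, chrom2: str, pos2: int
) -> StructuralVariant:
    """Type an intra-chromosomal breakend pair from the orientation of the
    lower-coordinate mate: ``t[p[`` joins rightward (deletion-like),
    ``]p]t`` joins leftward (tandem duplication), the two mixed forms are
    inversion breakends.  Inter-chromosomal pairs are translocations."""
    if chrom1 != chrom2:
        return StructuralVariant("TRA")
    m = _BND_RE.match(alt1)
    if not m:
        raise InvalidVariantError(f"unparseable breakend ALT {alt1!r}")
    length = abs(pos2 - pos1)
    leading = bool(m.group("leading"))
    bracket = m.group("open")
    if leading and bracket == "[":
        sv_type = "DEL"
    elif not leading and bracket == "]":
        sv_type = "DUP"
    else:
        sv_type = "INV"
    return StructuralVariant(sv_type, max(length, 1))


def read_sv_vcf(path) -> tuple[list[StructuralVariant], int]:
    """Read structural variants from symbolic-ALT or breakend records;
    returns ``(svs, n_skipped)``.  Each BND mate pair yields one SV."""
    svs: list[StructuralVariant] = []
    n_skipped = 0
    bnds: list[tuple[str, int, str, Optional[str]]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            svtype = info.get("SVTYPE")
            alt = (rec.alts or (None,))[0]
            try:
                if svtype == "BND" or (alt and ("[" in alt or "]" in alt)):
                    bnds.append((rec.chrom, rec.pos, alt, rec.id))
                    continue
                if svtype in ("DEL", "DUP", "INV"):
                    end = info.get("END")
                    if end is None and rec.stop and rec.stop > rec.start + 1:
                        end = rec.stop
                    if end is not None:
                        length = int(end) - rec.pos
                    elif "SVLEN" in info:
                        svlen = info["SVLEN"]
                        if isinstance(svlen, tuple):
                            svlen = svlen[0]
                        length = abs(int(svlen))
                    else:
                        raise InvalidVariantError("SV without END/SVLEN")
                    svs.append(StructuralVariant(svtype, length))
                elif svtype in ("TRA", "CTX"):
                    svs.append(StructuralVariant("TRA"))
                else:
                    raise InvalidVariantError(f"unsupported SVTYPE {svtype!r}")
            except InvalidVariantError:
                n_skipped += 1
    # pair breakends by mate coordinates; emit one SV per pair
    seen: set[tuple] = set()
    for chrom, pos, alt, _id in bnds:
        m = _BND_RE.match(alt or "")
        if not m:
            n_skipped += 1
            continue
        mate = (m.group("chrom"), int(m.group("pos")))
        key = tuple(sorted([(chrom, pos), mate]))
        if key in seen:
            continue
        seen.add(key)
        first = min((chrom, pos), mate)
        if (chrom, pos) == first:
            try:
                svs.append(_type_bnd_pair(chrom, pos, alt, *mate))
            except InvalidVariantError:
                n_skipped += 1
        else:
            # we hold the higher mate; infer from the lower one if present,
            # otherwise type from this record's mirrored orientation
            lower = next(
                (b for b in bnds if (b[0], b[1]) == first), None
            )
            if lower is None or not _BND_RE.match(lower[2] or ""):
                n_skipped += 1
            else:
                try:
                    svs.append(
                        _type_bnd_pair(lower[0], lower[1], lower[2], chrom, pos)
                    )
                except InvalidVariantError:
                    n_skipped += 1
    return svs, n_skipped


def write_sv_vcf(
    svs: Iterable[StructuralVariant],
    path,
    contig: str = "chr1",
    contig_length: int = 300_000_000,
    tra_contig: str = "chr2",
) -> None:
    """Materialize SVs as symbolic records (TRA as a breakend mate pair)."""
    header = _vcf_header({contig: contig_length, tra_contig: contig_length})
    header.info.add("SVTYPE", 1, "String", "SV type")
    header.info.add("END", 1, "Integer", "SV end")
    header.info.add("MATEID", 1, "String", "Breakend mate")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        pos = 10_000
        for i, sv in enumerate(svs):
            if sv.sv_type == "TRA":
                a, b = f"bnd_{i}a", f"bnd_{i}b"
                rec = out.new_record(
                    contig=contig, start=pos - 1,
                    alleles=("N", f"N[{tra_contig}:{pos}["), id=a,
                )
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = b
                out.write(rec)
                rec2 = out.new_record(
                    contig=tra_contig, start=pos - 1,
                    alleles=("N", f"]{contig}:{pos}]N"), id=b,
                )
                rec2.info["SVTYPE"] = "BND"
                rec2.info["MATEID"] = a
                out.write(rec2)
            else:
                rec = out.new_record(
                    contig=contig, start=pos - 1,
                    alleles=("N", f"<{sv.sv_type}>"),
                    stop=pos + sv.length,
                )
                rec.info["SVTYPE"] = sv.sv_type
                out.write(rec)
            pos += 10_000


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def read_copynumber_tsv(path) -> list[CopyNumberSegment]:
    """Copy-number segments from a TSV with columns chrom, start, end,
    total_cn, minor_cn."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "total_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"copy-number TSV lacks columns {sorted(missing)}")
    return [
        CopyNumberSegment(
            str(r.chrom), int(r.start), int(r.end), float(r.total_cn), float(r.minor_cn)
        )
        for r in df.itertuples()
    ]


def write_copynumber_tsv(segments: Iterable[CopyNumberSegment], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "total_cn": s.total_cn,
                "minor_cn": s.minor_cn,
            }
            for s in segments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneRegion]:
    """Gene coordinates from a BED-like TSV: chrom, start, end, gene."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneRegion(str(r.gene), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def read_pathogenicity_tsv(path) -> dict[tuple, str]:
    """Clinical-significance annotations keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): str(r.significance)
        for r in df.itertuples()
    }


def write_profile_tsv(
    profiles: Mapping[str, MutationContextProfile], path
) -> None:
    """Profiles as samples x 142 named context columns."""
    pd.DataFrame(
        {name: p.to_series() for name, p in profiles.items()}
    ).T.rename_axis("sample").to_csv(path, sep="\t")


def read_profile_tsv(path) -> dict[str, MutationContextProfile]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(ALL_CONTEXTS) - set(df.columns)
    if missing:
        raise ValueError(f"profile TSV lacks {len(missing)} context columns")
    return {
        str(name): MutationContextProfile.from_series(row)
        for name, row in df.iterrows()
    }
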