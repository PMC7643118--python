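"""Feature construction for the HRD classifier.

The 142 context counts are collapsed to 29 features: the 96 trinucleotide
contexts to the six substitution types, the 30 indel contexts to seven indel
types — with microhomology deletions split into 1 bp homology
(``del.mh.bimh.1``) and >=2 bp homology (``del.mh.bimh.2.5``), the split that
makes the classifier robust to radiotherapy-induced 1 bp-homology deletions —
and the 16 SV contexts kept as-is.  Relative contributions are computed
separately within each mutation class (SNV, indel, SV) so that samples with
very different mutational loads remain comparable.

Two variants of the feature set are provided: a 28-feature version with all
microhomology deletions merged into one ``del.mh`` feature, and a
signature-based version where SNV and SV contexts are replaced by
non-negative least-squares (NNLS) contributions to reference signature
matrices.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import (
    INDEL_CONTEXTS,
    MutationContextProfile,
    SNV_CONTEXTS,
    SUBSTITUTION_TYPES,
    SV_CONTEXTS,
)

# Fixed feature order: SNV block, indel block, SV block.  Persisted models
# depend on this order; do not reorder.
SPLIT_INDEL_FEATURES = (
    "del.mh.bimh.1",
    "del.mh.bimh.2.5",
    "ins.mh",
    "del.rep",
    "ins.rep",
    "del.none",
    "ins.none",
)
MERGED_INDEL_FEATURES = (
    "del.mh",
    "ins.mh",
    "del.rep",
    "ins.rep",
    "del.none",
    "ins.none",
)
SCAR_FEATURES: tuple[str, ...] = (
    SUBSTITUTION_TYPES + SPLIT_INDEL_FEATURES + SV_CONTEXTS
)
MERGED_FEATURES: tuple[str, ...] = (
    SUBSTITUTION_TYPES + MERGED_INDEL_FEATURES + SV_CONTEXTS
)

assert len(SCAR_FEATURES) == 29
assert len(MERGED_FEATURES) == 28


def _normalize(block: pd.Series) -> pd.Series:
    """Relative contribution within one mutation class; an empty class
    yields an all-zero block rather than NaN (the QC gate downstream flags
    samples with too few mutations to be reliable)."""
    total = block.sum()
    return block / total if total > 0 else block.astype(float)


def _collapse_snv(profile: MutationContextProfile) -> pd.Series:
    counts = pd.Series(profile.snv_96)
    # key "A[C>T]G" -> substitution "C>T"
    subs = counts.groupby(counts.index.str.slice(2, 5)).sum()
    return subs.reindex(SUBSTITUTION_TYPES, fill_value=0)


def _collapse_indel(
    profile: MutationContextProfile, split_mh: bool
) -> pd.Series:
    c = profile.indel_30
    out: dict[str, int] = {}
    if split_mh:
        out["del.mh.bimh.1"] = c["del.mh.bimh.1"]
        out["del.mh.bimh.2.5"] = sum(c[f"del.mh.bimh.{b}"] for b in (2, 3, 4, 5))
    else:
        out["del.mh"] = sum(c[f"del.mh.bimh.{b}"] for b in (1, 2, 3, 4, 5))
    out["ins.mh"] = sum(c[f"ins.mh.bimh.{b}"] for b in (1, 2, 3, 4, 5))
    for t in ("del.rep", "ins.rep", "del.none", "ins.none"):
        out[t] = sum(c[f"{t}.len.{b}"] for b in (1, 2, 3, 4, 5))
    order = SPLIT_INDEL_FEATURES if split_mh else MERGED_INDEL_FEATURES
    return pd.Series(out).reindex(order)


def build_scar_features(profile: MutationContextProfile) -> pd.Series:
    """The 29-feature vector: 6 SNV + 7 indel + 16 SV relative contributions,
    each block normalized by its own total."""
    snv = _normalize(_collapse_snv(profile))
    indel = _normalize(_collapse_indel(profile, split_mh=True))
    sv = _normalize(pd.Series(profile.sv_16).reindex(SV_CONTEXTS))
    return pd.concat([snv, indel, sv]).reindex(SCAR_FEATURES)


def build_merged_mh_features(profile: MutationContextProfile) -> pd.Series:
    """The 28-feature variant with all microhomology deletions in one bin."""
    snv = _normalize(_collapse_snv(profile))
    indel = _normalize(_collapse_indel(profile, split_mh=False))
    sv = _normalize(pd.Series(profile.sv_16).reindex(SV_CONTEXTS))
    return pd.concat([snv, indel, sv]).reindex(MERGED_FEATURES)


def build_feature_table(
    profiles: Mapping[str, MutationContextProfile] | Iterable[tuple[str, MutationContextProfile]],
    merged_mh: bool = False,
) -> pd.DataFrame:
    """Stack per-sample feature vectors into a samples x features table."""
    items = profiles.items() if hasattr(profiles, "items") else profiles
    build = build_merged_mh_features if merged_mh else build_scar_features
    return pd.DataFrame({name: build(p) for name, p in items}).T


def fit_signatures_nnls(
    catalog: pd.Series | np.ndarray, signatures: pd.DataFrame
) -> pd.Series:
    """Non-negative least-squares fit of a context-count catalog to a
    reference signature matrix (contexts x signatures, columns summing
    to 1); returns absolute per-signature contributions.
    """
    sig = np.asarray(signatures, dtype=float)
    if isinstance(catalog, pd.Series):
        if list(catalog.index) != list(signatures.index):
            catalog = catalog.reindex(signatures.index)
            if catalog.isna().any():
                raise ValueError("catalog and signature contexts do not match")
    y = np.asarray(catalog, dtype=float)
    if y.ndim != 1 or y.shape[0] != sig.shape[0]:
        raise ValueError(
            f"catalog length {y.shape[0]} != signature contexts {sig.shape[0]}"
        )
    if (y < 0).any():
        raise ValueError("context counts must be non-negative")
    coef, _ = nnls(sig, y)
    return pd.Series(coef, index=signatures.columns)


def build_signature_features(
    profile: MutationContextProfile,
    sbs_signatures: pd.DataFrame,
    sv_signatures: pd.DataFrame,
) -> pd.Series:
    """Signature-based feature variant: SNV and SV context counts are
    replaced by NNLS contributions to the supplied signature matrices
    (indexed by the 96 SNV / 16 SV context keys); the seven indel features
    are retained.  Each block is then normalized as usual.
    """
    snv_contrib = fit_signatures_nnls(
        pd.Series(profile.snv_96).reindex(list(SNV_CONTEXTS)), sbs_signatures
    )
    sv_contrib = fit_signatures_nnls(
        pd.Series(profile.sv_16).reindex(list(SV_CONTEXTS)), sv_signatures
    )
    indel = _normalize(_collapse_indel(profile, split_mh=True))
    return pd.concat([_normalize(snv_contrib), indel, _normalize(sv_contrib)])


def read_signature_tsv(path) -> pd.DataFrame:
    """Read a contexts x signatures TSV (first column = context keys)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("signature matrix must be non-negative")
    return df
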