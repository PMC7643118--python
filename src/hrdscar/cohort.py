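"""Cohort-level genetic explanation of HRD calls.

Three analyses link the classifier output back to gene inactivation:

* per-gene enrichment of biallelic deficiency in HRD vs HRP samples
  (one-tailed Fisher's exact test, Hochberg-adjusted);
* a copy-number-alteration co-occurrence test that exposes passenger genes
  whose deep deletions / LOH merely ride along with an anchor gene on the
  same chromosome arm (the classic neighbour-gene confound);
* the ordered clustering of HRD samples by subtype and causal gene used to
  lay out deficiency landscapes.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .biallelic import GeneStatusCall

HRD_GENE_PRIORITY = ("BRCA2", "BRCA1", "RAD51C", "PALB2")


def default_gene_universe(n: int = 781) -> list[str]:
    """The default gene universe for enrichment testing: the HRD priority
    genes followed by synthetic placeholder symbols up to ``n`` genes.

    The real curated cancer-gene list is external data; the universe is
    pluggable (any column set on the deficiency matrix works), and this
    stand-in only fixes its size and the guaranteed presence of the HRD
    genes."""
    if n < len(HRD_GENE_PRIORITY):
        raise ValueError("universe must include the HRD priority genes")
    fillers = [f"GENE{i:04d}" for i in range(n - len(HRD_GENE_PRIORITY))]
    return list(HRD_GENE_PRIORITY) + fillers


def _hochberg(p: np.ndarray) -> np.ndarray:
    # Hochberg step-up, as in R's p.adjust(method="hochberg")
    return multipletests(p, method="simes-hochberg")[1]


def enrichment_test(
    deficiency: pd.DataFrame, hrd_calls: pd.Series
) -> pd.DataFrame:
    """Per-gene one-tailed Fisher test for deficiency enrichment in HRD.

    Parameters
    ----------
    deficiency : boolean samples x genes matrix of biallelic inactivation.
    hrd_calls : boolean (or ``"HRD"``/``"HRP"``) per-sample classifier call.

    Returns a genes x (n_hrd_deficient, n_hrp_deficient, p, q) frame, with
    q-values from the Hochberg step-up over all tested genes.
    """
    hrd = hrd_calls.reindex(deficiency.index)
    if hrd.isna().any():
        raise ValueError("hrd_calls missing for some samples")
    if hrd.dtype == object:
        hrd = hrd == "HRD"
    hrd = hrd.astype(bool)
    if hrd.all() or not hrd.any():
        raise ValueError("need at least one HRD and one HRP sample")
    rows = []
    for gene in deficiency.columns:
        d = deficiency[gene].astype(bool)
        a = int((d & hrd).sum())     # deficient, HRD
        b = int((d & ~hrd).sum())    # deficient, HRP
        c = int((~d & hrd).sum())
        e = int((~d & ~hrd).sum())
        p = fisher_exact([[a, b], [c, e]], alternative="greater")[1]
        rows.append((gene, a, b, p))
    out = pd.DataFrame(
        rows, columns=["gene", "n_hrd_deficient", "n_hrp_deficient", "p"]
    ).set_index("gene")
    out["q"] = _hochberg(out["p"].values)
    return out


def cna_cooccurrence_test(
    cna: pd.DataFrame, anchor_genes: Sequence[str] = ("BRCA1", "BRCA2")
) -> pd.DataFrame:
    """Per-gene one-tailed Fisher test of CNA co-occurrence with each
    anchor gene (deep deletion or LOH treated as a single CNA state).

    Genes whose deficiency enrichment is explained by chromosomal linkage
    to an anchor (e.g. a neighbour on the same arm) show up with small
    q-values here while having no causal role themselves.
    """
    out = pd.DataFrame(index=cna.columns)
    for anchor in anchor_genes:
        if anchor not in cna.columns:
            raise ValueError(f"anchor gene {anchor!r} not in the CNA matrix")
        anchored = cna[anchor].astype(bool)
        ps = []
        for gene in cna.columns:
            g = cna[gene].astype(bool)
            table = [
                [int((g & anchored).sum()), int((g & ~anchored).sum())],
                [int((~g & anchored).sum()), int((~g & ~anchored).sum())],
            ]
            ps.append(fisher_exact(table, alternative="greater")[1])
        out[f"p_{anchor}"] = ps
        out[f"q_{anchor}"] = _hochberg(np.asarray(ps))
    return out


# ---------------------------------------------------------------------------
# Clustering of HRD samples
# ---------------------------------------------------------------------------


def _impactful(call: GeneStatusCall) -> bool:
    """An impactful biallelic event: P-score pair of 5 and >= 3 (a deep
    deletion counts as a 5+5 pair)."""
    if call.has_deep_deletion:
        return True
    if call.event_a is None or call.event_b is None:
        return False
    pa, pb = call.p_a, call.p_b
    return max(pa, pb) == 5 and min(pa, pb) >= 3


def _cosmetic_rank(call: GeneStatusCall) -> int:
    """Display ordering within a gene block: deep deletion first, then
    LOH + frameshift, then LOH + other variant, then the rest."""
    if call.has_deep_deletion:
        return 0
    kinds = {e.kind for e in (call.event_a, call.event_b) if e is not None}
    if "loh" in kinds:
        var = next(
            (
                e
                for e in (call.event_a, call.event_b)
                if e is not None and e.kind == "variant"
            ),
            None,
        )
        if var is not None and var.variant is not None and var.variant.is_frameshift():
            return 1
        return 2
    return 3


def cluster_hrd_samples(
    subtypes: Mapping[str, str],
    gene_calls: Mapping[str, Mapping[str, GeneStatusCall]],
    priority: Sequence[str] = HRD_GENE_PRIORITY,
) -> pd.DataFrame:
    """Order HRD samples into gene-deficiency clusters.

    Samples are split four ways by subtype (BRCA2-type before BRCA1-type)
    and by whether an impactful biallelic event exists in any of the
    priority genes.  Within the impactful groups each sample is greedily
    assigned the priority gene with the highest BP-score (ties resolved by
    the priority order, which reflects deficiency enrichment strength);
    sorting the resulting 0/1 assignment matrix groups consecutive 1s into
    per-gene clusters, with deep deletions, LOH+frameshift, and LOH+other
    ranked first within a block for display.  Each non-impactful group
    forms a single "unknown cause" cluster.

    Returns a frame (sample, subtype, gene, cluster_id) in display order;
    the result is independent of input ordering.
    """
    prio_idx = {g: i for i, g in enumerate(priority)}
    records = []
    for sample in sorted(subtypes):
        subtype = subtypes[sample]
        calls = gene_calls.get(sample, {})
        impact_genes = [
            g for g in priority if g in calls and _impactful(calls[g])
        ]
        if impact_genes:
            assigned = max(
                impact_genes, key=lambda g: (calls[g].bp_score, -prio_idx[g])
            )
            rank = _cosmetic_rank(calls[assigned])
        else:
            assigned, rank = None, 3
        records.append((sample, subtype, assigned, rank))

    subtype_order = {"BRCA2-type": 0, "BRCA1-type": 1}
    ordered = sorted(
        records,
        key=lambda r: (
            subtype_order.get(r[1], 2),
            r[2] is None,  # impactful group first
            prio_idx.get(r[2], len(priority)),
            r[3],
            r[0],
        ),
    )

    rows = []
    cluster_id = 0
    prev_key: tuple | None = None
    for sample, subtype, gene, _ in ordered:
        key = (subtype, gene)
        if key != prev_key:
            cluster_id += 1
            prev_key = key
        rows.append(
            {
                "sample": sample,
                "subtype": subtype,
                "gene": gene if gene is not None else "unknown",
                "cluster_id": cluster_id,
            }
        )
    return pd.DataFrame(rows)
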