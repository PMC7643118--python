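"""Central configuration: every threshold used by the classifier pipeline.

All cutoffs default to the published values; they are collected here so a
re-calibration for a different variant-calling pipeline touches one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class Thresholds:
    """Numeric cutoffs of the HRD classification pipeline.

    Attributes
    ----------
    msi_repeat_indels : int
        A sample with strictly more repeat-region indels than this is
        flagged as microsatellite-instable (MSI).
    deep_deletion_cn : float
        A gene whose minimum total copy number is strictly below this is
        called deeply deleted.
    loh_minor_cn : float
        A gene whose minimum minor-allele copy number is strictly below
        this is called LOH.
    hrd_cutoff : float
        HRD call iff P(BRCA1-type) + P(BRCA2-type) >= cutoff.
    qc_min_indels : int
        Samples with fewer total indels fail QC.
    qc_min_svs : int
        HRD-predicted samples with fewer SVs fail QC.
    wilcoxon_alpha : float
        One-sided rank-sum significance level for feature selection.
    blacklist_hrd_frac / blacklist_hrp_frac : float
        Deficient-labelled samples predicted HRD in fewer than
        ``blacklist_hrd_frac`` of the nested-CV repeats, and proficient
        samples predicted HRD in more than ``blacklist_hrp_frac`` of them,
        are blacklisted (0.6/0.4 reproduce the <60 / >40 of 100 rule).
    germline_benign_freq : float
        Germline variants seen in more than this fraction of cohort
        germlines are pre-marked benign (P-score 0).
    sv_min_length : int
        SVs shorter than this (bp) are excluded from the SV contexts and
        from the QC SV count; the context bins start at 1 kb.
    """

    msi_repeat_indels: int = 14_000
    deep_deletion_cn: float = 0.3
    loh_minor_cn: float = 0.2
    hrd_cutoff: float = 0.5
    qc_min_indels: int = 50
    qc_min_svs: int = 30
    wilcoxon_alpha: float = 0.01
    blacklist_hrd_frac: float = 0.6
    blacklist_hrp_frac: float = 0.4
    germline_benign_freq: float = 0.01
    sv_min_length: int = 1_000

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ForestParams:
    """Random-forest hyperparameters (unspecified upstream; defaults here)."""

    n_trees: int = 500
    max_features: str = "sqrt"
    min_samples_leaf: int = 1

    def as_dict(self) -> dict:
        return asdict(self)


# Resampling grid explored when balancing the three training classes:
# down-sampling factors for the proficient ("none") class crossed with
# up-sampling factors for the (smallest) BRCA1 class, row-major order.
RESAMPLING_GRID: tuple[tuple[float, float], ...] = tuple(
    (down, up) for down in (1.0, 2.0, 4.0) for up in (1.0, 1.5, 2.0)
)

DEFAULT_THRESHOLDS = Thresholds()
DEFAULT_FOREST = ForestParams()
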