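"""Three-class random-forest HRD classifier.

The model predicts, per tumor, the probability of BRCA1-type deficiency,
BRCA2-type deficiency, or neither; the HRD probability is the sum of the two
deficiency probabilities and a sample is called HRD when it reaches the
cutoff (default 0.5).

Training pipeline
-----------------
1. *Feature selection*: keep features significantly higher in deficient
   (BRCA1 + BRCA2) than proficient samples by one-tailed rank-sum test
   (p < 0.01).
2. *Class resampling*: a grid search over down-sampling of the dominant
   "none" class (1x/2x/4x) crossed with up-sampling of the smallest
   "BRCA1" class (1x/1.5x/2x), scored by out-of-fold AUPRC of the HRD
   probability under 10-fold stratified CV; resampling is applied to
   training folds only so evaluation folds contain only original samples.
3. *Forest fit* on the resampled training set.

The full two-stage procedure additionally blacklists training samples whose
out-of-fold predictions repeatedly contradict their genetic label across
repeated 10-fold CV (deficient samples predicted HRD in <60% of repeats,
proficient samples in >40%), then re-runs the core training on the filtered
set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import (
    DEFAULT_FOREST,
    DEFAULT_THRESHOLDS,
    RESAMPLING_GRID,
    ForestParams,
    Thresholds,
)
from .contexts import MutationContextProfile, detect_msi

CLASSES = ("BRCA1", "BRCA2", "none")
HRD_CLASSES = ("BRCA1", "BRCA2")

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ResamplingParams:
    """Class-balance multipliers chosen by the grid search."""

    down_none: float = 1.0
    up_brca1: float = 1.0


@dataclass
class PredictionResult:
    """Per-sample classifier output."""

    sample: str
    p_brca1: float
    p_brca2: float
    p_none: float
    cutoff: float = 0.5
    qc_flags: frozenset = field(default_factory=frozenset)

    @property
    def p_hrd(self) -> float:
        return self.p_brca1 + self.p_brca2

    @property
    def call(self) -> str:
        return "HRD" if self.p_hrd >= self.cutoff else "HRP"

    @property
    def subtype(self) -> str:
        if self.call != "HRD":
            return "none"
        # exact tie goes to BRCA2-type, the majority deficiency class
        return "BRCA1-type" if self.p_brca1 > self.p_brca2 else "BRCA2-type"


def _check_labels(labels: pd.Series) -> None:
    bad = set(labels.unique()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}; expected {CLASSES}")


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def select_features_wilcoxon(
    features: pd.DataFrame,
    labels: pd.Series,
    alpha: float = DEFAULT_THRESHOLDS.wilcoxon_alpha,
) -> list[str]:
    """Features significantly *higher* in deficient (BRCA1+BRCA2) than in
    proficient samples by one-tailed Mann-Whitney rank-sum test.

    The exact null distribution is used for group sizes <= 10 (where the
    asymptotic approximation is poor); the tie-corrected normal
    approximation otherwise.
    """
    _check_labels(labels)
    deficient = features.loc[labels.isin(HRD_CLASSES).values]
    proficient = features.loc[(labels == "none").values]
    if len(deficient) == 0 or len(proficient) == 0:
        raise ValueError("both deficient and proficient samples are required")
    method = (
        "exact" if max(len(deficient), len(proficient)) <= 10 else "asymptotic"
    )
    selected = []
    for col in features.columns:
        x, y = deficient[col].values, proficient[col].values
        m = "asymptotic" if method == "exact" and _has_ties(x, y) else method
        p = mannwhitneyu(x, y, alternative="greater", method=m).pvalue
        if p < alpha:
            selected.append(col)
    return selected


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


# ---------------------------------------------------------------------------
# Resampling and the grid search
# ---------------------------------------------------------------------------


def _resample_index(
    labels: pd.Series, params: ResamplingParams, rng: np.random.Generator
) -> np.ndarray:
    """Positional indices of the resampled training set: the "none" class
    down-sampled without replacement by ``down_none``, the "BRCA1" class
    up-sampled with replacement to ``up_brca1`` times its size."""
    idx = np.arange(len(labels))
    lab = labels.values
    none_idx = idx[lab == "none"]
    b1_idx = idx[lab == "BRCA1"]
    b2_idx = idx[lab == "BRCA2"]
    n_none = max(1, int(round(len(none_idx) / params.down_none)))
    kept_none = rng.choice(none_idx, size=n_none, replace=False)
    n_b1 = int(round(len(b1_idx) * params.up_brca1))
    extra = rng.choice(b1_idx, size=max(0, n_b1 - len(b1_idx)), replace=True)
    out = np.concatenate([b1_idx, extra, b2_idx, kept_none])
    return np.sort(out)


def _fit_forest(
    X: pd.DataFrame,
    y: Sequence[str],
    forest: ForestParams,
    seed: int,
) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=forest.n_trees,
        max_features=forest.max_features,
        min_samples_leaf=forest.min_samples_leaf,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(X.values, np.asarray(y))
    return clf


def _hrd_probability(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    cols = [i for i, c in enumerate(clf.classes_) if c in HRD_CLASSES]
    return proba[:, cols].sum(axis=1)


def _oof_hrd_scores(
    features: pd.DataFrame,
    labels: pd.Series,
    params: ResamplingParams,
    folds: int,
    seed: int,
    forest: ForestParams,
    feature_subset: Sequence[str] | None = None,
    select_per_fold: bool = False,
    alpha: float = DEFAULT_THRESHOLDS.wilcoxon_alpha,
) -> np.ndarray:
    """Out-of-fold HRD probabilities under stratified CV with resampling
    (and optionally feature selection) restricted to training folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    scores = np.empty(len(features))
    for train_idx, test_idx in skf.split(features.values, labels.values):
        tr_X = features.iloc[train_idx]
        tr_y = labels.iloc[train_idx]
        if select_per_fold:
            cols = select_features_wilcoxon(tr_X, tr_y, alpha=alpha)
            if len(cols) < 2:
                cols = list(features.columns)
        else:
            cols = list(feature_subset or features.columns)
        res = _resample_index(tr_y, params, rng)
        clf = _fit_forest(
            tr_X[cols].iloc[res],
            tr_y.iloc[res].values,
            forest,
            seed,
        )
        scores[test_idx] = _hrd_probability(clf, features[cols].iloc[test_idx].values)
    return scores


def grid_search_resampling(
    features: pd.DataFrame,
    labels: pd.Series,
    grid: Iterable[tuple[float, float]] = RESAMPLING_GRID,
    cv_folds: int = 10,
    seed: int = 0,
    forest: ForestParams = DEFAULT_FOREST,
) -> ResamplingParams:
    """Pick the (down-sampling, up-sampling) pair with the highest pooled
    out-of-fold AUPRC for the combined HRD positive class; ties go to the
    first cell in row-major grid order."""
    _check_labels(labels)
    grid = list(grid)
    if not grid:
        raise ValueError("empty resampling grid")
    y_true = labels.isin(HRD_CLASSES).values.astype(int)
    best: tuple[float, ResamplingParams] | None = None
    for down, up in grid:
        params = ResamplingParams(down_none=down, up_brca1=up)
        scores = _oof_hrd_scores(features, labels, params, cv_folds, seed, forest)
        auprc = average_precision_score(y_true, scores)
        if best is None or auprc > best[0]:
            best = (auprc, params)
    return best[1]


# ---------------------------------------------------------------------------
# The trained model
# ---------------------------------------------------------------------------


@dataclass
class TrainedScarModel:
    """A fitted three-class forest with its selected features, resampling
    parameters, classification cutoff and training seed."""

    forest: RandomForestClassifier
    selected_features: list[str]
    resampling: ResamplingParams
    cutoff: float = DEFAULT_THRESHOLDS.hrd_cutoff
    seed: int = 0
    blacklist: list[str] = field(default_factory=list)

    def predict(
        self, features: pd.DataFrame | pd.Series
    ) -> list[PredictionResult]:
        return predict(self, features)

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.forest.feature_importances_, index=self.selected_features
        ).sort_values(ascending=False)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "forest": self.forest,
                "selected_features": self.selected_features,
                "resampling": (self.resampling.down_none, self.resampling.up_brca1),
                "cutoff": self.cutoff,
                "seed": self.seed,
                "blacklist": self.blacklist,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedScarModel":
        d = joblib.load(path)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        return cls(
            forest=d["forest"],
            selected_features=list(d["selected_features"]),
            resampling=ResamplingParams(*d["resampling"]),
            cutoff=d["cutoff"],
            seed=d["seed"],
            blacklist=list(d.get("blacklist", [])),
        )


def core_train(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    forest: ForestParams = DEFAULT_FOREST,
    grid: Iterable[tuple[float, float]] = RESAMPLING_GRID,
    cv_folds: int = 10,
) -> TrainedScarModel:
    """Feature selection -> resampling grid search -> forest fit on the
    resampled full training set."""
    _check_labels(labels)
    missing = set(CLASSES) - set(labels.unique())
    if missing:
        raise ValueError(f"training set lacks class(es) {sorted(missing)}")
    selected = select_features_wilcoxon(features, labels, thresholds.wilcoxon_alpha)
    if len(selected) < 2:
        raise ValueError(
            f"only {len(selected)} feature(s) passed selection; need >= 2"
        )
    params = grid_search_resampling(
        features[selected], labels, grid, cv_folds, seed, forest
    )
    rng = np.random.default_rng(seed)
    res = _resample_index(labels, params, rng)
    clf = _fit_forest(
        features[selected].iloc[res], labels.iloc[res].values, forest, seed
    )
    return TrainedScarModel(
        forest=clf,
        selected_features=selected,
        resampling=params,
        cutoff=thresholds.hrd_cutoff,
        seed=seed,
    )


def blacklist_samples(
    features: pd.DataFrame,
    labels: pd.Series,
    repeats: int = 100,
    folds: int = 10,
    seed: int = 0,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    forest: ForestParams = DEFAULT_FOREST,
    grid: Iterable[tuple[float, float]] = RESAMPLING_GRID,
) -> list[str]:
    """Samples whose out-of-fold HRD calls contradict their genetic label.

    The core training (per-fold feature selection + resampling) runs inside
    a ``folds``-fold CV loop repeated ``repeats`` times; per sample, the
    number of repeats in which its out-of-fold HRD probability reached the
    cutoff is counted.  Deficient-labelled samples called HRD in fewer than
    60% of the repeats, and "none" samples called HRD in more than 40%,
    are blacklisted.  The resampling parameter pair is chosen once by a
    grid search up front and held fixed across repeats.
    """
    if repeats <= 0:
        raise ValueError("repeats must be positive")
    _check_labels(labels)
    params = grid_search_resampling(features, labels, grid, folds, seed, forest)
    hrd_counts = np.zeros(len(features), dtype=int)
    for r in range(repeats):
        scores = _oof_hrd_scores(
            features,
            labels,
            params,
            folds,
            seed + r,
            forest,
            select_per_fold=True,
            alpha=thresholds.wilcoxon_alpha,
        )
        hrd_counts += (scores >= thresholds.hrd_cutoff).astype(int)
    lo = thresholds.blacklist_hrd_frac * repeats
    hi = thresholds.blacklist_hrp_frac * repeats
    deficient = labels.isin(HRD_CLASSES).values
    out = (deficient & (hrd_counts < lo)) | (~deficient & (hrd_counts > hi))
    return list(features.index[out])


def train_full(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    repeats: int = 100,
    folds: int = 10,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    forest: ForestParams = DEFAULT_FOREST,
    grid: Iterable[tuple[float, float]] = RESAMPLING_GRID,
) -> TrainedScarModel:
    """Two-stage training: blacklist inconsistently-predicted samples via
    repeated nested CV, then run the core training on the filtered set."""
    bad = blacklist_samples(
        features, labels, repeats, folds, seed, thresholds, forest, grid
    )
    keep = ~features.index.isin(bad)
    model = core_train(
        features.loc[keep],
        labels.loc[keep],
        seed,
        thresholds,
        forest,
        grid,
        cv_folds=folds,
    )
    model.blacklist = list(bad)
    return model


# ---------------------------------------------------------------------------
# Prediction, QC, evaluation
# ---------------------------------------------------------------------------


def predict(
    model: TrainedScarModel, features: pd.DataFrame | pd.Series
) -> list[PredictionResult]:
    """Apply a trained model; input rows must provide every selected
    feature (extra columns are ignored)."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    missing = [f for f in model.selected_features if f not in features.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    X = features[model.selected_features].values
    proba = model.forest.predict_proba(X)
    cols = {c: i for i, c in enumerate(model.forest.classes_)}
    out = []
    for name, row in zip(features.index, proba):
        out.append(
            PredictionResult(
                sample=str(name),
                p_brca1=float(row[cols["BRCA1"]]),
                p_brca2=float(row[cols["BRCA2"]]),
                p_none=float(row[cols["none"]]),
                cutoff=model.cutoff,
            )
        )
    return out


def apply_qc(
    profile: MutationContextProfile,
    prediction: PredictionResult,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> frozenset:
    """QC flags for one sample: ``MSI`` (repeat-indel hypermutation),
    ``LOW_INDEL`` (fewer than 50 indels), and ``LOW_SV`` (predicted HRD on
    fewer than 30 SVs).  An empty set means the prediction is reliable."""
    flags = set()
    if detect_msi(profile, thresholds):
        flags.add("MSI")
    if profile.n_indels() < thresholds.qc_min_indels:
        flags.add("LOW_INDEL")
    if prediction.call == "HRD" and profile.n_svs() < thresholds.qc_min_svs:
        flags.add("LOW_SV")
    return frozenset(flags)


def predictions_to_frame(
    predictions: Iterable[PredictionResult],
) -> pd.DataFrame:
    rows = [
        {
            "sample": p.sample,
            "p_BRCA1": p.p_brca1,
            "p_BRCA2": p.p_brca2,
            "p_none": p.p_none,
            "p_hrd": p.p_hrd,
            "hr_status": p.call,
            "hrd_type": p.subtype,
            "qc": ";".join(sorted(p.qc_flags)) or "PASS",
        }
        for p in predictions
    ]
    return pd.DataFrame(rows).set_index("sample")


def evaluate(
    predictions: Iterable[PredictionResult] | pd.DataFrame,
    truth: pd.Series,
    cutoff_grid: np.ndarray | None = None,
) -> dict:
    """AUROC, AUPRC and an F1-vs-cutoff curve for each prediction class
    (HRD, BRCA1-type, BRCA2-type) against genetic truth labels
    (BRCA1/BRCA2/none)."""
    if not isinstance(predictions, pd.DataFrame):
        predictions = predictions_to_frame(predictions)
    truth = truth.reindex(predictions.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some predicted samples")
    _check_labels(truth)
    if cutoff_grid is None:
        cutoff_grid = np.linspace(0.0, 1.0, 101)
    tasks = {
        "HRD": (predictions["p_hrd"].values, truth.isin(HRD_CLASSES).values),
        "BRCA1-type": (predictions["p_BRCA1"].values, (truth == "BRCA1").values),
        "BRCA2-type": (predictions["p_BRCA2"].values, (truth == "BRCA2").values),
    }
    metrics: dict = {}
    for name, (score, y) in tasks.items():
        if y.all() or not y.any():
            raise ValueError(f"truth for class {name} has a single value")
        f1 = pd.DataFrame(
            {
                "cutoff": cutoff_grid,
                "f1": [
                    f1_score(y, score >= c, zero_division=0.0)
                    for c in cutoff_grid
                ],
            }
        )
        metrics[name] = {
            "auroc": float(roc_auc_score(y, score)),
            "auprc": float(average_precision_score(y, score)),
            "f1_curve": f1,
        }
    return metrics
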