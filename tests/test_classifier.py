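"""Classifier machinery: rank-sum feature selection, resampling, the core
training loop, prediction semantics, QC gating, and evaluation metrics."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hrdscar import (
    MutationContextProfile,
    PredictionResult,
    ResamplingParams,
    TrainedScarModel,
    apply_qc,
    core_train,
    evaluate,
    grid_search_resampling,
    select_features_wilcoxon,
    simulate_cohort,
)
from hrdscar.classifier import _resample_index, predictions_to_frame
from hrdscar.config import ForestParams

FAST_FOREST = ForestParams(n_trees=60)


def rank_sum_exact_p(x, y):
    """One-sided (x > y) rank-sum p by full enumeration of group
    assignments; the independent oracle for small groups."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().values
    n = len(x)
    observed = ranks[:n].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)
    ]
    return np.mean([s >= observed for s in stats])


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def _toy_frame(deficient_vals, proficient_vals, name="f"):
    X = pd.DataFrame({name: np.concatenate([deficient_vals, proficient_vals])})
    y = pd.Series(
        ["BRCA2"] * len(deficient_vals) + ["none"] * len(proficient_vals)
    )
    return X, y


def test_complete_separation_is_selected_and_matches_exact_oracle():
    """All deficient values above all proficient with n=m=5: one-sided
    p = 1/252 < 0.01, so the feature is retained."""
    d = np.array([1.1, 1.2, 1.3, 1.4, 1.5])
    p = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
    assert rank_sum_exact_p(d, p) == pytest.approx(1 / 252)
    X, y = _toy_frame(d, p)
    assert select_features_wilcoxon(X, y) == ["f"]


def test_identical_distribution_not_selected():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=40)
    X, y = _toy_frame(vals[:20], vals[20:])
    assert select_features_wilcoxon(X, y) == []


def test_constant_feature_not_selected():
    X, y = _toy_frame(np.ones(8), np.ones(8))
    assert select_features_wilcoxon(X, y) == []


def test_lower_in_deficient_not_selected():
    """The test is one-tailed: enrichment in proficient samples must not
    select the feature."""
    X, y = _toy_frame(np.arange(5), np.arange(10, 15))
    assert select_features_wilcoxon(X, y) == []


def test_empty_group_errors():
    X = pd.DataFrame({"f": [1.0, 2.0]})
    with pytest.raises(ValueError):
        select_features_wilcoxon(X, pd.Series(["BRCA1", "BRCA2"]))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def test_resample_index_multipliers():
    labels = pd.Series(["BRCA1"] * 10 + ["BRCA2"] * 20 + ["none"] * 100)
    rng = np.random.default_rng(1)
    idx = _resample_index(labels, ResamplingParams(2.0, 1.5), rng)
    res = labels.iloc[idx]
    assert (res == "none").sum() == 50      # down-sampled 2x, no replacement
    assert (res == "BRCA1").sum() == 15     # up-sampled 1.5x with replacement
    assert (res == "BRCA2").sum() == 20
    none_positions = idx[res.values == "none"]
    assert len(set(none_positions)) == 50   # originals only


def test_grid_of_one_cell_returned():
    X, y = simulate_cohort(8, 8, 30, seed=2)
    params = grid_search_resampling(
        X, y, grid=[(4.0, 2.0)], cv_folds=3, seed=0, forest=FAST_FOREST
    )
    assert params == ResamplingParams(4.0, 2.0)


# ---------------------------------------------------------------------------
# Core training
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_model_and_data():
    X, y = simulate_cohort(15, 15, 60, seed=5)
    model = core_train(
        X, y, seed=5, forest=FAST_FOREST, grid=[(1.0, 1.0), (2.0, 1.0)],
        cv_folds=5,
    )
    return model, X, y


def test_core_train_recovers_hrd_signal(small_model_and_data):
    model, _, _ = small_model_and_data
    Xt, yt = simulate_cohort(10, 10, 40, seed=77)
    preds = model.predict(Xt)
    scores = np.array([p.p_hrd for p in preds])
    truth = yt.isin(["BRCA1", "BRCA2"]).values
    from sklearn.metrics import roc_auc_score

    assert roc_auc_score(truth, scores) >= 0.95
    assert "del.mh.bimh.2.5" in model.selected_features


def test_training_is_deterministic(small_model_and_data):
    model, X, y = small_model_and_data
    model2 = core_train(
        X, y, seed=5, forest=FAST_FOREST, grid=[(1.0, 1.0), (2.0, 1.0)],
        cv_folds=5,
    )
    p1 = predictions_to_frame(model.predict(X))
    p2 = predictions_to_frame(model2.predict(X))
    pd.testing.assert_frame_equal(p1, p2)


def test_model_persistence_round_trip(small_model_and_data, tmp_path):
    model, X, _ = small_model_and_data
    path = tmp_path / "model.joblib"
    model.save(path)
    reloaded = TrainedScarModel.load(path)
    p1 = predictions_to_frame(model.predict(X))
    p2 = predictions_to_frame(reloaded.predict(X))
    pd.testing.assert_frame_equal(p1, p2)


def test_single_class_training_errors():
    X, y = simulate_cohort(0, 0, 30, seed=1)
    with pytest.raises(ValueError):
        core_train(X, y, forest=FAST_FOREST)


def test_predict_missing_features_errors(small_model_and_data):
    model, X, _ = small_model_and_data
    with pytest.raises(ValueError, match="missing"):
        model.predict(X.drop(columns=model.selected_features[:1]))


# ---------------------------------------------------------------------------
# Prediction semantics
# ---------------------------------------------------------------------------


def test_hrd_probability_and_subtype_rules():
    p = PredictionResult("s", p_brca1=0.30, p_brca2=0.25, p_none=0.45)
    assert p.p_hrd == pytest.approx(0.55)
    assert p.call == "HRD"
    assert p.subtype == "BRCA1-type"


def test_cutoff_is_inclusive():
    p = PredictionResult("s", p_brca1=0.25, p_brca2=0.25, p_none=0.50)
    assert p.p_hrd == pytest.approx(0.5)
    assert p.call == "HRD"


def test_subtype_tie_goes_to_brca2():
    p = PredictionResult("s", p_brca1=0.3, p_brca2=0.3, p_none=0.4)
    assert p.subtype == "BRCA2-type"


def test_hrp_subtype_is_none():
    p = PredictionResult("s", p_brca1=0.1, p_brca2=0.1, p_none=0.8)
    assert p.call == "HRP" and p.subtype == "none"


def test_predicted_probabilities_sum_to_one(small_model_and_data):
    model, X, _ = small_model_and_data
    for p in model.predict(X.head(10)):
        assert p.p_brca1 + p.p_brca2 + p.p_none == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# QC gate
# ---------------------------------------------------------------------------


def _profile(n_indels=100, n_svs=50, n_rep=0):
    counts = {}
    if n_rep:
        counts["del.rep.len.1"] = n_rep
        n_indels = max(n_indels - n_rep, 0)
    counts["del.none.len.1"] = n_indels
    counts["DEL_1e03_1e04_bp"] = n_svs
    return MutationContextProfile(counts=counts)


HRD_PRED = PredictionResult("s", 0.4, 0.4, 0.2)
HRP_PRED = PredictionResult("s", 0.1, 0.1, 0.8)


@pytest.mark.parametrize(
    "profile, pred, expected",
    [
        (_profile(n_indels=49), HRP_PRED, {"LOW_INDEL"}),
        (_profile(n_indels=50), HRP_PRED, set()),
        (_profile(n_svs=0), HRP_PRED, set()),        # LOW_SV gated on HRD
        (_profile(n_svs=29), HRD_PRED, {"LOW_SV"}),
        (_profile(n_svs=30), HRD_PRED, set()),
        (_profile(n_rep=20_000), HRD_PRED, {"MSI"}),
    ],
)
def test_qc_flags(profile, pred, expected):
    assert set(apply_qc(profile, pred)) == expected


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _pred_frame(p_b1, p_b2, names=None):
    names = names or [f"s{i}" for i in range(len(p_b1))]
    preds = [
        PredictionResult(n, b1, b2, 1 - b1 - b2)
        for n, b1, b2 in zip(names, p_b1, p_b2)
    ]
    return predictions_to_frame(preds)


def test_perfect_separation_scores_one():
    frame = _pred_frame([0.45, 0.4, 0.05, 0.02], [0.45, 0.45, 0.05, 0.03])
    truth = pd.Series(["BRCA1", "BRCA2", "none", "none"], index=frame.index)
    m = evaluate(frame, truth)
    assert m["HRD"]["auroc"] == 1.0
    assert m["HRD"]["auprc"] == 1.0


def test_auroc_equals_pairwise_rank_statistic():
    """Trapezoidal AUROC equals the Mann-Whitney pair-counting form."""
    rng = np.random.default_rng(9)
    scores = rng.random(20)
    truth_bits = rng.random(20) < 0.4
    truth_bits[0], truth_bits[1] = True, False  # both classes present
    p_b2 = scores / 2
    frame = _pred_frame(list(scores / 2), list(p_b2))
    labels = pd.Series(
        np.where(truth_bits, "BRCA2", "none"), index=frame.index
    )
    labels.iloc[0] = "BRCA1"  # make all three classes appear
    try:
        m = evaluate(frame, labels)
    except ValueError:
        pytest.skip("degenerate draw")
    pos = frame["p_hrd"].values[labels.isin(["BRCA1", "BRCA2"]).values]
    neg = frame["p_hrd"].values[(labels == "none").values]
    pairs = [
        1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
    ]
    assert m["HRD"]["auroc"] == pytest.approx(np.mean(pairs))


def test_single_class_truth_errors():
    frame = _pred_frame([0.4, 0.5], [0.4, 0.4])
    truth = pd.Series(["BRCA1", "BRCA2"], index=frame.index)
    with pytest.raises(ValueError):
        evaluate(frame, truth)


def test_f1_curve_peaks_where_classes_split():
    frame = _pred_frame([0.4, 0.45, 0.1, 0.05], [0.4, 0.45, 0.1, 0.05])
    truth = pd.Series(["BRCA1", "BRCA2", "none", "none"], index=frame.index)
    m = evaluate(frame, truth)
    curve = m["HRD"]["f1_curve"]
    assert curve.loc[curve["cutoff"] == 0.5, "f1"].iloc[0] == 1.0
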