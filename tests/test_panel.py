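import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hdsheep.data_model import ValidationError
from hdsheep.panel import (
    MarkerFilterCriteria,
    PanelModel,
    _pairwise_auc,
    auc,
    auc_by_timepoint,
    fit_logistic,
    losocv_predictions,
    permutation_auc_test,
    pooled_cv_auc,
    preselect_markers,
    roc_curve,
    sensitivity_at_specificity,
    sheep_level_predictions,
    stepwise_build_panels,
)
from tests.conftest import make_cohort_table

ANN1 = pd.DataFrame(
    {
        "name": ["m"],
        "abbreviation": ["m"],
        "metabolite_class": "amino_acid",
        "lod": 0.0,
        "lloq": 0.001,
        "uloq": 1e9,
        "flags": "",
    }
)


def _ann(markers):
    return pd.DataFrame(
        {
            "name": markers,
            "abbreviation": markers,
            "metabolite_class": "amino_acid",
            "lod": 0.0,
            "lloq": 0.001,
            "uloq": 1e9,
            "flags": "",
        }
    )


# -- AUC -----------------------------------------------------------------------


def test_auc_examples():
    assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5
    # cases (0.9, 0.4), controls (0.5, 0.1): 3 of 4 pairs favorable
    assert auc([0.9, 0.4, 0.5, 0.1], [1, 1, 0, 0]) == 0.75


def test_auc_single_class_errors():
    with pytest.raises(ValidationError):
        auc([1, 2], [1, 1])


def test_auc_matches_pairwise_oracle_on_random_vectors():
    rng = np.random.default_rng(13)
    for _ in range(1000):
        n = int(rng.integers(4, 30))
        scores = rng.integers(0, 6, n).astype(float)  # heavy ties
        labels = np.zeros(n, dtype=int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.min() == labels.max():
            continue
        assert auc(scores, labels) == pytest.approx(_pairwise_auc(scores, labels), abs=1e-12)


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(14)
    scores = rng.normal(size=200)
    labels = (rng.random(200) < 0.4).astype(int)
    assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


# -- permutation test ------------------------------------------------------------


def _design_frame(sheep, genos):
    return pd.DataFrame({"sheep_id": sheep, "genotype": genos})


def test_permutation_null_metabolite_p_near_one():
    rng = np.random.default_rng(1)
    sheep = np.repeat([f"s{i}" for i in range(12)], 5)
    genos = np.repeat(["control"] * 6 + ["HD"] * 6, 5)
    values = np.tile(rng.normal(10, 1, 5), 12)  # identical pattern in both groups
    _, p = permutation_auc_test(
        values, _design_frame(sheep, genos), MarkerFilterCriteria(n_permutations=500)
    )
    assert p > 0.5


def test_permutation_p_matches_exhaustive_enumeration():
    """3+3 sheep: the sheep-level null has exactly C(6,3)=20 assignments."""
    rng = np.random.default_rng(2)
    sheep = np.repeat([f"s{i}" for i in range(6)], 4)
    genos = np.repeat(["control"] * 3 + ["HD"] * 3, 4)
    values = rng.normal(0, 1, 24) + 1.2 * (genos == "HD")
    criteria = MarkerFilterCriteria(n_permutations=20000, permutation_seed=9)
    observed, p = permutation_auc_test(values, _design_frame(sheep, genos), criteria)

    labels_by_sheep = {f"s{i}": values[sheep == f"s{i}"] for i in range(6)}
    null = []
    for hd_set in itertools.combinations(sorted(labels_by_sheep), 3):
        lab = np.concatenate(
            [np.full(4, int(s in hd_set)) for s in sorted(labels_by_sheep)]
        )
        vals = np.concatenate([labels_by_sheep[s] for s in sorted(labels_by_sheep)])
        a = _pairwise_auc(vals, lab)
        null.append(max(a, 1 - a))
    exact_q = np.mean([a >= observed - 1e-12 for a in null])
    assert p == pytest.approx(exact_q, abs=0.02)


def test_permutation_p_respects_add_one_bound():
    rng = np.random.default_rng(3)
    sheep = np.repeat([f"s{i}" for i in range(10)], 3)
    genos = np.repeat(["control"] * 5 + ["HD"] * 5, 3)
    values = rng.normal(0, 1, 30) + 10.0 * (genos == "HD")  # perfect separation
    criteria = MarkerFilterCriteria(n_permutations=200, permutation_seed=1)
    _, p = permutation_auc_test(values, _design_frame(sheep, genos), criteria)
    assert p >= 1.0 / 201.0


def test_permutation_requires_enough_assignments():
    sheep = np.repeat(["a", "b", "c", "d"], 2)
    genos = np.repeat(["control", "control", "HD", "HD"], 2)
    with pytest.raises(ValidationError, match="enumeration"):
        permutation_auc_test(np.arange(8.0), _design_frame(sheep, genos))


def test_permutation_reproducible_under_seed():
    rng = np.random.default_rng(8)
    sheep = np.repeat([f"s{i}" for i in range(12)], 3)
    genos = np.repeat(["control"] * 6 + ["HD"] * 6, 3)
    values = rng.normal(0, 1, 36)
    c = MarkerFilterCriteria(n_permutations=300, permutation_seed=77)
    r1 = permutation_auc_test(values, _design_frame(sheep, genos), c)
    r2 = permutation_auc_test(values, _design_frame(sheep, genos), c)
    assert r1 == r2


# -- preselection ------------------------------------------------------------------


def _screen_row(abbr, fdr, cmean, hmean):
    return {
        "abbreviation": abbr,
        "fdr_genotype": fdr,
        "control_mean": cmean,
        "hd_mean": hmean,
    }


def test_preselect_relative_difference_criterion():
    """Group means 164.49 vs 145.39 differ by ~11.6% (> 5%); equal means fail."""
    rng = np.random.default_rng(4)
    table = make_cohort_table(
        5,
        5,
        4,
        lambda si, g, t: [
            (145.39 if g == "HD" else 164.49) * (1 + 0.05 * rng.standard_normal()),
            10.0 * (1 + 0.05 * rng.standard_normal()),
        ],
        _ann(["Val", "flat"]),
    )
    results = pd.DataFrame(
        [
            _screen_row("Val", 0.001, 164.49, 145.39),
            _screen_row("flat", 0.001, 10.0, 10.0),
        ]
    )
    verdicts = preselect_markers(
        results, table, MarkerFilterCriteria(n_permutations=200, permutation_seed=1)
    ).set_index("abbreviation")
    assert verdicts.loc["Val", "relative_difference"] == pytest.approx(0.1161, abs=1e-3)
    assert bool(verdicts.loc["Val", "reldiff_pass"])
    assert not bool(verdicts.loc["flat", "reldiff_pass"])


def test_preselect_zero_control_mean_errors():
    table = make_cohort_table(5, 5, 2, lambda si, g, t: [1.0], ANN1)
    results = pd.DataFrame([_screen_row("m", 0.01, 0.0, 1.0)])
    with pytest.raises(ValidationError, match="control mean 0"):
        preselect_markers(results, table, MarkerFilterCriteria(n_permutations=100))


def test_preselect_separates_seeded_markers_from_nulls():
    """5 large-effect markers among 50 nulls: all 5 pass, most nulls fail."""
    rng = np.random.default_rng(11)
    markers = [f"eff{i}" for i in range(5)] + [f"null{i}" for i in range(50)]
    sheep_shift = {}

    def values(si, g, t):
        out = []
        for m in markers:
            base = 10.0 * (1.3 if (g == "HD" and m.startswith("eff")) else 1.0)
            key = (si, m)
            if key not in sheep_shift:
                sheep_shift[key] = rng.normal(0, 0.08)
            out.append(base * np.exp(sheep_shift[key] + rng.normal(0, 0.08)))
        return out

    table = make_cohort_table(8, 8, 6, values, _ann(markers))
    from hdsheep.diffstats import screen_metabolites

    screen = screen_metabolites(table)
    verdicts = preselect_markers(
        screen, table, MarkerFilterCriteria(n_permutations=300, permutation_seed=3)
    ).set_index("abbreviation")
    assert verdicts.loc[[f"eff{i}" for i in range(5)], "selected"].all()
    null_fail = (~verdicts.loc[[f"null{i}" for i in range(50)], "selected"]).mean()
    assert null_fail >= 0.9


# -- logistic regression -----------------------------------------------------------


def test_logistic_intercept_only_equals_logit_prevalence():
    y = np.array([1] * 14 + [0] * 10)
    fit = fit_logistic(np.empty((24, 0)), y)
    assert fit.coefficients[0] == pytest.approx(math.log(14 / 10), abs=1e-8)


def test_logistic_binary_feature_equals_log_odds_ratio():
    # 2x2 table: exposed 30 (20 cases), unexposed 30 (5 cases)
    x = np.array([1.0] * 30 + [0.0] * 30)
    y = np.array([1] * 20 + [0] * 10 + [1] * 5 + [0] * 25)
    fit = fit_logistic(x, y)
    log_or = math.log((20 * 25) / (10 * 5))
    assert fit.coefficients[1] == pytest.approx(log_or, abs=1e-6)
    assert fit.coefficients[0] == pytest.approx(math.log(5 / 25), abs=1e-6)


def test_logistic_duplication_invariance():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(40, 2))
    y = (rng.random(40) < 0.5).astype(int)
    y[0], y[1] = 0, 1
    f1 = fit_logistic(X, y)
    f2 = fit_logistic(np.vstack([X, X]), np.concatenate([y, y]))
    np.testing.assert_allclose(f1.coefficients, f2.coefficients, atol=1e-6)


def test_logistic_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(16)
    X = rng.normal(size=(120, 3))
    eta = 0.3 + X @ np.array([0.8, -0.5, 0.1])
    y = (rng.random(120) < 1 / (1 + np.exp(-eta))).astype(int)
    fit = fit_logistic(X, y)
    sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, sm_fit.params, atol=1e-6)
    assert not fit.separation_flagged


def test_logistic_flags_separation():
    x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
    y = np.array([0, 0, 0, 1, 1, 1])
    fit = fit_logistic(x, y)
    assert fit.separation_flagged


def test_logistic_rejects_nonfinite():
    with pytest.raises(ValidationError):
        fit_logistic(np.array([[1.0], [np.nan]]), np.array([0, 1]))


# -- LOSOCV ------------------------------------------------------------------------


def _signal_table(shift_sd=3.0, n_control=10, n_hd=14, timepoints=13, seed=0):
    rng = np.random.default_rng(seed)
    shifts = {}

    def values(si, g, t):
        if si not in shifts:
            shifts[si] = rng.normal(0, 0.5)
        mu = 10.0 + (shift_sd if g == "HD" else 0.0)
        return [mu + shifts[si] + rng.normal(0, 1.0)]

    return make_cohort_table(n_control, n_hd, timepoints, values, ANN1)


def test_losocv_one_prediction_per_study_sample():
    table = _signal_table()
    preds = losocv_predictions(table, ["m"])
    assert len(preds) == len(table.study_samples())
    assert preds["predicted_probability"].between(0, 1).all()
    assert preds["sheep_id"].nunique() == 24


def test_losocv_null_marker_never_beats_chance():
    """Pooled LOSOCV is pessimistic under the null (per-fold prevalence shift),
    so the null AUC must not exceed chance plus Monte-Carlo slack."""
    aucs = []
    for seed in range(30):
        table = _signal_table(shift_sd=0.0, n_control=5, n_hd=7, timepoints=5, seed=seed)
        aucs.append(pooled_cv_auc(losocv_predictions(table, ["m"])))
    assert np.mean(aucs) < 0.5 + 3 * np.std(aucs) / np.sqrt(len(aucs))


def test_losocv_strong_marker_high_auc():
    table = _signal_table(shift_sd=3.0)
    assert pooled_cv_auc(losocv_predictions(table, ["m"])) > 0.95


def test_losocv_imputes_missing_from_training_fold():
    table = _signal_table()
    table.values.iloc[0, 0] = np.nan
    preds = losocv_predictions(table, ["m"])
    assert preds["predicted_probability"].notna().all()


def test_losocv_requires_three_sheep_per_genotype():
    table = _signal_table(n_control=2, n_hd=5, timepoints=3)
    with pytest.raises(ValidationError, match="3 sheep"):
        losocv_predictions(table, ["m"])


def test_sheep_level_predictions_median():
    table = _signal_table(shift_sd=3.0)
    preds = losocv_predictions(table, ["m"])
    by_sheep = sheep_level_predictions(preds)
    assert len(by_sheep) == 24
    one = preds[preds["sheep_id"] == by_sheep["sheep_id"].iloc[0]]
    assert by_sheep["predicted_probability"].iloc[0] == pytest.approx(
        one["predicted_probability"].median()
    )


# -- stepwise ----------------------------------------------------------------------


def _multi_marker_table(n_null=10, seed=0):
    rng = np.random.default_rng(seed)
    markers = ["signal"] + [f"null{i}" for i in range(n_null)]
    shifts = {}

    def values(si, g, t):
        out = []
        for m in markers:
            key = (si, m)
            if key not in shifts:
                shifts[key] = rng.normal(0, 0.3)
            mu = 10.0 + (2.5 if (m == "signal" and g == "HD") else 0.0)
            out.append(max(mu + shifts[key] + rng.normal(0, 1.0), 0.01))
        return out

    return make_cohort_table(8, 8, 6, values, _ann(markers))


def test_stepwise_first_pick_is_informative_marker():
    for seed in range(3):
        table = _multi_marker_table(seed=seed)
        models = stepwise_build_panels(table, table.annotation["abbreviation"], max_size=4)
        assert models[0].markers == ["signal"]


def test_stepwise_step_auc_strictly_increasing():
    table = _multi_marker_table(seed=5)
    models = stepwise_build_panels(table, table.annotation["abbreviation"], max_size=6)
    seq = models[-1].step_auc
    assert all(b > a for a, b in zip(seq, seq[1:]))
    # all intermediate panels are returned, nested in order
    for k, m in enumerate(models, start=1):
        assert len(m.markers) == k
        assert m.markers == models[-1].markers[:k]


def test_stepwise_all_null_candidates_small_panel():
    rng = np.random.default_rng(30)
    markers = [f"null{i}" for i in range(5)]
    table = make_cohort_table(
        6, 6, 5, lambda si, g, t: list(rng.lognormal(2, 0.3, 5)), _ann(markers)
    )
    models = stepwise_build_panels(table, markers, max_size=5)
    assert len(models[-1].markers) <= 3


def test_panel_model_invariants():
    with pytest.raises(ValidationError):
        PanelModel(["a", "a"], np.zeros(3), [0.6], 0.6)
    with pytest.raises(ValidationError):
        PanelModel(["a", "b"], np.zeros(3), [0.7, 0.6], 0.6)


# -- operating points --------------------------------------------------------------


def _pred_frame(probs, genos):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(probs))],
            "sheep_id": [f"sh{i}" for i in range(len(probs))],
            "genotype": genos,
            "phase_bin": 0.0,
            "predicted_probability": probs,
        }
    )


def test_sensitivity_at_specificity_hand_example():
    controls = [0.05 * k for k in range(1, 11)]
    cases = [0.45, 0.55, 0.65, 0.75, 0.85]
    preds = _pred_frame(controls + cases, ["control"] * 10 + ["HD"] * 5)
    sens, thr = sensitivity_at_specificity(preds, 0.90)
    assert sens == pytest.approx(0.8)
    assert thr == pytest.approx(0.50)


def test_sensitivity_perfect_and_degenerate():
    perfect = _pred_frame([0.1, 0.2, 0.8, 0.9], ["control", "control", "HD", "HD"])
    assert sensitivity_at_specificity(perfect)[0] == 1.0
    constant = _pred_frame([0.5] * 6, ["control"] * 3 + ["HD"] * 3)
    assert sensitivity_at_specificity(constant, 0.9)[0] == 0.0


def test_sensitivity_target_out_of_range():
    preds = _pred_frame([0.1, 0.9], ["control", "HD"])
    with pytest.raises(ValidationError):
        sensitivity_at_specificity(preds, 1.0)


def test_roc_curve_monotone_and_area():
    rng = np.random.default_rng(17)
    probs = rng.random(60)
    genos = np.where(rng.random(60) < 0.5, "HD", "control")
    genos[:2] = ["HD", "control"]
    curve = roc_curve(probs, (genos == "HD").astype(int))
    assert np.all(np.diff(curve.sensitivity) >= 0)
    # trapezoidal area over (1-specificity, sensitivity) equals the AUC
    fpr = 1 - curve.specificity
    assert np.trapezoid(curve.sensitivity, fpr) == pytest.approx(curve.auc, abs=1e-12)


def test_auc_by_timepoint_matches_per_bin_pair_count():
    rng = np.random.default_rng(18)
    probs = rng.random(40)
    genos = np.array(["control", "HD"] * 20)
    preds = _pred_frame(probs, genos)
    preds["phase_bin"] = np.repeat([0.0, 2.0, 4.0, 6.0], 10)
    table = auc_by_timepoint(preds).set_index("phase_bin")
    for b in (0.0, 2.0, 4.0, 6.0):
        sel = preds["phase_bin"] == b
        want = _pairwise_auc(
            probs[sel.to_numpy()], (genos[sel.to_numpy()] == "HD").astype(int)
        )
        assert table.loc[b, "auc"] == pytest.approx(want, abs=1e-12)


def test_auc_by_timepoint_single_class_bin_reported_nan():
    preds = _pred_frame([0.1, 0.9, 0.5, 0.6], ["control", "HD", "control", "control"])
    preds["phase_bin"] = [0.0, 0.0, 2.0, 2.0]
    table = auc_by_timepoint(preds).set_index("phase_bin")
    assert np.isnan(table.loc[2.0, "auc"])
    assert table.loc[0.0, "auc"] == 1.0
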