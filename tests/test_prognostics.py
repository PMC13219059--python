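"""Outcome analytics: pair-counting oracles for AUC and C-index, closed-form
odds ratios and VIFs, hand-computed product-limit tables, DeLong behaviour,
bootstrap optimism direction, and the polynomial comparator contract."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from petmpi.prognostics import (
    ConvergenceError,
    SeparationError,
    auc_with_ci,
    bootstrap_optimism,
    calibration_by_decile,
    delong_auc_covariance,
    delong_compare,
    fit_cox,
    fit_logistic,
    km_median,
    likelihood_ratio,
    polynomial_comparator,
    univariable_screen,
    vif,
)


def brute_force_auc(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# AUC / DeLong


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_auc_equals_pair_counting(seed):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=40)
    y[:2] = [0, 1]  # both classes present
    x = np.round(rng.normal(size=40), 1)  # ties included
    auc, _ = auc_with_ci(x, y)
    assert auc == pytest.approx(brute_force_auc(x, y), abs=1e-12)


def test_brute_force_fixtures():
    aucs, _ = delong_auc_covariance(
        np.array([[0.9, 0.8, 0.2, 0.1], [0.9, 0.1, 0.8, 0.2]]),
        np.array([1, 1, 0, 0]),
    )
    assert aucs[0] == pytest.approx(1.0)
    assert aucs[1] == pytest.approx(0.5)


def test_delong_identical_predictions():
    rng = np.random.default_rng(4)
    y = np.array([1] * 10 + [0] * 10)
    pred = rng.normal(size=20)
    res = delong_compare(pred, pred, y)
    assert res.delta_auc == 0.0
    assert res.p_value == 1.0


def test_delong_symmetric_in_model_order():
    rng = np.random.default_rng(5)
    y = np.array([1] * 15 + [0] * 15)
    p1 = y + rng.normal(scale=1.0, size=30)
    p2 = y + rng.normal(scale=2.0, size=30)
    a = delong_compare(p1, p2, y)
    b = delong_compare(p2, p1, y)
    assert a.p_value == pytest.approx(b.p_value, rel=1e-12)
    assert a.delta_auc == pytest.approx(-b.delta_auc)


def test_delong_degenerate_variance_raises():
    y = np.array([1, 1, 0, 0])
    perfect = np.array([0.9, 0.8, 0.2, 0.1])
    also_perfect = np.array([0.95, 0.85, 0.1, 0.05])
    with pytest.raises(ValueError, match="degenerate"):
        delong_compare(perfect, also_perfect, y)


def test_delong_variance_close_to_jackknife_oracle():
    """On a 12-patient fixture the DeLong variance must agree with the
    leave-one-out jackknife variance of the AUC within 10%."""
    rng = np.random.default_rng(6)
    y = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
    x = y * 1.0 + rng.normal(scale=1.2, size=12)
    _, cov = delong_auc_covariance(x[None, :], y)
    loo = np.array(
        [brute_force_auc(np.delete(x, i), np.delete(y, i)) for i in range(12)]
    )
    jk_var = (11 / 12) * np.sum((loo - loo.mean()) ** 2)
    assert cov[0, 0] == pytest.approx(jk_var, rel=0.10)


def test_univariable_screen_contract(default_fm, default_outcomes):
    res = univariable_screen(default_fm, default_outcomes["dead_12mo"])
    assert res.shape[0] == default_fm.shape[1]
    assert ((res["auc"] >= 0) & (res["auc"] <= 1)).all()
    # identical-in-both-groups feature -> AUC 0.5, p ~ 1
    fm = default_fm.copy()
    fm["flat"] = 1.0
    fm["flat"] += np.where(np.arange(len(fm)) % 2, 0, 0)  # stays constant
    res2 = univariable_screen(fm[["flat"]].assign(flat=1.0), default_outcomes["dead_12mo"])
    assert res2.loc["flat", "auc"] == pytest.approx(0.5)
    assert res2.loc["flat", "p_value"] > 0.9


def test_univariable_screen_one_empty_group(default_fm):
    y = pd.Series(1, index=default_fm.index)
    with pytest.raises(ValueError, match="non-empty"):
        univariable_screen(default_fm, y)


# ---------------------------------------------------------------------------
# logistic regression


def test_two_by_two_odds_ratio_exact():
    # exposed: 8/10 events; unexposed: 2/10 -> OR = (8*8)/(2*2) = 16
    X = pd.DataFrame({"exposed": [1] * 10 + [0] * 10})
    y = pd.Series([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
    rep = fit_logistic(X, y)
    assert rep.coefficients.loc["exposed", "or_"] == pytest.approx(16.0, rel=1e-6)


def test_intercept_only_predicts_event_rate():
    y = pd.Series([1] * 13 + [0] * 7)
    rep = fit_logistic(pd.DataFrame(index=y.index), y)
    assert np.allclose(rep.predictions, 13 / 20, atol=1e-9)


def test_per_point_one_or_definition(default_fm, default_outcomes):
    from petmpi.trajectory import derive_mpi

    mpi = derive_mpi(default_fm, k=20).mpi
    X = pd.DataFrame({"MPI": mpi, "bone_met": default_outcomes["bone_met"]})
    rep = fit_logistic(X, default_outcomes["dead_12mo"])
    beta = rep.coefficients.loc["MPI", "coef"]
    assert rep.or_per_0p1["MPI"]["or"] == pytest.approx(np.exp(0.1 * beta), rel=1e-12)


def test_perfect_separation_raises():
    X = pd.DataFrame({"x": np.linspace(-2, 2, 30)})
    y = (X["x"] > 0).astype(int)
    with pytest.raises((SeparationError, ConvergenceError)):
        fit_logistic(X, y)


# ---------------------------------------------------------------------------
# likelihood ratio


def test_lrt_identical_models(default_fm, default_outcomes):
    y = default_outcomes["dead_12mo"]
    X = default_fm[["tMTV"]]
    a = fit_logistic(X, y, name="a")
    b = fit_logistic(X, y, name="b")
    res = likelihood_ratio(a, b)
    assert res.delta_deviance == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == 1.0


def test_lrt_non_nested_rejected(default_fm, default_outcomes):
    y = default_outcomes["dead_12mo"]
    a = fit_logistic(default_fm[["tMTV"]], y)
    b = fit_logistic(default_fm[["DmaxVox"]], y)
    with pytest.raises(ValueError, match="nested"):
        likelihood_ratio(a, b)


def test_lrt_grows_with_strong_predictor():
    rng = np.random.default_rng(7)
    deltas = []
    for n in (100, 400):
        x = rng.normal(size=n)
        y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-2 * x))).astype(int))
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
        small = fit_logistic(X[["noise"]], y)
        large = fit_logistic(X, y)
        deltas.append(likelihood_ratio(small, large).delta_deviance)
    assert deltas[1] > deltas[0] > 0


# ---------------------------------------------------------------------------
# bootstrap optimism and calibration


def test_optimism_null_model_near_zero(default_outcomes):
    y = default_outcomes["dead_12mo"]
    X = pd.DataFrame(index=y.index)
    rep = bootstrap_optimism(X, y, iterations=50, seed=0)
    assert abs(rep.optimism) < 0.02


def test_optimism_seeded_reproducibility(default_fm, default_outcomes):
    X = default_fm[["tMTV", "DmaxVox"]]
    y = default_outcomes["dead_12mo"]
    a = bootstrap_optimism(X, y, iterations=40, seed=9)
    b = bootstrap_optimism(X, y, iterations=40, seed=9)
    assert a == b


def test_overfit_model_corrected_below_apparent():
    rng = np.random.default_rng(8)
    n = 60
    X = pd.DataFrame(rng.normal(size=(n, 10)), columns=[f"n{i}" for i in range(10)])
    y = pd.Series(rng.integers(0, 2, size=n))
    rep = bootstrap_optimism(X, y, iterations=100, seed=1)
    assert rep.corrected_auc < rep.apparent_auc
    assert rep.optimism > 0.02


def test_calibration_counts_partition_cohort(default_fm, default_outcomes):
    y = default_outcomes["dead_12mo"]
    rep = fit_logistic(default_fm[["tMTV"]], y)
    cal = calibration_by_decile(rep.predictions, y)
    assert cal.table["count"].sum() == len(y)
    assert cal.table["mean_predicted"].is_monotonic_increasing


def test_calibration_constant_predictions_single_group(default_outcomes):
    y = default_outcomes["dead_12mo"]
    pred = pd.Series(0.5, index=y.index)
    cal = calibration_by_decile(pred, y)
    assert cal.n_groups == 1 and cal.collapsed


# ---------------------------------------------------------------------------
# survival


def test_km_median_ten_uncensored_times():
    res = km_median(np.arange(1.0, 11.0), np.ones(10, int))
    assert res.median == pytest.approx(5.0)
    assert res.reached


def test_km_all_censored_not_reached():
    res = km_median([5.0, 8.0, 9.0], [0, 0, 0])
    assert not res.reached
    assert np.isinf(res.median)


def test_km_mixed_censoring_hand_table():
    # times 1,2,3,4,5 events 1,0,1,1,0:
    # S(1)=4/5, S(3)=4/5*2/3=0.533, S(4)=0.267 -> median = 4
    res = km_median([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
    assert res.median == pytest.approx(4.0)
    assert res.n_events == 3


def test_cox_recovers_true_hazard_ratio():
    """Two-group exponential survival with true HR 2: the Wald CI must
    cover 2.0 in at least 8 of 10 seeded replicates."""
    cover = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 400
        grp = rng.integers(0, 2, size=n)
        t = rng.exponential(1.0 / (0.5 * 2.0**grp))
        rep = fit_cox(pd.DataFrame({"grp": grp}), t, np.ones(n, int))
        lo, hi = rep.coefficients.loc["grp", ["ci_low", "ci_high"]]
        cover += lo <= 2.0 <= hi
    assert cover >= 8


def test_cox_cindex_matches_pair_counting_without_censoring():
    rng = np.random.default_rng(11)
    n = 80
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.8 * x))
    rep = fit_cox(pd.DataFrame({"x": x}), t, np.ones(n, int))
    beta = rep.coefficients.loc["x", "coef"]
    risk = beta * x
    concordant, usable = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                continue
            usable += 1
            early, late = (i, j) if t[i] < t[j] else (j, i)
            if risk[early] > risk[late]:
                concordant += 1
            elif risk[early] == risk[late]:
                concordant += 0.5
    assert rep.c_index == pytest.approx(concordant / usable, abs=1e-9)


def test_cox_random_score_cindex_near_half():
    rng = np.random.default_rng(12)
    n = 500
    t = rng.exponential(size=n)
    rep = fit_cox(pd.DataFrame({"noise": rng.normal(size=n)}), t, np.ones(n, int))
    assert abs(rep.c_index - 0.5) < 0.05


def test_cox_requires_events():
    with pytest.raises(ValueError, match="two events"):
        fit_cox(pd.DataFrame({"x": [1.0, 2.0, 3.0]}), [1, 2, 3], [0, 0, 1])


def test_cox_per_point_one_hr(default_fm, default_outcomes):
    from petmpi.trajectory import derive_mpi

    mpi = derive_mpi(default_fm, k=20).mpi
    rep = fit_cox(
        pd.DataFrame({"MPI": mpi}),
        default_outcomes["time_months"],
        default_outcomes["event"],
    )
    beta = rep.coefficients.loc["MPI", "coef"]
    assert rep.hr_per_0p1["MPI"]["hr"] == pytest.approx(np.exp(0.1 * beta), rel=1e-12)


# ---------------------------------------------------------------------------
# VIF and the polynomial comparator


def test_vif_orthogonal_covariates_unity():
    rng = np.random.default_rng(13)
    n = 400
    X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
    v = vif(X)
    assert np.all(v < 1.1)


def test_vif_closed_form_for_correlated_pair():
    rng = np.random.default_rng(14)
    n = 20000
    rho = 0.8
    a = rng.normal(size=n)
    b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n)
    v = vif(pd.DataFrame({"a": a, "b": b}))
    assert v["a"] == pytest.approx(1 / (1 - rho**2), rel=0.05)


def test_vif_duplicate_covariate_infinite():
    rng = np.random.default_rng(15)
    a = rng.normal(size=50)
    v = vif(pd.DataFrame({"a": a, "dup": a, "c": rng.normal(size=50)}))
    assert np.isinf(v["a"]) and np.isinf(v["dup"])


def test_polynomial_comparator_zero_variance_errors(default_outcomes):
    y = default_outcomes["dead_12mo"]
    const = pd.Series(5.0, index=y.index)
    varying = pd.Series(np.linspace(0, 1, len(y)), index=y.index)
    with pytest.raises(ValueError, match="zero variance"):
        polynomial_comparator(const, varying, y)


def test_polynomial_comparator_squared_terms_null_when_link_linear():
    rng = np.random.default_rng(16)
    n = 4000
    t = rng.normal(size=n)
    d = rng.normal(size=n)
    lin = 0.8 * t + 0.5 * d
    y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-lin))).astype(int))
    rep = polynomial_comparator(pd.Series(t), pd.Series(d), y)
    assert abs(rep.coefficients.loc["tMTV_z2", "coef"]) < 0.1
    assert abs(rep.coefficients.loc["DmaxVox_z2", "coef"]) < 0.1
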