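"""Outcome analyses: 12-month mortality models and overall survival.

Contents
--------
* univariable screening of features against the binary endpoint
  (Mann-Whitney p, AUC with DeLong confidence interval);
* multivariable logistic regression (maximum likelihood via statsmodels),
  with odds ratios, Wald CIs, deviance and in-sample predictions; effects
  of covariates on a 0-1 scale are additionally reported per 0.1-unit
  increase as exp(0.1 * beta);
* paired DeLong comparison of correlated ROC AUCs (structural
  components);
* likelihood-ratio testing of nested logistic models;
* Harrell's bootstrap optimism correction of the apparent AUC;
* decile-grouped calibration;
* Kaplan-Meier median survival with log-log CI, Cox proportional-hazards
  regression (Efron ties) with Harrell's C-index (both via lifelines);
* variance inflation factors;
* a second-order polynomial comparator model in tumor burden (tMTV) and
  dissemination (DmaxVox).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index, median_survival_times
from scipy import stats


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ROC / DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_covariance(
    predictions: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for one or more correlated markers.

    ``predictions`` has shape (n_markers, n_subjects).  Uses the
    structural-component (placement value) formulation: for marker r,
    V10_i = P(score_i > score_j | j negative) over negatives j, and
    V01_j over positives; the covariance combines their empirical
    covariances scaled by the class sizes.
    """
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    pos = predictions[:, labels == 1]
    neg = predictions[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    k = predictions.shape[0]
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        combined = np.concatenate([pos[r], neg[r]])
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(combined)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v10[r] = (tz[:m] - tx) / n
        v01[r] = 1.0 - (tz[m:] - ty) / m
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10, ddof=1))
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01, ddof=1))
    cov = s10 / m + s01 / n
    return aucs, np.atleast_2d(cov)


def auc_with_ci(pred, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC and its DeLong Wald confidence interval."""
    aucs, cov = delong_auc_covariance(np.asarray(pred)[None, :], y)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = aucs[0] - z * se, aucs[0] + z * se
    return float(aucs[0]), (max(0.0, lo), min(1.0, hi))


@dataclass
class ROCComparison:
    auc1: float
    auc2: float
    delta_auc: float
    ci: tuple[float, float]
    p_value: float


def delong_compare(pred1, pred2, y, alpha: float = 0.05) -> ROCComparison:
    """Paired DeLong test for two correlated AUCs on the same patients."""
    pred1 = np.asarray(pred1, dtype=float)
    pred2 = np.asarray(pred2, dtype=float)
    if pred1.shape != pred2.shape:
        raise ValueError("prediction vectors must cover the same patients")
    aucs, cov = delong_auc_covariance(np.vstack([pred1, pred2]), y)
    delta = float(aucs[0] - aucs[1])
    if np.array_equal(pred1, pred2):
        # identical predictions: no evidence of a difference
        return ROCComparison(float(aucs[0]), float(aucs[1]), 0.0, (0.0, 0.0), 1.0)
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        raise ValueError(
            "degenerate DeLong variance (e.g. both AUCs 1.0); the test is undefined"
        )
    se = float(np.sqrt(var))
    z = delta / se
    p = float(2 * stats.norm.sf(abs(z)))
    q = stats.norm.ppf(1 - alpha / 2)
    return ROCComparison(
        auc1=float(aucs[0]),
        auc2=float(aucs[1]),
        delta_auc=delta,
        ci=(delta - q * se, delta + q * se),
        p_value=p,
    )


# ---------------------------------------------------------------------------
# univariable screening


def univariable_screen(
    features: pd.DataFrame, outcome: pd.Series
) -> pd.DataFrame:
    """Per-feature two-group comparison against a binary endpoint.

    Returns Mann-Whitney p, AUC = U / (n1 * n0) and its DeLong CI, plus
    group medians.  Requires both outcome groups non-empty.
    """
    y = outcome.loc[features.index].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        u_stat, p = stats.mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided")
        auc, ci = auc_with_ci(x, y)
        rows.append(
            {
                "feature": name,
                "median_event": float(np.median(x[y == 1])),
                "median_no_event": float(np.median(x[y == 0])),
                "p_value": float(p),
                "auc": auc,
                "auc_ci_low": ci[0],
                "auc_ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# logistic regression


@dataclass
class LogisticReport:
    name: str
    coefficients: pd.DataFrame  # coef, or_, ci_low, ci_high, p
    deviance: float
    llf: float
    n: int
    auc: float
    auc_ci: tuple[float, float]
    predictions: pd.Series
    covariates: list[str]
    or_per_0p1: dict = field(default_factory=dict)  # 0-1-scaled covariates


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    name: str = "model",
    per_0p1_covariates: tuple[str, ...] = ("MPI",),
) -> LogisticReport:
    """Maximum-likelihood logistic regression with Wald inference.

    ``per_0p1_covariates`` lists covariates on a 0-1 scale whose odds
    ratio is additionally reported per 0.1-unit increase as exp(0.1*beta).
    Perfect separation and non-convergence raise explicit errors.
    """
    X = pd.DataFrame(X)
    y_arr = y.loc[X.index].astype(float) if isinstance(y, pd.Series) else pd.Series(
        np.asarray(y, dtype=float), index=X.index
    )
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.GLM(y_arr, design, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # statsmodels PerfectSeparation or LinAlg
        raise SeparationError(f"{name}: logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise ConvergenceError(f"{name}: non-finite coefficients")
    big = res.params.drop("const", errors="ignore").abs()
    if (big > 30).any():
        culprit = big.idxmax()
        raise SeparationError(
            f"{name}: coefficient for {culprit!r} diverged; data are "
            "(quasi-)separated on that covariate"
        )
    conf = res.conf_int()
    coef = pd.DataFrame(
        {
            "coef": res.params,
            "or_": np.exp(res.params),
            "ci_low": np.exp(conf[0]),
            "ci_high": np.exp(conf[1]),
            "p_value": res.pvalues,
        }
    )
    pred = pd.Series(res.predict(design), index=X.index, name="predicted_risk")
    auc, auc_ci = (
        auc_with_ci(pred.to_numpy(), y_arr.to_numpy().astype(int))
        if X.shape[1] > 0 and 0 < y_arr.sum() < len(y_arr)
        else (0.5, (0.5, 0.5))
    )
    per01 = {}
    for cov in per_0p1_covariates:
        if cov in res.params.index:
            per01[cov] = {
                "or": float(np.exp(0.1 * res.params[cov])),
                "ci_low": float(np.exp(0.1 * conf.loc[cov, 0])),
                "ci_high": float(np.exp(0.1 * conf.loc[cov, 1])),
            }
    return LogisticReport(
        name=name,
        coefficients=coef,
        deviance=float(res.deviance),
        llf=float(res.llf),
        n=int(X.shape[0]),
        auc=auc,
        auc_ci=auc_ci,
        predictions=pred,
        covariates=list(X.columns),
        or_per_0p1=per01,
    )


@dataclass
class LikelihoodRatioResult:
    delta_deviance: float
    df: int
    p_value: float


def likelihood_ratio(small: LogisticReport, large: LogisticReport) -> LikelihoodRatioResult:
    """LRT of nested logistic models fitted to the same patients."""
    if small.n != large.n:
        raise ValueError("models were fitted on different patients")
    if not set(small.covariates) <= set(large.covariates):
        raise ValueError("models are not nested")
    delta = small.deviance - large.deviance
    df = len(large.covariates) - len(small.covariates)
    if df == 0:
        return LikelihoodRatioResult(0.0, 0, 1.0)
    p = float(stats.chi2.sf(max(delta, 0.0), df))
    return LikelihoodRatioResult(float(delta), df, p)


# ---------------------------------------------------------------------------
# internal validation


@dataclass
class OptimismReport:
    apparent_auc: float
    optimism: float
    corrected_auc: float
    bootstrap_ci: tuple[float, float]
    iterations: int
    n_failed: int


def bootstrap_optimism(
    X: pd.DataFrame,
    y: pd.Series,
    iterations: int = 1000,
    seed: int = 0,
    stratified: bool = True,
) -> OptimismReport:
    """Harrell's optimism-corrected AUC.

    Refit on each bootstrap resample (patient-level, stratified on outcome
    by default so both classes stay present); optimism is the mean of
    (resample AUC - AUC of the resample model evaluated on the original
    data); corrected = apparent - optimism.  More than 5% failed resample
    fits is an error.
    """
    X = pd.DataFrame(X).astype(float)
    y = pd.Series(y).loc[X.index].astype(int)
    apparent = fit_logistic(X, y, name="apparent")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(y))
    pos, neg = idx[y.to_numpy() == 1], idx[y.to_numpy() == 0]
    optimisms, boot_aucs = [], []
    n_failed = 0
    design_orig = sm.add_constant(X, has_constant="add")
    for _ in range(iterations):
        if stratified:
            take = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
        else:
            take = rng.choice(idx, len(idx))
        Xb, yb = X.iloc[take].reset_index(drop=True), y.iloc[take].reset_index(drop=True)
        try:
            rep = fit_logistic(Xb, yb, name="boot")
        except (SeparationError, ConvergenceError):
            n_failed += 1
            continue
        # resample model applied back to the original patients
        params = rep.coefficients["coef"]
        lin = design_orig.to_numpy() @ params.reindex(design_orig.columns).to_numpy()
        pred_orig = 1.0 / (1.0 + np.exp(-lin))
        auc_orig, _ = auc_with_ci(pred_orig, y.to_numpy())
        optimisms.append(rep.auc - auc_orig)
        boot_aucs.append(rep.auc)
    if n_failed > 0.05 * iterations:
        raise ConvergenceError(
            f"{n_failed}/{iterations} bootstrap fits failed to converge"
        )
    optimism = float(np.mean(optimisms))
    ci = tuple(np.percentile(boot_aucs, [2.5, 97.5]))
    return OptimismReport(
        apparent_auc=apparent.auc,
        optimism=optimism,
        corrected_auc=apparent.auc - optimism,
        bootstrap_ci=(float(ci[0]), float(ci[1])),
        iterations=iterations,
        n_failed=n_failed,
    )


@dataclass
class CalibrationTable:
    table: pd.DataFrame
    n_groups: int
    collapsed: bool


def calibration_by_decile(pred: pd.Series, y: pd.Series, n_bins: int = 10) -> CalibrationTable:
    """Grouped calibration over deciles of predicted risk.

    Ties may collapse deciles; the result is flagged rather than failed.
    """
    pred = pd.Series(pred).astype(float)
    y = pd.Series(y).loc[pred.index].astype(int)
    if len(pred) < 20:
        raise ValueError("calibration needs n >= 20")
    if pred.nunique() == 1:
        table = pd.DataFrame(
            {
                "bin_low": [pred.iloc[0]],
                "bin_high": [pred.iloc[0]],
                "mean_predicted": [pred.mean()],
                "observed_fraction": [y.mean()],
                "count": [len(y)],
            }
        )
        return CalibrationTable(table=table, n_groups=1, collapsed=True)
    bins = pd.qcut(pred, q=n_bins, duplicates="drop")
    grouped = pd.DataFrame({"pred": pred, "y": y, "bin": bins}).groupby(
        "bin", observed=True
    )
    table = grouped.agg(
        mean_predicted=("pred", "mean"),
        observed_fraction=("y", "mean"),
        count=("y", "size"),
    ).reset_index()
    table["bin_low"] = table["bin"].map(lambda iv: iv.left).astype(float)
    table["bin_high"] = table["bin"].map(lambda iv: iv.right).astype(float)
    table = table.drop(columns="bin")[
        ["bin_low", "bin_high", "mean_predicted", "observed_fraction", "count"]
    ]
    if int(table["count"].sum()) != len(y):
        raise AssertionError("calibration bins must partition the cohort")
    return CalibrationTable(
        table=table, n_groups=len(table), collapsed=len(table) < n_bins
    )


# ---------------------------------------------------------------------------
# survival


@dataclass
class KMResult:
    median: float  # np.inf when not reached
    ci: tuple[float, float]
    reached: bool
    n: int
    n_events: int


def km_median(time, event) -> KMResult:
    """Kaplan-Meier median survival with (log-log) confidence interval."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    median = float(kmf.median_survival_time_)
    ci_frame = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(v) for v in ci_frame.iloc[0])
    return KMResult(
        median=median,
        ci=(lo, hi),
        reached=np.isfinite(median),
        n=len(time),
        n_events=int(event.sum()),
    )


@dataclass
class CoxReport:
    name: str
    coefficients: pd.DataFrame  # coef, hr, ci_low, ci_high, p
    c_index: float
    n: int
    n_events: int
    hr_per_0p1: dict = field(default_factory=dict)


def fit_cox(
    X: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    name: str = "cox",
    per_0p1_covariates: tuple[str, ...] = ("MPI",),
) -> CoxReport:
    """Cox proportional-hazards fit (Efron tie handling) with Harrell's
    C-index computed on the fitted risk scores."""
    X = pd.DataFrame(X).astype(float)
    df = X.copy()
    df["time"] = np.asarray(time, dtype=float)
    df["event"] = np.asarray(event).astype(int)
    if df["event"].sum() < 2:
        raise ValueError("need at least two events")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    coef = pd.DataFrame(
        {
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "p_value": summary["p"],
        }
    )
    risk = cph.predict_partial_hazard(df)
    c_index = float(concordance_index(df["time"], -risk, df["event"]))
    per01 = {}
    for cov in per_0p1_covariates:
        if cov in summary.index:
            per01[cov] = {
                "hr": float(np.exp(0.1 * summary.loc[cov, "coef"])),
                "ci_low": float(np.exp(0.1 * summary.loc[cov, "coef lower 95%"])),
                "ci_high": float(np.exp(0.1 * summary.loc[cov, "coef upper 95%"])),
            }
    return CoxReport(
        name=name,
        coefficients=coef,
        c_index=c_index,
        n=len(df),
        n_events=int(df["event"].sum()),
        hr_per_0p1=per01,
    )


# ---------------------------------------------------------------------------
# collinearity and the comparator model


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    Exact collinearity is reported as infinity for the culprit covariate.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two covariates")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs n > number of covariates")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def polynomial_comparator(
    tmtv: pd.Series, dmax_vox: pd.Series, y: pd.Series, name: str = "polynomial"
) -> LogisticReport:
    """Logistic model with linear + squared terms of tumor burden and
    voxel-level dissemination (both z-scored before squaring)."""
    def z(v: pd.Series, label: str) -> pd.Series:
        v = pd.Series(v).astype(float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {label!r} has zero variance")
        return (v - v.mean()) / sd

    zt, zd = z(tmtv, "tMTV"), z(dmax_vox, "DmaxVox")
    X = pd.DataFrame(
        {"tMTV_z": zt, "DmaxVox_z": zd, "tMTV_z2": zt**2, "DmaxVox_z2": zd**2}
    )
    return fit_logistic(X, y, name=name, per_0p1_covariates=())
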