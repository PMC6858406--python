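"""Statistical primitives for prediction-equation development.

Forced-entry OLS with inference, semi-partial (part) correlation,
Durbin-Watson with tabulated 5% upper bounds, a Lilliefors-corrected
normality test, a quantitative homoscedasticity check, and the
difference-versus-mean (Bland-Altman style) trend test.

Conventions (documented, not universal):

* SEE = sqrt(SS_res / (n - p - 1)); standardised residuals are
  residual / SEE (not studentised).
* 95% CIs use the t distribution with n - p - 1 df.
* Durbin-Watson cases are taken in dataset row order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "CoefficientEstimate",
    "RegressionFit",
    "AgreementResult",
    "DurbinWatsonResult",
    "HomoscedasticityResult",
    "fit_ols",
    "semi_partial_correlation",
    "durbin_watson",
    "durbin_watson_verdict",
    "bland_altman_trend",
    "normality_test",
    "homoscedasticity_check",
    "adjusted_r2_from_see",
    "see_pct_of_mean",
]


@dataclass(frozen=True)
class CoefficientEstimate:
    name: str
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p_value: float


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit with the inference and fit statistics used downstream."""

    coefficients: tuple[CoefficientEstimate, ...]  # constant first
    r2: float
    adj_r2: float
    see_abs: float
    see_pct: float
    residuals: np.ndarray
    std_residuals: np.ndarray
    predictions: np.ndarray
    dw: float
    n_cases: int
    n_predictors: int

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.coefficients[1:])


def fit_ols(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    names: Sequence[str] | None = None,
) -> RegressionFit:
    """Forced-entry OLS of ``y`` on ``X`` plus an intercept.

    ``X`` holds the predictors only (no intercept column).  Raises on
    rank-deficient designs and on n <= p + 1.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = list(names) if names is not None else [f"x{i+1}" for i in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if yv.shape != (n,):
        raise ValueError("y and X have incompatible shapes")
    if n <= p + 1:
        raise ValueError(f"need more than p + 1 = {p + 1} cases, got {n}")
    if any(np.ptp(Xm[:, j]) == 0 for j in range(p)):
        raise ValueError("constant-valued predictor column")

    design = np.column_stack([np.ones(n), Xm])
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design matrix (collinear predictors)")

    beta, *_ = np.linalg.lstsq(design, yv, rcond=None)
    predictions = design @ beta
    residuals = yv - predictions
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    df_resid = n - p - 1
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    see_abs = math.sqrt(ss_res / df_resid)
    mean_y = float(yv.mean())
    see_pct = 100.0 * see_abs / mean_y if mean_y != 0 else math.nan
    std_residuals = residuals / see_abs if see_abs > 0 else np.zeros(n)

    cov = np.linalg.inv(design.T @ design) * see_abs**2
    se = np.sqrt(np.diag(cov))
    tcrit = stats.t.ppf(0.975, df_resid)
    coefficients = []
    for j, name in enumerate(["constant", *names]):
        b = float(beta[j])
        sj = float(se[j])
        if sj > 0:
            tval = b / sj
            pval = float(2.0 * stats.t.sf(abs(tval), df_resid))
        else:  # degenerate (noiseless) fit
            pval = 0.0 if b != 0 else 1.0
        coefficients.append(
            CoefficientEstimate(
                name=name,
                beta=b,
                se=sj,
                ci95_low=b - tcrit * sj,
                ci95_high=b + tcrit * sj,
                p_value=pval,
            )
        )

    return RegressionFit(
        coefficients=tuple(coefficients),
        r2=r2,
        adj_r2=adj_r2,
        see_abs=see_abs,
        see_pct=see_pct,
        residuals=residuals,
        std_residuals=std_residuals,
        predictions=predictions,
        dw=durbin_watson(residuals) if ss_res > 0 else math.nan,
        n_cases=n,
        n_predictors=p,
    )


def semi_partial_correlation(
    y: Sequence[float], X: pd.DataFrame, target: str
) -> float:
    """Semi-partial (part) correlation of ``target`` with ``y``.

    The target predictor is residualised on the remaining columns of ``X``;
    the result is the Pearson correlation of ``y`` with that residual.  With
    a single column this reduces to the plain Pearson correlation.
    """
    if target not in X.columns:
        raise ValueError(f"target {target!r} not among predictors")
    yv = np.asarray(y, dtype=float)
    t = X[target].to_numpy(dtype=float)
    others = X.drop(columns=[target])
    if others.shape[1] == 0:
        return float(stats.pearsonr(yv, t)[0])
    n = len(yv)
    if n <= X.shape[1] + 1:
        raise ValueError("too few cases for the partialling set")
    design = np.column_stack([np.ones(n), others.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank deficiency among the partialling set")
    coef, *_ = np.linalg.lstsq(design, t, rcond=None)
    resid = t - design @ coef
    if np.allclose(resid, 0.0):
        raise ValueError(
            f"predictor {target!r} is perfectly collinear with the partialling set"
        )
    return float(stats.pearsonr(yv, resid)[0])


def durbin_watson(residuals: Sequence[float]) -> float:
    """Durbin-Watson d = sum (e_t - e_{t-1})^2 / sum e_t^2 for ordered residuals."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 residuals")
    denom = float(e @ e)
    if denom == 0:
        raise ValueError("all-zero residuals: d undefined")
    return float(np.sum(np.diff(e) ** 2) / denom)


# 5% significance points of dL/dU (Savin & White 1977), k = number of
# regressors excluding the intercept.  Values outside the table fall back to
# the nearest tabulated n (and k clipped to 2) with a warning.
_DW_BOUNDS_5PCT: dict[int, dict[int, tuple[float, float]]] = {
    1: {
        6: (0.610, 1.400), 7: (0.700, 1.356), 8: (0.763, 1.332),
        9: (0.824, 1.320), 10: (0.879, 1.320), 11: (0.927, 1.324),
        12: (0.971, 1.331), 13: (1.010, 1.340), 14: (1.045, 1.350),
        15: (1.077, 1.361), 16: (1.106, 1.371), 17: (1.133, 1.381),
        18: (1.158, 1.391), 19: (1.180, 1.401), 20: (1.201, 1.411),
    },
    2: {
        7: (0.467, 1.896), 8: (0.559, 1.777), 9: (0.629, 1.699),
        10: (0.697, 1.641), 11: (0.758, 1.604), 12: (0.812, 1.579),
        13: (0.861, 1.562), 14: (0.905, 1.551), 15: (0.946, 1.543),
        16: (0.982, 1.539), 17: (1.015, 1.536), 18: (1.046, 1.535),
        19: (1.074, 1.536), 20: (1.100, 1.537),
    },
}


@dataclass(frozen=True)
class DurbinWatsonResult:
    d: float
    n: int
    k: int
    du: float
    passed: bool
    degenerate: bool = False
    note: str = ""


def durbin_watson_verdict(
    residuals: Sequence[float], k: int, alpha: float = 0.05
) -> DurbinWatsonResult:
    """Durbin-Watson statistic plus a pass verdict against tabulated dU.

    Pass when d exceeds the 5% upper bound dU(n, k).  All-zero residuals
    (a noiseless fit) are degenerate: reported as pass-with-flag.
    """
    if alpha != 0.05:
        raise ValueError("only 5% bounds are tabulated")
    e = np.asarray(residuals, dtype=float)
    n = int(e.size)
    if float(e @ e) == 0:
        return DurbinWatsonResult(
            d=math.nan, n=n, k=k, du=math.nan, passed=True,
            degenerate=True, note="all-zero residuals; d undefined",
        )
    d = durbin_watson(e)
    k_used = min(max(k, 1), 2)
    table = _DW_BOUNDS_5PCT[k_used]
    n_used = min(max(n, min(table)), max(table))
    note = ""
    if k_used != k or n_used != n:
        note = f"bounds for n={n_used}, k={k_used} used (requested n={n}, k={k})"
        warnings.warn("Durbin-Watson n/k outside table; " + note, stacklevel=2)
    du = table[n_used][1]
    return DurbinWatsonResult(d=d, n=n, k=k, du=du, passed=d > du, note=note)


@dataclass(frozen=True)
class AgreementResult:
    """Difference-versus-mean agreement between criterion and model values."""

    mean_of_methods: np.ndarray
    residuals: np.ndarray  # criterion - model
    trend_r: float
    trend_p: float
    systematic_error: bool
    degenerate: bool = False


def bland_altman_trend(
    criterion: Sequence[float], model: Sequence[float]
) -> AgreementResult:
    """Trend of (criterion - model) differences against the pairwise means.

    A significant Pearson correlation (two-sided p < 0.05) flags
    proportional systematic error.  Zero-variance differences are reported
    as no-trend with a degenerate flag.
    """
    c = np.asarray(criterion, dtype=float)
    m = np.asarray(model, dtype=float)
    if c.shape != m.shape or c.ndim != 1:
        raise ValueError("criterion and model must be paired 1-D sequences")
    if c.size < 4:
        raise ValueError("need at least 4 pairs")
    residuals = c - m
    means = (c + m) / 2.0
    if np.ptp(residuals) == 0 or np.ptp(means) == 0:
        return AgreementResult(
            mean_of_methods=means, residuals=residuals,
            trend_r=0.0, trend_p=1.0, systematic_error=False, degenerate=True,
        )
    r, p = stats.pearsonr(means, residuals)
    return AgreementResult(
        mean_of_methods=means, residuals=residuals,
        trend_r=float(r), trend_p=float(p), systematic_error=bool(p < 0.05),
    )


def normality_test(values: Sequence[float], method: str = "lilliefors") -> float:
    """P-value of a normality test with estimated mean and SD.

    ``lilliefors`` (default) is the Kolmogorov-Smirnov statistic with the
    Lilliefors small-sample correction; ``shapiro`` is available as an
    alternative.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(v) == 0:
        raise ValueError("constant input: normality undefined")
    if method == "lilliefors":
        return float(lilliefors(v, dist="norm")[1])
    if method == "shapiro":
        return float(stats.shapiro(v)[1])
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class HomoscedasticityResult:
    r: float
    p: float
    passed: bool
    degenerate: bool = False


def homoscedasticity_check(fit: RegressionFit) -> HomoscedasticityResult:
    """Quantitative surrogate for the residual-versus-prediction plot.

    Correlates |standardised residual| with the standardised prediction;
    pass when the two-sided p-value is >= 0.05 (no trend).  Constant
    residuals are degenerate and pass with a flag.
    """
    if fit.n_cases < 5:
        raise ValueError("need at least 5 cases")
    abs_resid = np.abs(fit.std_residuals)
    preds = fit.predictions
    # a (near-)noiseless fit leaves only float dust in the residuals
    noiseless = fit.see_abs <= 1e-9 * (np.abs(preds).mean() + preds.std())
    if noiseless or np.ptp(abs_resid) == 0 or np.ptp(preds) == 0:
        return HomoscedasticityResult(r=0.0, p=1.0, passed=True, degenerate=True)
    z_pred = (preds - preds.mean()) / preds.std(ddof=1)
    r, p = stats.pearsonr(z_pred, abs_resid)
    return HomoscedasticityResult(r=float(r), p=float(p), passed=bool(p >= 0.05))


def adjusted_r2_from_see(see_abs: float, sd_y: float) -> float:
    """Adjusted R^2 implied by the SEE and the outcome SD: 1 - SEE^2/SD^2.

    Exact under the shared n - p - 1 degrees-of-freedom convention.
    """
    if sd_y <= 0:
        raise ValueError("outcome SD must be positive")
    return 1.0 - (see_abs / sd_y) ** 2


def see_pct_of_mean(see_abs: float, mean_y: float) -> float:
    """SEE (or any residual summary) as a percentage of a reference mean."""
    if mean_y == 0:
        raise ValueError("reference mean must be non-zero")
    return 100.0 * see_abs / mean_y
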