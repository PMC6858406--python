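"""End-to-end development of a muscle-group volume prediction equation.

Stages, in order: outlier exclusion (largest-|z| removal until the group
volumes test normal, capped), semi-partial screening of candidate
predictors with a collinearity rule and a one-predictor-per-15-cases cap,
a reproducible 80/20 split, leave-one-out candidate retention, a final
forced-entry fit on the development set, a seven-criterion diagnostic
battery, holdout cross-validation residuals, and a difference-versus-mean
agreement check over all cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import regression as reg

__all__ = [
    "PipelineConfig",
    "ScreeningResult",
    "DiagnosticsReport",
    "DevelopedModel",
    "PipelineError",
    "DEFAULT_CANDIDATES",
    "add_composite_predictors",
    "exclude_outliers",
    "screen_variables",
    "split_sample",
    "loo_candidate_selection",
    "evaluate_diagnostics",
    "develop_model",
    "compare_models",
]


class PipelineError(RuntimeError):
    """Stage-labelled failure inside the development pipeline."""


class PipelineConfig(BaseModel):
    """Tunable thresholds; defaults follow the published procedure."""

    alpha: float = Field(default=0.05, gt=0, lt=1)
    holdout_fraction: float = Field(default=0.2, gt=0, le=0.5)
    max_outlier_removals: int = Field(default=2, ge=0)
    cases_per_predictor: int = Field(default=15, ge=2)
    collinearity_r: float = 0.80
    r2_gap: float = 0.10
    std_residual_bound: float = 2.00
    semi_partial_gap: float = 0.20
    normality_method: str = "lilliefors"
    # advisory practicality weights for criterion 7 (higher = easier to acquire)
    practicality_weights: dict[str, float] = Field(default_factory=dict)


#: Composite predictor columns the screening roster expects; each is the
#: product of two measurement columns.
COMPOSITE_PREDICTORS: dict[str, tuple[str, str]] = {
    "body_mass_x_thigh_length": ("body_mass_kg", "thigh_length_m"),
    "mt_anterior_thigh_50_x_body_mass": ("mt_anterior_thigh_50_cm", "body_mass_kg"),
    "mt_biceps_femoris_sh_75_x_thigh_length": (
        "mt_biceps_femoris_sh_75_cm",
        "thigh_length_m",
    ),
    "csa_lateral_gastroc_25_x_body_mass": (
        "csa_lateral_gastroc_25_cm2",
        "body_mass_kg",
    ),
}

#: Default candidate rosters per muscle group (anthropometrics plus the
#: composite ultrasound/anthropometric products; configuration, not dogma).
DEFAULT_CANDIDATES: dict[str, tuple[str, ...]] = {
    "hip_extensors": (
        "body_mass_x_thigh_length",
        "mt_hip_cm",
        "height_m",
    ),
    "knee_extensors": (
        "mt_anterior_thigh_50_x_body_mass",
        "mt_anterior_thigh_50_cm",
        "height_m",
    ),
    "knee_flexors": (
        "mt_biceps_femoris_sh_75_x_thigh_length",
        "mt_biceps_femoris_sh_75_cm",
        "height_m",
    ),
    "ankle_plantarflexors": (
        "csa_lateral_gastroc_25_x_body_mass",
        "csa_lateral_gastroc_25_cm2",
        "height_m",
    ),
}


def add_composite_predictors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the product predictor columns appended (if absent)."""
    out = cohort.copy()
    for name, (a, b) in COMPOSITE_PREDICTORS.items():
        if name not in out.columns and a in out.columns and b in out.columns:
            out[name] = out[a] * out[b]
    return out


def exclude_outliers(
    values: Sequence[float],
    max_removals: int = 2,
    alpha: float = 0.05,
    method: str = "lilliefors",
) -> tuple[list[int], list[int], dict]:
    """Remove extreme cases until the sample tests normal, up to a cap.

    While the normality p-value is below ``alpha`` and fewer than
    ``max_removals`` cases were removed, drop the case farthest (in |z|)
    from the current mean.  Returns (retained indices, removed indices,
    evidence dict).  A sample still non-normal after the cap is kept with a
    warning flag rather than rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 6:
        raise ValueError("need at least 6 cases for outlier screening")
    retained = list(range(v.size))
    removed: list[int] = []
    p_history = []
    while True:
        p = reg.normality_test(v[retained], method=method)
        p_history.append(p)
        if p >= alpha or len(removed) >= max_removals:
            break
        sub = v[retained]
        z = np.abs(sub - sub.mean()) / sub.std(ddof=1)
        worst = retained[int(np.argmax(z))]
        removed.append(worst)
        retained.remove(worst)
    evidence = {
        "p_history": p_history,
        "final_p": p_history[-1],
        "still_non_normal": p_history[-1] < alpha,
    }
    return retained, removed, evidence


@dataclass(frozen=True)
class ScreeningResult:
    candidates: tuple[tuple[str, float], ...]  # (name, semi-partial r), ranked
    retained: tuple[str, ...]
    excluded: tuple[tuple[str, str], ...]  # (name, reason)
    max_predictors: int


def screen_variables(
    cohort: pd.DataFrame,
    group: str,
    candidates: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
) -> ScreeningResult:
    """Rank candidates by |semi-partial correlation| with the group volume.

    Candidates perfectly collinear with the rest of the roster are ranked by
    plain Pearson correlation instead (flagged).  Pairs correlated beyond
    the collinearity threshold keep only the stronger member, and the
    retained count is capped at floor(n / cases_per_predictor), minimum 1.
    """
    config = config or PipelineConfig()
    candidates = tuple(candidates or DEFAULT_CANDIDATES[group])
    mv_col = f"mv_{group}_cm3"
    missing = [c for c in (*candidates, mv_col) if c not in cohort.columns]
    if missing:
        raise PipelineError(f"screen_variables: missing columns {missing}")
    y = cohort[mv_col].to_numpy(dtype=float)
    X = cohort[list(candidates)]

    scored: list[tuple[str, float]] = []
    for name in candidates:
        try:
            r = reg.semi_partial_correlation(y, X, name)
        except ValueError:
            from scipy.stats import pearsonr

            r = float(pearsonr(y, X[name].to_numpy(dtype=float))[0])
        scored.append((name, r))
    scored.sort(key=lambda t: abs(t[1]), reverse=True)

    max_predictors = max(1, len(y) // config.cases_per_predictor)
    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    corr = cohort[list(candidates)].corr()
    for name, r in scored:
        clash = next(
            (k for k in retained if abs(corr.loc[name, k]) > config.collinearity_r),
            None,
        )
        if clash is not None:
            excluded.append((name, f"collinear with {clash} (|r| > {config.collinearity_r})"))
        elif len(retained) >= max_predictors:
            excluded.append((name, "over the 1-predictor-per-15-cases cap"))
        else:
            retained.append(name)
    return ScreeningResult(
        candidates=tuple(scored),
        retained=tuple(retained),
        excluded=tuple(excluded),
        max_predictors=max_predictors,
    )


def split_sample(
    cohort: pd.DataFrame, holdout_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random development/validation split, round-half-up holdout size.

    round-half-up gives holdout 3 of 17 and 4 of 18 at fraction 0.2.
    """
    if not 0 < holdout_fraction <= 0.5:
        raise ValueError("holdout_fraction must be in (0, 0.5]")
    n = len(cohort)
    if n < 5:
        raise ValueError("need at least 5 cases to split")
    n_holdout = int(math.floor(n * holdout_fraction + 0.5))
    n_holdout = max(1, n_holdout)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    holdout_idx = np.sort(order[:n_holdout])
    dev_idx = np.sort(order[n_holdout:])
    return cohort.iloc[dev_idx], cohort.iloc[holdout_idx]


def loo_candidate_selection(
    dev: pd.DataFrame,
    group: str,
    candidates: Sequence[str],
    alpha: float = 0.05,
) -> tuple[tuple[str, ...], list[dict]]:
    """Leave-one-out stability screen for forced-entry candidates.

    For each left-out case the remaining cases are refit with all
    candidates entered; a candidate counts as present in that fold when its
    p-value is below ``alpha`` and its 95% CI excludes zero.  Only
    candidates present in every fold are retained.
    """
    candidates = list(candidates)
    mv_col = f"mv_{group}_cm3"
    n = len(dev)
    if n < len(candidates) + 3:
        raise PipelineError(
            f"loo_candidate_selection: development set of {n} too small for "
            f"{len(candidates)} candidates"
        )
    present_in_all = {c: True for c in candidates}
    fold_reports: list[dict] = []
    for i in range(n):
        sub = dev.drop(dev.index[i])
        fit = reg.fit_ols(sub[mv_col].to_numpy(dtype=float), sub[candidates])
        fold = {}
        for coef in fit.coefficients[1:]:
            ok = coef.p_value < alpha and not (coef.ci95_low <= 0 <= coef.ci95_high)
            fold[coef.name] = {
                "p": coef.p_value,
                "ci": (coef.ci95_low, coef.ci95_high),
                "present": ok,
            }
            if not ok:
                present_in_all[coef.name] = False
        fold_reports.append(fold)
    retained = tuple(c for c in candidates if present_in_all[c])
    return retained, fold_reports


@dataclass(frozen=True)
class Criterion:
    id: int
    description: str
    passed: bool
    evidence: dict
    advisory: bool = False


@dataclass(frozen=True)
class DiagnosticsReport:
    criteria: tuple[Criterion, ...]
    overall_pass: bool  # AND of criteria 1-6; criterion 7 is advisory

    def criterion(self, cid: int) -> Criterion:
        return next(c for c in self.criteria if c.id == cid)


def evaluate_diagnostics(
    fit: reg.RegressionFit,
    dev: pd.DataFrame,
    group: str,
    config: PipelineConfig | None = None,
) -> DiagnosticsReport:
    """Seven-criterion suitability battery for a fitted model.

    1. Generalisation: all 95% CIs exclude zero, at most one standardised
       residual beyond +/-2.00, and R^2 - adjusted R^2 within the gap.
    2. All coefficient p-values below alpha.
    3. No predictor pair correlated beyond the collinearity threshold.
    4. Semi-partial correlations of the predictors similar (vacuous for one).
    5. No |standardised residual| trend against standardised predictions.
    6. Durbin-Watson above the tabulated upper bound and residuals normal.
    7. Practicality of acquisition (advisory; config weights, not a gate).
    A noiseless fit (SEE ~ 0) makes the residual-based checks degenerate;
    they pass with a flag.
    """
    config = config or PipelineConfig()
    mv_col = f"mv_{group}_cm3"
    y = dev[mv_col].to_numpy(dtype=float)
    names = list(fit.predictor_names)
    X = dev[names]
    degenerate = fit.see_abs <= 1e-9 * max(1.0, float(np.mean(np.abs(y))))

    # criteria 1-2 gate on the predictor coefficients; the constant's CI is
    # recorded as evidence but does not fail the model on its own
    cis_ok = all(
        not (c.ci95_low <= 0 <= c.ci95_high) for c in fit.coefficients[1:]
    )
    const = fit.coefficients[0]
    constant_ci_ok = not (const.ci95_low <= 0 <= const.ci95_high)
    n_big_resid = int(np.sum(np.abs(fit.std_residuals) > config.std_residual_bound))
    gap = fit.r2 - fit.adj_r2
    c1 = Criterion(
        1,
        "generalisation: CIs exclude zero, <=1 large standardised residual, "
        "R2 ~ adjusted R2",
        bool(cis_ok and n_big_resid <= 1 and gap <= config.r2_gap),
        {
            "cis_exclude_zero": cis_ok,
            "constant_ci_excludes_zero": constant_ci_ok,
            "n_std_residuals_beyond_bound": n_big_resid,
            "r2_adj_r2_gap": gap,
        },
    )

    pvals = {c.name: c.p_value for c in fit.coefficients[1:]}
    c2 = Criterion(
        2,
        "all predictor p-values below alpha",
        bool(all(p < config.alpha for p in pvals.values())),
        {"p_values": pvals, "constant_p": const.p_value},
    )

    if len(names) >= 2:
        corr = X.corr().abs()
        worst = max(
            corr.loc[a, b] for i, a in enumerate(names) for b in names[i + 1:]
        )
        c3 = Criterion(
            3,
            "predictors not strongly correlated",
            bool(worst <= config.collinearity_r),
            {"max_abs_pairwise_r": float(worst)},
        )
    else:
        c3 = Criterion(3, "predictors not strongly correlated", True,
                       {"note": "single predictor; vacuously true"})

    if len(names) >= 2:
        sps = {n: reg.semi_partial_correlation(y, X, n) for n in names}
        spread = max(abs(a - b) for a in sps.values() for b in sps.values())
        c4 = Criterion(
            4,
            "semi-partial correlations similar (additivity)",
            bool(spread <= config.semi_partial_gap),
            {"semi_partials": sps, "max_abs_difference": spread},
        )
    else:
        c4 = Criterion(4, "semi-partial correlations similar (additivity)", True,
                       {"note": "single predictor; vacuously true"})

    homo = reg.homoscedasticity_check(fit)
    c5 = Criterion(
        5,
        "no trend of standardised residuals against standardised predictions",
        homo.passed,
        {"r": homo.r, "p": homo.p, "degenerate": homo.degenerate},
    )

    dwres = reg.durbin_watson_verdict(fit.residuals, k=fit.n_predictors)
    if degenerate or dwres.degenerate:
        resid_normal_p = None
        c6_pass = True
        note = "degenerate residuals (noiseless fit)"
    else:
        resid_normal_p = reg.normality_test(
            fit.residuals, method=config.normality_method
        )
        c6_pass = bool(dwres.passed and resid_normal_p >= config.alpha)
        note = dwres.note
    c6 = Criterion(
        6,
        "Durbin-Watson above the tabulated upper bound and residuals normal",
        c6_pass,
        {"d": dwres.d, "du": dwres.du, "residual_normality_p": resid_normal_p,
         "note": note},
    )

    weights = {n: config.practicality_weights.get(n, 1.0) for n in names}
    c7 = Criterion(
        7,
        "ease/speed of acquisition and measurement reliability (advisory)",
        True,
        {"practicality_weights": weights},
        advisory=True,
    )

    criteria = (c1, c2, c3, c4, c5, c6, c7)
    overall = all(c.passed for c in criteria if not c.advisory)
    return DiagnosticsReport(criteria=criteria, overall_pass=overall)


@dataclass
class DevelopedModel:
    """Full provenance-carrying result of one pipeline run."""

    group: str
    fit: reg.RegressionFit
    diagnostics: DiagnosticsReport
    screening: ScreeningResult
    retained_variables: tuple[str, ...]
    cv_mean_residual: float  # signed, cm^3 (criterion - predicted)
    cv_mean_residual_abs: float
    cv_mean_residual_pct: float  # 100 * |signed| / holdout mean MV
    agreement: reg.AgreementResult
    seed: int
    dev_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    removed_outlier_ids: tuple[str, ...]

    def to_report(self) -> dict:
        """JSON-serialisable report (deterministic key order)."""
        return {
            "group": self.group,
            "seed": self.seed,
            "retained_variables": list(self.retained_variables),
            "coefficients": [
                {
                    "name": c.name,
                    "beta": c.beta,
                    "se": c.se,
                    "ci95": [c.ci95_low, c.ci95_high],
                    "p_value": c.p_value,
                }
                for c in self.fit.coefficients
            ],
            "r2": self.fit.r2,
            "adj_r2": self.fit.adj_r2,
            "see_cm3": self.fit.see_abs,
            "see_pct": self.fit.see_pct,
            "durbin_watson": self.fit.dw,
            "cv_mean_residual_cm3": self.cv_mean_residual,
            "cv_mean_residual_pct": self.cv_mean_residual_pct,
            "diagnostics": {
                "overall_pass": self.diagnostics.overall_pass,
                "criteria": [
                    {
                        "id": c.id,
                        "description": c.description,
                        "passed": c.passed,
                        "advisory": c.advisory,
                        "evidence": _jsonable(c.evidence),
                    }
                    for c in self.diagnostics.criteria
                ],
            },
            "agreement": {
                "trend_r": self.agreement.trend_r,
                "trend_p": self.agreement.trend_p,
                "systematic_error": self.agreement.systematic_error,
            },
            "provenance": {
                "dev_ids": list(self.dev_ids),
                "holdout_ids": list(self.holdout_ids),
                "removed_outlier_ids": list(self.removed_outlier_ids),
            },
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def develop_model(
    cohort: pd.DataFrame,
    group: str,
    config: PipelineConfig | None = None,
    seed: int = 0,
    candidates: Sequence[str] | None = None,
) -> DevelopedModel:
    """Run the full development procedure for one muscle group.

    ``cohort`` must carry one row per subject with a ``subject_id`` column,
    the candidate measurement columns, and the criterion volume column
    ``mv_<group>_cm3`` (computed from CSA profiles by the volumetry stage,
    never a shortcut field).
    """
    config = config or PipelineConfig()
    mv_col = f"mv_{group}_cm3"
    if mv_col not in cohort.columns:
        raise PipelineError(f"develop_model: missing criterion column {mv_col}")
    cohort = add_composite_predictors(cohort).reset_index(drop=True)

    try:
        retained_idx, removed_idx, _ = exclude_outliers(
            cohort[mv_col].to_numpy(dtype=float),
            max_removals=config.max_outlier_removals,
            alpha=config.alpha,
            method=config.normality_method,
        )
    except ValueError as e:
        raise PipelineError(f"exclude_outliers: {e}") from e
    removed_ids = tuple(cohort.loc[removed_idx, "subject_id"].astype(str))
    data = cohort.loc[retained_idx].reset_index(drop=True)

    screening = screen_variables(data, group, candidates=candidates, config=config)

    dev, holdout = split_sample(data, config.holdout_fraction, seed=seed)

    retained, fold_reports = loo_candidate_selection(
        dev, group, screening.retained, alpha=config.alpha
    )
    if not retained:
        raise PipelineError(
            "loo_candidate_selection: no candidate present in every fold; "
            f"fold summaries: {fold_reports}"
        )

    try:
        fit = reg.fit_ols(dev[mv_col].to_numpy(dtype=float), dev[list(retained)])
    except ValueError as e:
        raise PipelineError(f"fit_ols: {e}") from e

    diagnostics = evaluate_diagnostics(fit, dev, group, config=config)

    design = np.column_stack(
        [np.ones(len(holdout)), holdout[list(retained)].to_numpy(dtype=float)]
    )
    beta = np.array([c.beta for c in fit.coefficients])
    holdout_pred = design @ beta
    holdout_y = holdout[mv_col].to_numpy(dtype=float)
    cv_resid = float(np.mean(holdout_y - holdout_pred))
    holdout_mean = float(np.mean(holdout_y))
    cv_pct = 100.0 * abs(cv_resid) / holdout_mean

    all_design = np.column_stack(
        [np.ones(len(data)), data[list(retained)].to_numpy(dtype=float)]
    )
    agreement = reg.bland_altman_trend(
        data[mv_col].to_numpy(dtype=float), all_design @ beta
    )

    return DevelopedModel(
        group=group,
        fit=fit,
        diagnostics=diagnostics,
        screening=screening,
        retained_variables=retained,
        cv_mean_residual=cv_resid,
        cv_mean_residual_abs=abs(cv_resid),
        cv_mean_residual_pct=cv_pct,
        agreement=agreement,
        seed=seed,
        dev_ids=tuple(dev["subject_id"].astype(str)),
        holdout_ids=tuple(holdout["subject_id"].astype(str)),
        removed_outlier_ids=removed_ids,
    )


@dataclass(frozen=True)
class ModelSelection:
    selected: Optional[str]  # "a", "b", or None
    residual_r: Optional[float]
    rationale: str


def compare_models(model_a: DevelopedModel, model_b: DevelopedModel) -> ModelSelection:
    """Select between two models developed on the same cases.

    Both passing with strongly correlated residuals: higher R^2 wins (ties
    broken by fewer predictors).  Only one passing: it wins.  Neither: no
    suitable model.  Weakly correlated residuals: selection deferred.
    """
    if model_a.dev_ids != model_b.dev_ids:
        raise ValueError("models were not fit to the same development cases")
    a_ok = model_a.diagnostics.overall_pass
    b_ok = model_b.diagnostics.overall_pass
    r = None
    if a_ok and b_ok:
        from scipy.stats import pearsonr

        ra, rb = model_a.fit.residuals, model_b.fit.residuals
        if np.ptp(ra) == 0 and np.ptp(rb) == 0:
            r = 1.0
        elif np.ptp(ra) == 0 or np.ptp(rb) == 0:
            r = 0.0
        else:
            r = float(pearsonr(ra, rb)[0])
        if abs(r) > 0.80:
            if model_a.fit.r2 != model_b.fit.r2:
                pick = "a" if model_a.fit.r2 > model_b.fit.r2 else "b"
                why = "both pass; residuals strongly correlated; higher R2"
            else:
                pick = "a" if model_a.fit.n_predictors <= model_b.fit.n_predictors else "b"
                why = "both pass; R2 tied; fewer predictors"
            return ModelSelection(selected=pick, residual_r=r, rationale=why)
        return ModelSelection(
            selected=None,
            residual_r=r,
            rationale="both pass but residuals weakly correlated; "
            "selection deferred to diagnostics ranking",
        )
    if a_ok:
        return ModelSelection("a", r, "only model a passes diagnostics")
    if b_ok:
        return ModelSelection("b", r, "only model b passes diagnostics")
    return ModelSelection(None, r, "no suitable model: neither passes diagnostics")
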