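"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's raw data are not public, so this module generates cohorts that
emulate the published model-development group statistics: anthropometric and
ultrasound measurements are drawn from the printed marginal normal
distributions (truncated at +/-3 SD and at zero), and each group's latent
criterion volume follows the published linear model

    MV = constant + slope * (factor1 * factor2) + Normal(0, noise_sd)

with noise_sd defaulting to the printed SEE.  Session-2 replicates add
Normal(0, TEM * sqrt(2)) measurement error.  Per-subject CSA slice profiles
are jittered parabolic envelopes rescaled so that trapezoidal integration
recovers the latent volume exactly (the group volume is split across the
roster muscles).

The joint distribution of the predictors is NOT reported in the source
tables; factors are drawn independently by default, with an equicorrelation
knob (``measurement_correlation``) for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .volumetry import MUSCLE_GROUPS, CSAProfile, compute_muscle_volume

__all__ = [
    "MeasurementSpec",
    "GroupModelSpec",
    "CohortSpec",
    "SyntheticCohort",
    "default_cohort_spec",
    "generate_cohort",
    "generate_csa_profile",
]


class MeasurementSpec(BaseModel):
    """Marginal distribution and between-session error of one measurement."""

    mean: float = Field(gt=0)
    sd: float = Field(ge=0)
    tem: float = Field(default=0.0, ge=0)


class GroupModelSpec(BaseModel):
    """Generating linear model for one muscle group's latent volume."""

    constant: float
    slope: float
    noise_sd: float = Field(ge=0)
    factors: tuple[str, str]
    mv_mean: float = Field(gt=0)
    mv_sd: float = Field(ge=0)


class CohortSpec(BaseModel):
    """Generative parameters for a synthetic cohort."""

    n_subjects: int = Field(ge=3)
    seed: int = 0
    measurements: dict[str, MeasurementSpec]
    models: dict[str, GroupModelSpec]
    n_slices_range: tuple[int, int] = (30, 50)
    slice_spacing_cm: float = Field(default=1.5, gt=0)
    measurement_correlation: float = Field(default=0.0, ge=-0.2, le=0.95)
    make_profiles: bool = True

    @field_validator("n_slices_range")
    @classmethod
    def _slices_ok(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo < 3 or hi < lo:
            raise ValueError("n_slices_range must satisfy 3 <= low <= high")
        return v

    @model_validator(mode="after")
    def _factors_known(self) -> "CohortSpec":
        for group, model in self.models.items():
            if group not in MUSCLE_GROUPS:
                raise ValueError(f"unknown muscle group {group!r}")
            for f in model.factors:
                if f not in self.measurements:
                    raise ValueError(
                        f"model for {group!r} references unknown measurement {f!r}"
                    )
        return self


#: Printed model-development group statistics used as generation defaults:
#: measurement marginals (mean, SD, between-session TEM) and per-group
#: linear models (constant, slope, residual SD = SEE, group MV mean/SD).
_DEFAULT_MEASUREMENTS = {
    "height_m": dict(mean=1.81, sd=0.07),
    "body_mass_kg": dict(mean=78.5, sd=8.2),
    "thigh_length_m": dict(mean=0.41, sd=0.04),
    "shank_length_m": dict(mean=0.44, sd=0.03),
    "mt_hip_cm": dict(mean=3.0, sd=0.5),
    "mt_anterior_thigh_50_cm": dict(mean=3.6, sd=0.4, tem=0.1),
    "mt_biceps_femoris_sh_75_cm": dict(mean=2.9, sd=0.6, tem=0.006),
    "csa_lateral_gastroc_25_cm2": dict(mean=8.6, sd=1.9, tem=0.24),
}

_DEFAULT_MODELS = {
    "hip_extensors": dict(
        constant=1087.037, slope=64.946, noise_sd=283.01,
        factors=("body_mass_kg", "thigh_length_m"),
        mv_mean=3171.9, mv_sd=488.7,
    ),
    "knee_extensors": dict(
        constant=996.168, slope=4.664, noise_sd=121.10,
        factors=("mt_anterior_thigh_50_cm", "body_mass_kg"),
        mv_mean=2311.6, mv_sd=214.3,
    ),
    "knee_flexors": dict(
        constant=1199.444, slope=318.147, noise_sd=125.37,
        factors=("mt_biceps_femoris_sh_75_cm", "thigh_length_m"),
        mv_mean=1589.5, mv_sd=149.6,
    ),
    "ankle_plantarflexors": dict(
        constant=878.606, slope=0.553, noise_sd=134.91,
        factors=("csa_lateral_gastroc_25_cm2", "body_mass_kg"),
        mv_mean=1252.0, mv_sd=165.5,
    ),
}


def default_cohort_spec(
    n_subjects: int = 18, seed: int = 0, **overrides
) -> CohortSpec:
    """CohortSpec reproducing the published group statistics by default."""
    return CohortSpec(
        n_subjects=n_subjects,
        seed=seed,
        measurements={k: MeasurementSpec(**v) for k, v in _DEFAULT_MEASUREMENTS.items()},
        models={k: GroupModelSpec(**v) for k, v in _DEFAULT_MODELS.items()},
        **overrides,
    )


@dataclass
class SyntheticCohort:
    """Generated cohort: measurements, latent volumes, replicates, profiles."""

    spec: CohortSpec
    subjects: pd.DataFrame  # session-1 measurements + mv_<group>_cm3 columns
    session2: pd.DataFrame  # replicate measurements (same columns)
    profiles: Optional[pd.DataFrame]  # long format, or None

    def cohort_frame(self) -> pd.DataFrame:
        """Long-format table, one row per subject-session."""
        s1 = self.subjects.copy()
        s1.insert(1, "session", 1)
        s2 = self.session2.copy()
        s2.insert(1, "session", 2)
        return pd.concat([s1, s2], ignore_index=True)


# SD of a standard normal truncated at +/-3: the generator divides by this
# so that the post-truncation sample SD matches the spec SD.
_TRUNC3_SD = 0.9865783925581086


def _draw_measurements(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = list(spec.measurements)
    k = len(cols)
    rho = spec.measurement_correlation
    cov = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
    chol = np.linalg.cholesky(cov)
    means = np.array([spec.measurements[c].mean for c in cols])
    sds = np.array([spec.measurements[c].sd for c in cols]) / _TRUNC3_SD

    out = np.empty((spec.n_subjects, k))
    todo = np.arange(spec.n_subjects)
    # redraw rows violating the +/-3 SD physiological truncation
    while todo.size:
        z = rng.standard_normal((todo.size, k)) @ chol.T
        vals = means + sds * z
        ok = (np.abs(z) <= 3.0).all(axis=1) & (vals > 0).all(axis=1)
        out[todo[ok]] = vals[ok]
        todo = todo[~ok]
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(spec.n_subjects)])
    return df


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec.seed``.

    Latent group volumes satisfy the spec's linear models; session-2
    replicates perturb only measurements with a nonzero TEM; profiles (when
    ``spec.make_profiles``) integrate back to the latent volumes.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_meas, rng_noise, rng_repl, rng_prof = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    subjects = _draw_measurements(spec, rng_meas)
    for group, model in spec.models.items():
        f1, f2 = model.factors
        product = subjects[f1].to_numpy() * subjects[f2].to_numpy()
        eps = rng_noise.normal(0.0, model.noise_sd, size=spec.n_subjects)
        subjects[f"mv_{group}_cm3"] = model.constant + model.slope * product + eps

    session2 = subjects.copy()
    for col, m in spec.measurements.items():
        if m.tem > 0:
            session2[col] = session2[col] + rng_repl.normal(
                0.0, m.tem * np.sqrt(2.0), size=spec.n_subjects
            )

    profiles = _generate_profiles(spec, subjects, rng_prof) if spec.make_profiles else None
    return SyntheticCohort(
        spec=spec, subjects=subjects, session2=session2, profiles=profiles
    )


def _generate_profiles(
    spec: CohortSpec, subjects: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    records = []
    lo, hi = spec.n_slices_range
    for _, row in subjects.iterrows():
        for group in spec.models:
            roster = MUSCLE_GROUPS[group]
            # split the group volume across its roster muscles
            weights = rng.dirichlet(np.full(len(roster), 4.0))
            for muscle, w in zip(roster, weights):
                n_slices = int(rng.integers(lo, hi + 1))
                profile = generate_csa_profile(
                    latent_volume=float(row[f"mv_{group}_cm3"]) * float(w),
                    n_slices=n_slices,
                    spacing_cm=spec.slice_spacing_cm,
                    rng=rng,
                    muscle=muscle,
                )
                for i, csa in enumerate(profile.csa_cm2):
                    records.append(
                        (row["subject_id"], group, muscle, i, csa, spec.slice_spacing_cm)
                    )
    return pd.DataFrame.from_records(
        records,
        columns=["subject_id", "group", "muscle", "slice_index", "csa_cm2", "spacing_cm"],
    )


def generate_csa_profile(
    latent_volume: float,
    n_slices: int,
    spacing_cm: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    muscle: str = "muscle",
) -> CSAProfile:
    """Non-negative jittered parabolic CSA series with an exact integral.

    The slice series is a parabolic envelope (zero at origin and insertion)
    with 5% multiplicative jitter, rescaled so that its trapezoidal integral
    equals ``latent_volume`` (well within the 0.1% contract).
    """
    if latent_volume <= 0:
        raise ValueError("latent_volume must be positive")
    if n_slices < 3:
        raise ValueError("n_slices must be at least 3")
    if spacing_cm <= 0:
        raise ValueError("spacing_cm must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_slices)
    base = 4.0 * x * (1.0 - x)
    jitter = rng.uniform(0.95, 1.05, size=n_slices)
    csa = base * jitter
    integral = float(np.sum((csa[:-1] + csa[1:]) / 2.0) * spacing_cm)
    csa *= latent_volume / integral
    return CSAProfile(muscle=muscle, csa_cm2=tuple(csa), spacing_cm=spacing_cm)
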