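"""Published clinical prediction equations for lower-limb muscle-group volume.

Each model estimates a muscle-group volume (cm^3) from a single product of
two bedside measurements:

* hip extensors:          body mass (kg) x thigh length (m)
* knee extensors:         anterior-thigh MT at 50% thigh length (cm) x body mass (kg)
* knee flexors:           biceps femoris short-head MT at 75% thigh length (cm) x thigh length (m)
* ankle plantarflexors:   lateral gastrocnemius CSA at 25% shank length (cm^2) x body mass (kg)

The registry freezes the published coefficients, inference and fit
statistics; the uncertainty band attached to an estimate is +/- 1 SEE (a
proper prediction interval would need the development-set design moments,
which were not published).  The knee-flexor and plantarflexor models carry a
systematic-error caveat (significant positive difference-versus-mean trend).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "PublishedModel",
    "PredictionResult",
    "SensitivityResult",
    "PUBLISHED_MODELS",
    "estimate_volume",
    "sensitivity_check",
]


@dataclass(frozen=True)
class InputSpec:
    """One required measurement: key, unit, sanity range, dev-group moments."""

    key: str
    unit: str
    plausible_low: float  # hard unit-sanity bounds (reject outside)
    plausible_high: float
    dev_mean: float
    dev_sd: float
    unit_hint: str


@dataclass(frozen=True)
class PublishedModel:
    group: str
    predictor_label: str
    constant: float
    constant_se: float
    constant_ci95: tuple[float, float]
    constant_p: str
    slope: float
    slope_se: float
    slope_ci95: tuple[float, float]
    slope_p: str
    r2: float
    adj_r2: float
    see_cm3: float
    see_pct: float
    cv_residual_cm3: float
    cv_residual_pct: float
    durbin_watson: float
    dev_n: int
    cv_n: int
    dev_mv_mean: float
    dev_mv_sd: float
    cv_mv_mean: float
    inputs: tuple[InputSpec, ...]
    systematic_error_caveat: bool = False


PUBLISHED_MODELS: dict[str, PublishedModel] = {
    "hip_extensors": PublishedModel(
        group="hip_extensors",
        predictor_label="body mass (kg) x thigh length (m)",
        constant=1087.037, constant_se=410.022,
        constant_ci95=(193.676, 1980.398), constant_p="0.021",
        slope=64.946, slope_se=12.554,
        slope_ci95=(37.594, 92.298), slope_p="<0.001",
        r2=0.690, adj_r2=0.665,
        see_cm3=283.01, see_pct=8.92,
        cv_residual_cm3=-347.32, cv_residual_pct=11.28,
        durbin_watson=1.67,
        dev_n=14, cv_n=3,
        dev_mv_mean=3171.9, dev_mv_sd=488.7, cv_mv_mean=3078.8,
        inputs=(
            InputSpec("body_mass_kg", "kg", 30.0, 250.0, 77.8, 9.7,
                      "body mass in kilograms"),
            InputSpec("thigh_length_m", "m", 0.2, 0.8, 0.41, 0.03,
                      "thigh length in metres (a value above 0.8 looks like cm)"),
        ),
    ),
    "knee_extensors": PublishedModel(
        group="knee_extensors",
        predictor_label="anterior thigh MT at 50% thigh length (cm) x body mass (kg)",
        constant=996.168, constant_se=257.349,
        constant_ci95=(429.747, 1562.588), constant_p="0.003",
        slope=4.664, slope_se=0.905,
        slope_ci95=(2.673, 6.655), slope_p="<0.001",
        r2=0.707, adj_r2=0.681,
        see_cm3=121.10, see_pct=5.24,
        cv_residual_cm3=20.11, cv_residual_pct=0.95,
        durbin_watson=2.32,
        dev_n=13, cv_n=3,
        dev_mv_mean=2311.6, dev_mv_sd=214.3, cv_mv_mean=2110.32,
        inputs=(
            InputSpec("mt_anterior_thigh_50_cm", "cm", 0.5, 10.0, 3.6, 0.4,
                      "muscle thickness in centimetres"),
            InputSpec("body_mass_kg", "kg", 30.0, 250.0, 78.2, 8.2,
                      "body mass in kilograms"),
        ),
    ),
    "knee_flexors": PublishedModel(
        group="knee_flexors",
        predictor_label="biceps femoris short-head MT at 75% thigh length (cm) "
                        "x thigh length (m)",
        constant=1199.444, constant_se=161.753,
        constant_ci95=(843.428, 1555.461), constant_p="<0.001",
        slope=318.147, slope_se=128.860,
        slope_ci95=(34.528, 601.766), slope_p="0.031",
        r2=0.357, adj_r2=0.298,
        see_cm3=125.37, see_pct=7.89,
        cv_residual_cm3=-42.72, cv_residual_pct=-2.66,
        durbin_watson=2.18,
        dev_n=13, cv_n=3,
        dev_mv_mean=1589.5, dev_mv_sd=149.6, cv_mv_mean=1607.2,
        inputs=(
            InputSpec("mt_biceps_femoris_sh_75_cm", "cm", 0.3, 10.0, 2.9, 0.6,
                      "muscle thickness in centimetres"),
            InputSpec("thigh_length_m", "m", 0.2, 0.8, 0.41, 0.04,
                      "thigh length in metres (a value above 0.8 looks like cm)"),
        ),
        systematic_error_caveat=True,
    ),
    "ankle_plantarflexors": PublishedModel(
        group="ankle_plantarflexors",
        predictor_label="lateral gastrocnemius CSA at 25% shank length (cm^2) "
                        "x body mass (kg)",
        constant=878.606, constant_se=140.417,
        constant_ci95=(572.662, 1184.549), constant_p="<0.001",
        slope=0.553, slope_se=0.201,
        slope_ci95=(0.115, 0.991), slope_p="0.018",
        r2=0.387, adj_r2=0.336,
        see_cm3=134.91, see_pct=10.78,
        cv_residual_cm3=92.44, cv_residual_pct=6.37,
        durbin_watson=1.44,
        dev_n=14, cv_n=4,
        dev_mv_mean=1252.0, dev_mv_sd=165.5, cv_mv_mean=1451.5,
        inputs=(
            InputSpec("csa_lateral_gastroc_25_cm2", "cm^2", 1.0, 50.0, 8.6, 1.9,
                      "cross-sectional area in square centimetres"),
            InputSpec("body_mass_kg", "kg", 30.0, 250.0, 78.5, 7.8,
                      "body mass in kilograms"),
        ),
        systematic_error_caveat=True,
    ),
}


@dataclass(frozen=True)
class PredictionResult:
    group: str
    estimate_cm3: float
    band_low_cm3: float  # estimate - SEE
    band_high_cm3: float  # estimate + SEE
    see_cm3: float
    inputs: dict[str, float]
    warnings: tuple[str, ...] = ()
    systematic_error_caveat: bool = False


def estimate_volume(group: str, measurements: Mapping[str, float]) -> PredictionResult:
    """Evaluate a published equation on new measurements.

    Measurements must be supplied under the registry's keys, positive, and
    in the declared units (the equations mix metres and centimetres; gross
    unit mismatches are rejected with a hint).  Inputs more than 2.5 SD from
    the development-group mean attach an extrapolation warning.
    """
    if group not in PUBLISHED_MODELS:
        raise ValueError(
            f"unknown group {group!r}; known: {sorted(PUBLISHED_MODELS)}"
        )
    model = PUBLISHED_MODELS[group]
    values = []
    warns: list[str] = []
    for spec in model.inputs:
        if spec.key not in measurements:
            raise ValueError(f"missing measurement {spec.key!r} ({spec.unit_hint})")
        v = float(measurements[spec.key])
        if not v > 0:
            raise ValueError(f"{spec.key} must be positive, got {v}")
        if not spec.plausible_low <= v <= spec.plausible_high:
            raise ValueError(
                f"{spec.key}={v} outside plausible range "
                f"[{spec.plausible_low}, {spec.plausible_high}] {spec.unit}; "
                f"expected {spec.unit_hint}"
            )
        lo = spec.dev_mean - 2.5 * spec.dev_sd
        hi = spec.dev_mean + 2.5 * spec.dev_sd
        if not lo <= v <= hi:
            warns.append(
                f"{spec.key}={v} is outside the model-development range "
                f"(~{lo:.3g}-{hi:.3g} {spec.unit}); estimate is an extrapolation"
            )
        values.append(v)
    estimate = model.constant + model.slope * values[0] * values[1]
    return PredictionResult(
        group=group,
        estimate_cm3=estimate,
        band_low_cm3=estimate - model.see_cm3,
        band_high_cm3=estimate + model.see_cm3,
        see_cm3=model.see_cm3,
        inputs={s.key: v for s, v in zip(model.inputs, values)},
        warnings=tuple(warns),
        systematic_error_caveat=model.systematic_error_caveat,
    )


@dataclass(frozen=True)
class SensitivityResult:
    group: str
    effect_pct: float
    see_pct: float
    detectable: bool
    margin_pct: float  # effect - SEE%


def sensitivity_check(group: str, effect_pct: float) -> SensitivityResult:
    """Is a hypothesised percentage difference larger than the model's SEE%?"""
    if group not in PUBLISHED_MODELS:
        raise ValueError(f"unknown group {group!r}")
    if not effect_pct > 0:
        raise ValueError("effect_pct must be positive")
    see_pct = PUBLISHED_MODELS[group].see_pct
    return SensitivityResult(
        group=group,
        effect_pct=effect_pct,
        see_pct=see_pct,
        detectable=bool(effect_pct > see_pct),
        margin_pct=effect_pct - see_pct,
    )
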