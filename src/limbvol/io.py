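"""File formats shared by the CLI: cohort/profile CSV, YAML/JSON configs.

CSV dialect: comma-separated, UTF-8, mandatory header row, decimal point.
Units are encoded in column names (``body_mass_kg``, ``thigh_length_m``,
``mt_anterior_thigh_50_cm``, ...).  The cohort table is long over sessions
(one row per subject-session); profiles are long over slices.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import CohortSpec, SyntheticCohort, default_cohort_spec

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "load_cohort_spec",
    "write_data_dictionary",
]

_FLOAT_FMT = "%.10g"


def write_cohort_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    cohort.cohort_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(path: str | Path, session: int | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: cohort CSV must carry a subject_id column")
    if session is not None and "session" in df.columns:
        df = df[df["session"] == session].drop(columns=["session"])
    return df.reset_index(drop=True)


def write_profiles_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_profiles_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_cohort_spec(source: str | Path) -> CohortSpec:
    """CohortSpec from a YAML/JSON file, or the built-in ``default`` spec."""
    if str(source) == "default":
        return default_cohort_spec()
    path = Path(source)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return CohortSpec(**data)


def write_data_dictionary(path: str | Path) -> None:
    """Column documentation for the cohort CSV."""
    lines = [
        "# Cohort CSV data dictionary",
        "",
        "| column | unit | description |",
        "|---|---|---|",
        "| subject_id | - | subject identifier |",
        "| session | - | measurement session (1 or 2) |",
        "| height_m | m | standing height |",
        "| body_mass_kg | kg | body mass |",
        "| thigh_length_m | m | greater trochanter to lateral femoral epicondyle |",
        "| shank_length_m | m | lateral femoral epicondyle to lateral malleolus |",
        "| mt_hip_cm | cm | gluteal muscle thickness at mid-hip |",
        "| mt_anterior_thigh_50_cm | cm | anterior thigh muscle thickness at 50% thigh length |",
        "| mt_biceps_femoris_sh_75_cm | cm | biceps femoris short-head muscle thickness at 75% thigh length |",
        "| csa_lateral_gastroc_25_cm2 | cm^2 | lateral gastrocnemius CSA at 25% shank length |",
        "| mv_<group>_cm3 | cm^3 | latent criterion muscle-group volume |",
        "",
        "Profile CSV columns: subject_id, group, muscle, slice_index,",
        "csa_cm2 (cm^2), spacing_cm (cm).",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
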