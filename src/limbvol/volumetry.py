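"""Criterion muscle and muscle-group volumes from serial axial CSA slices.

A muscle is represented by an ordered series of axial cross-sectional areas
(cm^2) at uniform inter-slice spacing (cm).  Volume is the trapezoidal sum

    MV = sum_{i=1..n-1} ((CSA_i + CSA_{i+1}) / 2) * h      [cm^3]

Individual muscle volumes are summed into functional group volumes using the
rosters in :data:`MUSCLE_GROUPS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MUSCLE_GROUPS",
    "CSAProfile",
    "MuscleVolumeResult",
    "compute_muscle_volume",
    "compute_group_volume",
    "group_volumes_from_profiles",
]

#: Functional muscle-group rosters.  Membership is validated by
#: :func:`compute_group_volume`; the gastrocnemii appear in two groups.
MUSCLE_GROUPS: dict[str, tuple[str, ...]] = {
    "hip_extensors": (
        "gluteus_maximus",
        "gluteus_medius",
        "biceps_femoris_long_head",
        "semimembranosus",
        "semitendinosus",
        "adductor_magnus",
    ),
    "knee_extensors": (
        "rectus_femoris",
        "vastus_intermedius",
        "vastus_lateralis",
        "vastus_medialis",
    ),
    "knee_flexors": (
        "semimembranosus",
        "semitendinosus",
        "biceps_femoris_long_head",
        "biceps_femoris_short_head",
        "medial_gastrocnemius",
        "lateral_gastrocnemius",
        "popliteus",
        "sartorius",
        "gracilis",
    ),
    "ankle_plantarflexors": (
        "medial_gastrocnemius",
        "lateral_gastrocnemius",
        "soleus",
        "peroneals",
        "tibialis_posterior",
        "flexor_digitorum_longus",
        "flexor_hallucis_longus",
    ),
}


@dataclass(frozen=True)
class CSAProfile:
    """Ordered axial CSA slice series for one muscle.

    Parameters
    ----------
    muscle : str
        Muscle name (snake_case, see :data:`MUSCLE_GROUPS`).
    csa_cm2 : tuple of float
        CSA at each slice, cm^2, ordered along the limb.
    spacing_cm : float
        Uniform inter-slice distance h, cm.
    """

    muscle: str
    csa_cm2: tuple[float, ...]
    spacing_cm: float

    def __post_init__(self) -> None:
        csa = tuple(float(v) for v in self.csa_cm2)
        object.__setattr__(self, "csa_cm2", csa)
        if len(csa) < 2:
            raise ValueError("at least two slices required")
        if any(v < 0 for v in csa):
            raise ValueError(f"negative CSA in profile for {self.muscle!r}")
        if not self.spacing_cm > 0:
            raise ValueError("slice spacing must be positive")

    @property
    def n(self) -> int:
        return len(self.csa_cm2)


@dataclass(frozen=True)
class MuscleVolumeResult:
    """Volume of one muscle or one muscle group, cm^3."""

    name: str
    volume_cm3: float

    def __post_init__(self) -> None:
        if self.volume_cm3 < 0:
            raise ValueError("volume must be non-negative")


def compute_muscle_volume(profile: CSAProfile) -> MuscleVolumeResult:
    """Trapezoidal volume of a single muscle from its CSA slice series."""
    csa = np.asarray(profile.csa_cm2, dtype=float)
    h = float(profile.spacing_cm)
    volume = float(np.sum((csa[:-1] + csa[1:]) / 2.0) * h)
    return MuscleVolumeResult(name=profile.muscle, volume_cm3=volume)


def compute_group_volume(
    volumes: Iterable[MuscleVolumeResult], group: str
) -> MuscleVolumeResult:
    """Sum member muscle volumes into a group volume.

    Every member must belong to the named group's roster; the sum is
    order-independent.
    """
    if group not in MUSCLE_GROUPS:
        raise ValueError(
            f"unknown muscle group {group!r}; known: {sorted(MUSCLE_GROUPS)}"
        )
    volumes = list(volumes)
    if not volumes:
        raise ValueError("empty muscle list")
    roster = MUSCLE_GROUPS[group]
    for v in volumes:
        if v.name not in roster:
            raise ValueError(f"muscle {v.name!r} is not in group {group!r}")
    # fsum: exact permutation-invariant summation
    return MuscleVolumeResult(
        name=group, volume_cm3=math.fsum(v.volume_cm3 for v in volumes)
    )


def profiles_from_frame(df: pd.DataFrame) -> list[tuple[str, str, CSAProfile]]:
    """Parse a long-format profile table into per-muscle profiles.

    Expects columns ``subject_id, group, muscle, slice_index, csa_cm2,
    spacing_cm``; slices are ordered by ``slice_index`` within each profile.
    Non-uniform spacing within a profile is rejected.
    """
    required = {"subject_id", "group", "muscle", "slice_index", "csa_cm2", "spacing_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    out: list[tuple[str, str, CSAProfile]] = []
    for (subject, group, muscle), sub in df.groupby(
        ["subject_id", "group", "muscle"], sort=True
    ):
        sub = sub.sort_values("slice_index")
        spacing = sub["spacing_cm"].to_numpy(dtype=float)
        if not np.allclose(spacing, spacing[0]):
            raise ValueError(
                f"non-uniform spacing for subject {subject}, muscle {muscle!r}"
            )
        profile = CSAProfile(
            muscle=str(muscle),
            csa_cm2=tuple(sub["csa_cm2"].to_numpy(dtype=float)),
            spacing_cm=float(spacing[0]),
        )
        out.append((str(subject), str(group), profile))
    return out


def group_volumes_from_profiles(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-group criterion volumes from a long profile table.

    Returns a frame with columns ``subject_id, group, volume_cm3``.
    """
    rows: dict[tuple[str, str], list[MuscleVolumeResult]] = {}
    for subject, group, profile in profiles_from_frame(df):
        rows.setdefault((subject, group), []).append(compute_muscle_volume(profile))
    records = [
        {
            "subject_id": subject,
            "group": group,
            "volume_cm3": compute_group_volume(muscles, group).volume_cm3,
        }
        for (subject, group), muscles in sorted(rows.items())
    ]
    return pd.DataFrame.from_records(records)
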