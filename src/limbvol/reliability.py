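"""Between-session measurement reliability: typical error of measurement.

TEM = SD(session1 - session2) / sqrt(2), with the sample (n-1) standard
deviation.  The percentage form divides by the mean of the *first* session,
so swapping the sessions leaves the absolute TEM unchanged but can change
the percentage through its denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TEMResult", "compute_tem"]


@dataclass(frozen=True)
class TEMResult:
    measurement: str
    tem_abs: float
    tem_pct: float | None
    n_pairs: int


def compute_tem(
    session1: Sequence[float],
    session2: Sequence[float],
    measurement: str = "measurement",
) -> TEMResult:
    """Typical error of measurement between two paired sessions.

    Raises
    ------
    ValueError
        If the sessions differ in length or fewer than 2 pairs are given.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be 1-D and equal length (paired by subject)")
    if s1.size < 2:
        raise ValueError("at least 2 pairs required")
    tem_abs = float(np.std(s1 - s2, ddof=1) / math.sqrt(2.0))
    mean1 = float(np.mean(s1))
    # tem_pct is undefined when the first-session mean is zero
    tem_pct = 100.0 * tem_abs / mean1 if mean1 != 0 else None
    return TEMResult(
        measurement=measurement, tem_abs=tem_abs, tem_pct=tem_pct, n_pairs=int(s1.size)
    )
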