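"""Builders for clinical-style fractionation schedules.

The xenograft studies irradiate Monday-Friday: fractions on days
``0..4, 7..11, ...`` with weekend gaps.  The radiosensitizer is given just
before each fraction, so each event carries the arm's plasma concentration.
"""

from __future__ import annotations

import numpy as np

from .model import Regimen

__all__ = ["weekday_fraction_times", "mon_fri_regimen", "total_dose_regimen"]


def weekday_fraction_times(weeks: int, fractions_per_week: int = 5) -> np.ndarray:
    """Days of all fractions for a Mon-Fri x ``weeks`` schedule."""
    if weeks < 1 or not 1 <= fractions_per_week <= 7:
        raise ValueError("need weeks >= 1 and 1 <= fractions_per_week <= 7")
    return np.array(
        [7 * w + d for w in range(weeks) for d in range(fractions_per_week)],
        dtype=float,
    )


def mon_fri_regimen(
    weeks: int,
    dose_per_fraction: float,
    concentration: float = 0.0,
    horizon: float | None = None,
    fractions_per_week: int = 5,
) -> Regimen:
    """Fixed per-fraction dose, Mon-Fri over ``weeks`` weeks."""
    times = weekday_fraction_times(weeks, fractions_per_week)
    if horizon is None:
        horizon = float(times[-1]) + 21.0
    n = len(times)
    return Regimen(
        times=tuple(times),
        doses=(float(dose_per_fraction),) * n,
        concentrations=(float(concentration),) * n,
        horizon=float(horizon),
    )


def total_dose_regimen(
    total_dose: float,
    concentration: float = 0.0,
    weeks: int = 6,
    fractions_per_week: int = 5,
    horizon: float | None = None,
) -> Regimen:
    """Split a total dose evenly over a Mon-Fri schedule.

    This is the schedule family swept when tracing TSE curves: the
    fractionation stays fixed (default 30 fractions over 6 weeks) while the
    total dose varies.
    """
    if total_dose < 0:
        raise ValueError("total_dose must be >= 0")
    n = weeks * fractions_per_week
    return mon_fri_regimen(
        weeks,
        total_dose / n,
        concentration=concentration,
        horizon=horizon,
        fractions_per_week=fractions_per_week,
    )
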