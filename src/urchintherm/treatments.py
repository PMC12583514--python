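"""Mesocosm thermal schedules for the heatwave experiments.

Two families of daily set-point trajectories are used:

* constant treatments — a linear acclimation ramp from ambient up (or down) to a
  target temperature, then a flat hold for the rest of the experiment;
* event treatments (El Niño / La Niña) — a seasonal peak-and-decline trajectory
  built from an initial plateau at the seasonal peak followed by a constant-rate
  decline (at most 0.5 °C per day, matching a single manual set-point adjustment
  each morning), with the plateau length solved so that the window mean hits the
  historical event mean exactly.

Temperatures are single daily set points in °C; mesocosm hardware cannot track
sub-daily structure, so no within-day variation is represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ThermalSchedule",
    "make_constant",
    "make_event_schedule",
    "schedule_mean",
    "default_schedules_exp1",
    "schedules_to_csv",
    "schedules_from_csv",
    "MAX_DAILY_STEP_C",
    "PHYSICAL_BOUNDS_C",
]

#: Largest permitted day-to-day set-point change for variable treatments (°C);
#: one manual 0.5 °C adjustment per day.
MAX_DAILY_STEP_C = 0.5

#: Physically plausible mesocosm range (°C); outside this the chillers/heaters
#: used in the experiments cannot hold a set point.
PHYSICAL_BOUNDS_C = (5.0, 25.0)

#: Ambient intake temperature (°C) from which acclimation ramps start.
AMBIENT_START_C = 13.3

#: Default acclimation ramp length (days): targets reached after two weeks.
DEFAULT_RAMP_DAYS = 14

#: Default exposure window lengths (days): 10-week and 12-week experiments.
EXP1_DURATION_DAYS = 70
EXP2_DURATION_DAYS = 84

#: Constant-treatment levels (°C) used in the first experiment.
EXP1_CONSTANT_LEVELS = (10.0, 13.0, 16.0, 17.0, 18.0, 20.0)

#: El Niño event: 21 °C declining to 18 °C with a window mean of 20 °C.
EL_NINO_EVENT = (21.0, 18.0, 20.0)
#: La Niña event: 18 °C declining to 14 °C with a window mean of 16 °C.
LA_NINA_EVENT = (18.0, 14.0, 16.0)


@dataclass(frozen=True)
class ThermalSchedule:
    """Daily temperature trajectory for one mesocosm.

    ``temp_c[d]`` is the set point on day ``day_index[d]``.  ``ramp_days``
    leading days are acclimation and are excluded from the analysis window:
    ``realized_mean_c`` is the arithmetic mean of the post-ramp days only and
    is the temperature covariate carried by every animal in the mesocosm.
    """

    treatment_label: str  # one of {"constant", "el_nino", "la_nina"}
    level_tag: str
    temp_c: np.ndarray
    ramp_days: int = 0
    day_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    realized_mean_c: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        temps = np.asarray(self.temp_c, dtype=float)
        if temps.ndim != 1 or temps.size == 0:
            raise ValueError("temp_c must be a non-empty 1-d array")
        if not np.all(np.isfinite(temps)):
            raise ValueError("temp_c contains non-finite values")
        lo, hi = PHYSICAL_BOUNDS_C
        if temps.min() < lo or temps.max() > hi:
            raise ValueError(
                f"temperatures outside physical bounds [{lo}, {hi}] °C: "
                f"range [{temps.min():.2f}, {temps.max():.2f}]"
            )
        if not 0 <= self.ramp_days < temps.size:
            raise ValueError("ramp_days must lie inside the schedule")
        object.__setattr__(self, "temp_c", temps)
        object.__setattr__(self, "day_index", np.arange(temps.size))
        object.__setattr__(
            self, "realized_mean_c", float(temps[self.ramp_days :].mean())
        )

    @property
    def n_days(self) -> int:
        return int(self.temp_c.size)

    @property
    def exposure_temp_c(self) -> np.ndarray:
        """Post-ramp daily temperatures (the analysis window)."""
        return self.temp_c[self.ramp_days :]

    def max_daily_step(self) -> float:
        if self.n_days < 2:
            return 0.0
        return float(np.max(np.abs(np.diff(self.temp_c))))


def make_constant(
    target_c: float,
    n_days: int = EXP1_DURATION_DAYS,
    start_c: float = AMBIENT_START_C,
    ramp_days: int = DEFAULT_RAMP_DAYS,
    level_tag: str | None = None,
) -> ThermalSchedule:
    """Constant treatment: linear ramp from ``start_c`` reaching ``target_c``
    on day ``ramp_days``, then held flat through day ``n_days - 1``.

    The realized mean is computed over the post-ramp hold only, so it equals
    ``target_c`` exactly.
    """
    lo, hi = PHYSICAL_BOUNDS_C
    if not lo <= target_c <= hi:
        raise ValueError(f"target {target_c} °C outside physical bounds [{lo}, {hi}]")
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if ramp_days < 0 or ramp_days >= n_days:
        raise ValueError("need 0 <= ramp_days < n_days")
    days = np.arange(n_days, dtype=float)
    if ramp_days == 0:
        temps = np.full(n_days, float(target_c))
    else:
        temps = start_c + (target_c - start_c) * np.minimum(days / ramp_days, 1.0)
        temps[ramp_days:] = target_c
    if level_tag is None:
        level_tag = f"{target_c:g}C"
    return ThermalSchedule("constant", level_tag, temps, ramp_days=ramp_days)


def _plateau_decline_temps(
    start_c: float, end_c: float, n_days: int, decline_start: float, rate: float
) -> np.ndarray:
    """Daily set points of a plateau → constant-rate decline → hold trajectory.

    ``decline_start`` may be fractional; daily values are the continuous-time
    trajectory sampled at integer days, which keeps day-to-day steps <= rate.
    """
    days = np.arange(n_days, dtype=float)
    temps = start_c - rate * np.clip(days - decline_start, 0.0, None)
    return np.maximum(temps, end_c)


def make_event_schedule(
    start_c: float,
    end_c: float,
    target_mean_c: float,
    n_days: int = EXP1_DURATION_DAYS,
    treatment_label: str = "el_nino",
    level_tag: str | None = None,
    rate: float = MAX_DAILY_STEP_C,
    mean_tol: float = 1e-6,
) -> ThermalSchedule:
    """Seasonal peak-and-decline event trajectory with an exact window mean.

    The trajectory holds ``start_c``, declines at ``rate`` °C/day to ``end_c``
    and holds there; the decline onset is solved (by root finding on the day-
    sampled mean, which is continuous and monotone in the onset) so the mean
    over all ``n_days`` equals ``target_mean_c``.  Deterministic: identical
    arguments always yield identical trajectories.

    Raises ``ValueError`` when the (start, end, mean) triple is unreachable
    given the step bound and the window length.
    """
    if start_c < end_c:
        raise ValueError("event schedules are seasonal declines: need start_c >= end_c")
    if not end_c <= target_mean_c <= start_c:
        raise ValueError("target mean must lie between the endpoints")
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if not 0 < rate <= MAX_DAILY_STEP_C:
        raise ValueError(f"rate must be in (0, {MAX_DAILY_STEP_C}]")
    if level_tag is None:
        level_tag = treatment_label

    if start_c == end_c:
        temps = np.full(n_days, float(start_c))
        return ThermalSchedule(treatment_label, level_tag, temps, ramp_days=0)

    decline_days = (start_c - end_c) / rate
    # Latest onset that still reaches end_c by the final day.
    max_onset = (n_days - 1) - decline_days
    if max_onset < 0:
        raise ValueError(
            f"infeasible event schedule: {start_c}->{end_c} °C needs "
            f"{decline_days:.1f} days at {rate} °C/day but only {n_days - 1} available"
        )

    def mean_err(onset: float) -> float:
        return _plateau_decline_temps(start_c, end_c, n_days, onset, rate).mean() - (
            target_mean_c
        )

    lo, hi = mean_err(0.0), mean_err(max_onset)
    if not lo - mean_tol <= 0.0 <= hi + mean_tol:
        raise ValueError(
            "infeasible event schedule: achievable means are "
            f"[{lo + target_mean_c:.3f}, {hi + target_mean_c:.3f}] °C, "
            f"target {target_mean_c} °C"
        )
    if lo >= 0.0:
        onset = 0.0
    elif hi <= 0.0:
        onset = max_onset
    else:
        onset = brentq(mean_err, 0.0, max_onset, xtol=1e-10)
    temps = _plateau_decline_temps(start_c, end_c, n_days, onset, rate)
    # Pin the endpoints exactly (float noise only).
    temps[0] = start_c
    temps[-1] = end_c
    return ThermalSchedule(treatment_label, level_tag, temps, ramp_days=0)


def schedule_mean(schedule: ThermalSchedule, window: tuple[int, int] | None = None) -> float:
    """Arithmetic mean of daily temperatures over ``window = (first, last)``
    inclusive day indices; the full schedule when ``window`` is None."""
    if window is None:
        return float(schedule.temp_c.mean())
    first, last = window
    if not (0 <= first <= last < schedule.n_days):
        raise ValueError(f"window {window} outside schedule of {schedule.n_days} days")
    return float(schedule.temp_c[first : last + 1].mean())


def default_schedules_exp1(
    n_days: int = EXP1_DURATION_DAYS,
    ramp_days: int = DEFAULT_RAMP_DAYS,
) -> dict[str, ThermalSchedule]:
    """The eight treatment schedules of the first experiment, keyed by tag.

    Six constant levels plus the El Niño (21→18 °C, mean 20) and La Niña
    (18→14 °C, mean 16) event trajectories.  Event schedules carry no in-window
    ramp: their animals were ramped to the seasonal start before day 0.
    """
    out: dict[str, ThermalSchedule] = {}
    for level in EXP1_CONSTANT_LEVELS:
        sched = make_constant(level, n_days=n_days + ramp_days, ramp_days=ramp_days)
        out[sched.level_tag] = sched
    s, e, m = EL_NINO_EVENT
    out["elnino"] = make_event_schedule(s, e, m, n_days, "el_nino", "elnino")
    s, e, m = LA_NINA_EVENT
    out["lanina"] = make_event_schedule(s, e, m, n_days, "la_nina", "lanina")
    return out


def schedules_to_csv(schedules: dict[str, ThermalSchedule], path) -> None:
    """Write one row per mesocosm-day: (mesocosm_id, day_index, temp_c)."""
    frames = []
    for tag, sched in schedules.items():
        frames.append(
            pd.DataFrame(
                {
                    "mesocosm_id": tag,
                    "day_index": sched.day_index,
                    "temp_c": sched.temp_c,
                    "treatment_label": sched.treatment_label,
                    "ramp_days": sched.ramp_days,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def schedules_from_csv(path) -> dict[str, ThermalSchedule]:
    df = pd.read_csv(path)
    out = {}
    for tag, grp in df.groupby("mesocosm_id", sort=False):
        grp = grp.sort_values("day_index")
        out[str(tag)] = ThermalSchedule(
            treatment_label=str(grp["treatment_label"].iloc[0]),
            level_tag=str(tag),
            temp_c=grp["temp_c"].to_numpy(),
            ramp_days=int(grp["ramp_days"].iloc[0]),
        )
    return out
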