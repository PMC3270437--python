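"""Oral dosing schedules.

The study design uses four protocols at each dose level (dose level in μg
per kg body weight of *each* congener per administration): one dose per day,
one dose per week, daily doses through day 13 followed by no exposure, and
13 irregularly timed doses.  The exact irregular times are a documented
package default and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DoseSchedule", "build_schedule", "PROTOCOLS", "NONPERIODIC_DAYS"]

PROTOCOLS = ("daily", "weekly", "daily-to-day-13", "nonperiodic")

#: Default irregular dose days for the nonperiodic protocol (13 doses).
NONPERIODIC_DAYS: tuple[int, ...] = (0, 1, 2, 5, 8, 9, 15, 22, 29, 43, 57, 71, 85)


class ScheduleError(ValueError):
    """A dose schedule is malformed or its protocol label unknown."""


@dataclass(frozen=True)
class DoseSchedule:
    """Discrete oral dose events.

    ``times_h`` are strictly increasing, nonnegative event times in hours;
    ``dose_per_kg`` is the dose of each congener per event in μg/kg body
    weight.  The dose mass administered at an event is recomputed from the
    body weight at that time (configurable at the simulation layer).
    """

    times_h: tuple[float, ...]
    dose_per_kg: float
    protocol_label: str = "custom"

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.times_h):
            raise ScheduleError("dose times must be nonnegative")
        if any(b <= a for a, b in zip(self.times_h, self.times_h[1:])):
            raise ScheduleError("dose times must be strictly increasing")
        if self.dose_per_kg < 0:
            raise ScheduleError("dose must be nonnegative")

    @property
    def n_events(self) -> int:
        return len(self.times_h)


def build_schedule(
    protocol_label: str,
    dose_level: float,
    n_days: float,
    nonperiodic_days: tuple[int, ...] = NONPERIODIC_DAYS,
) -> DoseSchedule:
    """Construct the dose schedule for one of the study protocols.

    Parameters
    ----------
    protocol_label : str
        ``daily``, ``weekly``, ``daily-to-day-13`` or ``nonperiodic``.
    dose_level : float
        μg of each congener per kg body weight per administration.
    n_days : float
        Length of the exposure window (the sacrifice day); events at or
        after ``n_days`` are dropped.
    nonperiodic_days : tuple of int
        Dose days used by the nonperiodic protocol.
    """
    if protocol_label == "daily":
        days = [d for d in range(int(-(-n_days // 1))) if d < n_days]
    elif protocol_label == "weekly":
        days = [d for d in range(0, int(n_days) + 7, 7) if d < n_days]
    elif protocol_label == "daily-to-day-13":
        days = [d for d in range(13) if d < n_days]
    elif protocol_label == "nonperiodic":
        days = [d for d in nonperiodic_days if d < n_days]
    else:
        raise ScheduleError(
            f"unknown dose protocol {protocol_label!r}; expected one of {PROTOCOLS}"
        )
    return DoseSchedule(
        times_h=tuple(24.0 * d for d in days),
        dose_per_kg=float(dose_level),
        protocol_label=protocol_label,
    )
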