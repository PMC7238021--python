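"""Dose-event schedules and evaluation windows for the adherence scenarios.

The study design: regular dosing from treatment start, steady state reached
by day 7; a single dose irregularity occurs on day 8 (the last scheduled
day-8 dose: 180 h for q12h IR, 168 h for q24h XR) and regular dosing resumes
at 192 h.  Scenarios:

- ``adherence``       every dose taken on schedule;
- ``delay``           the irregular dose taken ``delay_fraction`` of the
                      dosing interval late (100 % delay ⇒ taken together
                      with the next scheduled dose);
- ``omission``        the irregular dose skipped without replacement;
- ``doubling``        the irregular dose accidentally taken twice;
- ``discontinuation`` no doses after the irregular one.

Summary parameters are evaluated after the next scheduled dose: the
reference window is day 9 ([192, 216] h).  The omission window opens at
the skipped dose's scheduled time so that the pre-dose undershoot is
captured; the discontinuation window runs from the last dose to the
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "DoseEvent",
    "Regimen",
    "EvaluationWindows",
    "FORMULATIONS",
    "SCENARIOS",
    "build_regimen",
    "evaluation_windows",
    "irregular_dose_time",
]

SCENARIOS = ("adherence", "delay", "omission", "doubling", "discontinuation")

#: Default study arms: total daily dose 400 mg either as 200 mg q12h (IR)
#: or 400 mg q24h (XR).  Amounts in µg.
FORMULATIONS: dict[str, dict[str, float]] = {
    "IR": {"dose_ug": 200_000.0, "tau": 12.0},
    "XR": {"dose_ug": 400_000.0, "tau": 24.0},
}

#: Day-9 window over which steady-state parameters are read off.
REFERENCE_WINDOW = (192.0, 216.0)

DEFAULT_HORIZON = 216.0
#: Longer horizon for analyses that follow the profile past day 9
#: (recovery after omission, hangover after discontinuation).
LONG_HORIZON = 504.0


@dataclass(frozen=True)
class DoseEvent:
    time: float    # h since treatment start
    amount: float  # µg

    def __post_init__(self) -> None:
        if self.time < 0 or self.amount < 0:
            raise ConfigError("dose event time and amount must be non-negative")


@dataclass(frozen=True)
class Regimen:
    formulation: str
    tau: float
    events: tuple[DoseEvent, ...]
    scenario: str
    delay_fraction: float | None
    horizon: float

    @property
    def dose_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def last_dose_time(self) -> float:
        return self.events[-1].time if self.events else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Dose events as a (time_h, amount_ug) table."""
        return pd.DataFrame(
            {"time_h": [e.time for e in self.events],
             "amount_ug": [e.amount for e in self.events]}
        )


@dataclass(frozen=True)
class EvaluationWindows:
    reference_window: tuple[float, float]
    scenario_window: tuple[float, float]
    last_dose_time: float


def irregular_dose_time(tau: float) -> float:
    """Scheduled time of the dose affected by the irregularity.

    The last dose scheduled within day 8 ([168, 192) h): 180 h for tau=12,
    168 h for tau=24.
    """
    return float(tau * np.ceil(192.0 / tau) - tau)


def build_regimen(
    formulation: str,
    scenario: str,
    delay_fraction: float | None = None,
    horizon: float | None = None,
    dose_ug: float | None = None,
    tau: float | None = None,
) -> tuple[Regimen, EvaluationWindows]:
    """Construct the explicit dose-event list and evaluation windows.

    ``delay_fraction`` is required for the delay scenario and must lie in
    (0, 1]; the study grid uses 0.25, 0.5, 0.75 and 1.0.
    """
    if formulation not in FORMULATIONS:
        raise ConfigError(f"unknown formulation {formulation!r}")
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    spec = FORMULATIONS[formulation]
    dose = spec["dose_ug"] if dose_ug is None else float(dose_ug)
    tau = spec["tau"] if tau is None else float(tau)

    if scenario == "delay":
        if delay_fraction is None or not (0.0 < delay_fraction <= 1.0):
            raise ConfigError("delay_fraction must lie in (0, 1] for the delay scenario")
    elif delay_fraction is not None:
        raise ConfigError("delay_fraction only applies to the delay scenario")

    if horizon is None:
        horizon = LONG_HORIZON if scenario in ("omission", "discontinuation") else DEFAULT_HORIZON

    t_irr = irregular_dose_time(tau)
    times = [(t, dose) for t in np.arange(0.0, horizon, tau)]

    if scenario == "delay":
        times = [(t, a) for t, a in times if t != t_irr]
        times.append((t_irr + delay_fraction * tau, dose))
    elif scenario == "omission":
        times = [(t, a) for t, a in times if t != t_irr]
    elif scenario == "doubling":
        times = [(t, 2 * a) if t == t_irr else (t, a) for t, a in times]
    elif scenario == "discontinuation":
        times = [(t, a) for t, a in times if t <= t_irr]

    times.sort(key=lambda ta: ta[0])
    events = tuple(DoseEvent(float(t), float(a)) for t, a in times)
    regimen = Regimen(
        formulation=formulation,
        tau=tau,
        events=events,
        scenario=scenario,
        delay_fraction=delay_fraction,
        horizon=float(horizon),
    )
    return regimen, evaluation_windows(regimen)


def evaluation_windows(regimen: Regimen) -> EvaluationWindows:
    """Day-9 reference window plus the scenario-specific evaluation window."""
    t_irr = irregular_dose_time(regimen.tau)
    ref = REFERENCE_WINDOW
    if regimen.scenario == "omission":
        scen = (t_irr, ref[1])
    elif regimen.scenario == "discontinuation":
        scen = (t_irr, regimen.horizon)
    else:  # adherence, delay, doubling: after the next scheduled dose
        scen = ref
    return EvaluationWindows(
        reference_window=ref,
        scenario_window=scen,
        last_dose_time=regimen.last_dose_time,
    )
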