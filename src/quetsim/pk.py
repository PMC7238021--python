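"""One-compartment, first-order absorption/elimination concentration engine.

A single oral dose D (µg) into a compartment of volume V (L) with absorption
rate ka and elimination rate ke (both 1/h) gives

    Cp(t) = D * ka / (V * (ka - ke)) * (exp(-ke t) - exp(-ka t)),

with the continuous limit D * ka * t * exp(-ka t) / V as ka → ke.  The model
is linear, so a multi-dose profile is the superposition of single-dose
contributions; steady state is reached by brute-force simulation from t = 0
rather than by a steady-state formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .population import Patient
from .regimen import Regimen

__all__ = [
    "ConcentrationProfile",
    "single_dose_cp",
    "concentration_profile",
    "population_concentrations",
    "time_grid",
    "DEFAULT_STEP",
]

DEFAULT_STEP = 0.05  # h; bounds peak-capture error well below printed precision

#: Below this |ka - ke| (1/h) the closed form is numerically unstable and the
#: ka = ke limit is used instead.
_KA_KE_TOL = 1e-6


@dataclass(frozen=True)
class ConcentrationProfile:
    """Plasma concentration (µg/L) on a uniform time grid (h)."""

    times: np.ndarray
    cp: np.ndarray
    patient_id: int = -1
    label: str = ""

    def __post_init__(self) -> None:
        if self.times.shape != self.cp.shape[-1:]:
            raise ContractError("times and cp grids do not match")


def time_grid(horizon: float, step: float = DEFAULT_STEP) -> np.ndarray:
    """Uniform grid [0, horizon] inclusive of both ends."""
    n = int(round(horizon / step))
    return np.linspace(0.0, n * step, n + 1)


def single_dose_cp(t_since_dose, dose: float, ka: float, ke: float, v: float):
    """Concentration after one dose; vectorised over ``t_since_dose``.

    Negative times raise; ka, ke, v must be positive.
    """
    t = np.asarray(t_since_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_dose must be non-negative")
    if min(ka, ke, v) <= 0:
        raise ValueError("ka, ke and v must be strictly positive")
    if abs(ka - ke) < _KA_KE_TOL:
        out = dose * ka * t * np.exp(-ka * t) / v
    else:
        out = dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return out if out.shape else float(out)


def concentration_profile(
    regimen: Regimen,
    patient: Patient,
    step: float = DEFAULT_STEP,
) -> ConcentrationProfile:
    """Superposed concentration profile for one patient under a regimen."""
    ka = patient.ka(regimen.formulation)
    times, cp = _superpose(
        regimen,
        np.array([ka]),
        np.array([patient.ke]),
        np.array([patient.v]),
        step,
    )
    return ConcentrationProfile(
        times=times,
        cp=cp[0],
        patient_id=patient.id,
        label=f"{regimen.formulation}:{regimen.scenario}",
    )


def population_concentrations(
    regimen: Regimen,
    ka: np.ndarray,
    ke: np.ndarray,
    v: np.ndarray,
    step: float = DEFAULT_STEP,
) -> tuple[np.ndarray, np.ndarray]:
    """Profiles for a whole cohort at once.

    Returns ``(times, cp)`` with ``cp`` of shape (n_patients, n_times).
    """
    return _superpose(regimen, np.asarray(ka, float), np.asarray(ke, float),
                      np.asarray(v, float), step)


def _superpose(
    regimen: Regimen,
    ka: np.ndarray,
    ke: np.ndarray,
    v: np.ndarray,
    step: float,
) -> tuple[np.ndarray, np.ndarray]:
    if step <= 0:
        raise ValueError("step must be positive")
    times = time_grid(regimen.horizon, step)
    cp = np.zeros((ka.size, times.size))

    near = np.abs(ka - ke) < _KA_KE_TOL
    amp = np.empty_like(ka)
    amp[~near] = ka[~near] / (v[~near] * (ka[~near] - ke[~near]))

    for event in regimen.events:
        if event.amount == 0.0:
            continue
        i0 = int(np.searchsorted(times, event.time - 1e-9))
        dt = times[i0:] - event.time
        dt[dt < 0] = 0.0
        if np.any(~near):
            sel = ~near
            cp[sel, i0:] += (
                event.amount
                * amp[sel, None]
                * (np.exp(-np.outer(ke[sel], dt)) - np.exp(-np.outer(ka[sel], dt)))
            )
        if np.any(near):
            sel = near
            cp[sel, i0:] += (
                event.amount
                * (ka[sel] / v[sel])[:, None]
                * dt[None, :]
                * np.exp(-np.outer(ka[sel], dt))
            )
    if not np.all(np.isfinite(cp)):
        bad = np.where(~np.isfinite(cp).all(axis=1))[0]
        raise ContractError(f"non-finite concentration for patient index {bad[0]}")
    return times, cp
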