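"""Per-patient summary parameters read off the simulated profiles.

Steady-state parameters are evaluated over the day-9 window after the next
scheduled dose.  Peak values (Cmax, peak % reduction) are plain grid maxima
over the window.  Trough values (Cmin, trough % reduction) are read at the
pre-dose time points: the profile value at each dose time strictly inside
the window together with the window end point.  This matches the clinical
notion of a trough and keeps the transient undershoot just before a 100 %
delayed dose — administered exactly at the window start — out of the
trough, while the omission window (which opens at the skipped dose's
scheduled time) retains its undershoot because the resumption dose falls
strictly inside it.

All functions accept a 1-D profile or an (n_patients, n_times) matrix and
reduce along the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .response import RESPONSE_THRESHOLD_PCT

__all__ = [
    "window_extrema",
    "trough_minimum",
    "delta_parameters",
    "recovery_time",
    "therapeutic_duration_and_hangover",
    "risk_outcomes",
    "CONCENTRATION_CEILING",
]

#: Upper bound of the quetiapine therapeutic window (µg/L).
CONCENTRATION_CEILING = 500.0


def _window_indices(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    if not (start < end):
        raise ContractError("window start must precede end")
    idx = np.nonzero((times >= start - 1e-9) & (times <= end + 1e-9))[0]
    if idx.size == 0:
        raise ContractError("window contains no grid points")
    return idx


def window_extrema(
    times: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
):
    """(max, min, t_at_max, t_at_min) over grid points inside the window."""
    idx = _window_indices(times, window)
    seg = np.asarray(values)[..., idx]
    imax = np.argmax(seg, axis=-1)
    imin = np.argmin(seg, axis=-1)
    vmax = np.take_along_axis(seg, np.expand_dims(imax, -1), axis=-1)[..., 0]
    vmin = np.take_along_axis(seg, np.expand_dims(imin, -1), axis=-1)[..., 0]
    return vmax, vmin, times[idx][imax], times[idx][imin]


def trough_minimum(
    times: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float],
    dose_times: np.ndarray,
) -> np.ndarray:
    """Trough value: minimum over pre-dose points inside the window.

    Candidates are the profile values at each dose time strictly inside
    (start, end) — the instantaneous-input model makes the value at a dose
    time the pre-dose value — plus the window end point.
    """
    start, end = window
    dose_times = np.asarray(dose_times, float)
    interior = dose_times[(dose_times > start + 1e-9) & (dose_times < end - 1e-9)]
    candidates = np.unique(np.concatenate([interior, [end]]))
    cols = np.searchsorted(times, candidates - 1e-9)
    if np.any(cols >= times.size):
        raise ContractError("trough candidate time beyond the grid")
    return np.min(np.asarray(values)[..., cols], axis=-1)


def delta_parameters(scenario: dict, reference: dict) -> dict:
    """Signed % change of each summary parameter vs the adherent reference.

    ``100 * (irregular - regular) / regular`` per parameter; entries with a
    non-positive reference are returned as NaN (undefined).
    """
    out = {}
    for key, scen_val in scenario.items():
        ref_val = np.asarray(reference[key], float)
        scen_val = np.asarray(scen_val, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(ref_val > 0, 100.0 * (scen_val - ref_val) / ref_val, np.nan)
        out[key] = delta if delta.shape else float(delta)
    return out


def recovery_time(
    times: np.ndarray,
    cp_omission: np.ndarray,
    cp_adherent: np.ndarray,
    t0: float,
    rel_tol: float = 0.05,
):
    """Time to rejoin the adherent steady-state profile after an omission.

    Smallest t* with |cp_omit - cp_adh| / cp_adh <= rel_tol for every grid
    point t >= t*, reported relative to ``t0`` (the omitted dose's
    scheduled time).  Returns ``(hours, censored)``; censored entries are
    set to ``horizon - t0``.
    """
    cp_adherent = np.asarray(cp_adherent, float)
    cp_omission = np.asarray(cp_omission, float)
    after_first = times > 0
    if np.any(cp_adherent[..., after_first] <= 0):
        raise ContractError("adherent concentration must be positive past the first dose")
    rel = np.zeros_like(cp_adherent)
    rel[..., after_first] = np.abs(
        cp_omission[..., after_first] - cp_adherent[..., after_first]
    ) / cp_adherent[..., after_first]
    outside = rel > rel_tol
    # index of the last violation; -1 when the band is never left
    rev_first = np.argmax(outside[..., ::-1], axis=-1)
    any_out = np.any(outside, axis=-1)
    last = np.where(any_out, times.size - 1 - rev_first, -1)
    censored = outside[..., -1]
    t_star = np.where(any_out, times[np.minimum(last + 1, times.size - 1)], 0.0)
    hours = np.clip(t_star - t0, 0.0, None)
    hours = np.where(censored, times[-1] - t0, hours)
    if hours.shape:
        return hours, censored
    return float(hours), bool(censored)


def therapeutic_duration_and_hangover(
    times: np.ndarray,
    profile: np.ndarray,
    last_dose_time: float,
    tau: float,
    threshold: float = RESPONSE_THRESHOLD_PCT,
):
    """Duration of therapeutic response after the last dose, and its
    overshoot past one dosing interval.

    ``profile`` is whichever trajectory defines "therapeutic": the default
    study convention compares the concentration profile against the fixed
    borderline concentration for a 14 % BPRS reduction (the horizontal
    line of the hangover analysis); passing the % reduction profile with
    the 14 % threshold applies the time-varying BPRS criterion instead.

    duration = first time at or after the last dose with the profile below
    the threshold, minus the last dose time (0 for patients already
    sub-therapeutic at the last dose; censored at the horizon when the
    response never lapses).  hangover = duration - tau, signed; histogram
    consumers clamp it at 0.

    Returns ``(duration, hangover, censored)``.
    """
    pct = np.asarray(profile, float)
    threshold_pct = threshold
    i0 = int(np.searchsorted(times, last_dose_time - 1e-9))
    below = pct[..., i0:] < threshold_pct
    first = np.argmax(below, axis=-1)
    lapses = np.any(below, axis=-1)
    duration = np.where(lapses, times[i0 + first] - last_dose_time,
                        times[-1] - last_dose_time)
    censored = ~lapses
    hangover = duration - tau
    if duration.shape:
        return duration, hangover, censored
    return float(duration), float(hangover), bool(censored)


def risk_outcomes(
    times: np.ndarray,
    cp: np.ndarray,
    pct_reduction: np.ndarray,
    window: tuple[float, float],
    dose_times: np.ndarray,
    low_threshold_pct: float = RESPONSE_THRESHOLD_PCT,
    high_threshold: float = CONCENTRATION_CEILING,
):
    """Binary window outcomes: sub-therapeutic response and excessive peak.

    event_low: trough % reduction in the window below the 14 % borderline.
    event_high: peak concentration in the window above 500 µg/L.
    """
    pct_trough = trough_minimum(times, pct_reduction, window, dose_times)
    cmax = window_extrema(times, cp, window)[0]
    return pct_trough < low_threshold_pct, cmax > high_threshold
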