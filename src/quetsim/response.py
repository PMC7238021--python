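"""BPRS response model: linear placebo drift plus Emax drug inhibition.

    BPRS(t) = BPRS0 + alpha * t - Emax * Cp(t) / (EC50 + Cp(t))

with time measured from treatment start.  The reported response metric is
the percent reduction from baseline,

    pct_reduction(t) = 100 * (BPRS0 - BPRS(t)) / BPRS0,

and a reduction of at least 14 % is taken as a genuine (beyond-placebo)
therapeutic response.  BPRS values are not clamped at zero; the trial
runner records the fraction of patients whose trajectory goes negative as
a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .pk import ConcentrationProfile
from .population import Patient

__all__ = [
    "ResponseProfile",
    "bprs_profile",
    "population_pct_reduction",
    "threshold_concentration",
    "RESPONSE_THRESHOLD_PCT",
]

#: Percent reduction in BPRS from baseline regarded as a true drug response.
RESPONSE_THRESHOLD_PCT = 14.0


@dataclass(frozen=True)
class ResponseProfile:
    """BPRS score and % reduction from baseline on the PK time grid."""

    times: np.ndarray
    bprs: np.ndarray
    pct_reduction: np.ndarray

    def __post_init__(self) -> None:
        if not (self.times.shape == self.bprs.shape[-1:] == self.pct_reduction.shape[-1:]):
            raise ContractError("response grids do not match")


def bprs_profile(conc: ConcentrationProfile, patient: Patient) -> ResponseProfile:
    """Map one concentration profile to the patient's BPRS trajectory."""
    t = conc.times
    drug = patient.emax * conc.cp / (patient.ec50 + conc.cp)
    bprs = patient.bprs0 + patient.alpha * t - drug
    pct = 100.0 * (patient.bprs0 - bprs) / patient.bprs0
    return ResponseProfile(times=t, bprs=bprs, pct_reduction=pct)


def population_pct_reduction(
    times: np.ndarray,
    cp: np.ndarray,
    bprs0: np.ndarray,
    alpha: np.ndarray,
    emax: np.ndarray,
    ec50: np.ndarray,
) -> np.ndarray:
    """% reduction from baseline for a cohort; cp of shape (n, n_times)."""
    if cp.shape[-1] != times.size:
        raise ContractError("cp and times grids do not match")
    drug = emax[:, None] * cp / (ec50[:, None] + cp)
    return 100.0 * (drug - alpha[:, None] * times[None, :]) / bprs0[:, None]


def threshold_concentration(
    patient: Patient,
    t_ref: float,
    threshold_pct: float = RESPONSE_THRESHOLD_PCT,
) -> float | None:
    """Plasma concentration at which the % reduction equals the threshold.

    The placebo term is evaluated at ``t_ref`` (hours from treatment
    start).  Returns 0.0 when the placebo effect alone already meets the
    threshold and ``None`` when the required drug effect exceeds Emax
    (threshold unreachable).
    """
    if t_ref < 0:
        raise ValueError("t_ref must be non-negative")
    required = threshold_pct / 100.0 * patient.bprs0 + patient.alpha * t_ref
    if required <= 0:
        return 0.0
    if required >= patient.emax:
        return None
    return patient.ec50 * required / (patient.emax - required)
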