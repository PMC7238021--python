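"""Population-level comparisons: Kolmogorov–Smirnov tests and odds ratios.

The two study arms (XR vs IR) are compared per summary parameter with the
two-sample KS test (asymptotic p-values), and per binary risk outcome with
the odds ratio from the 2×2 outcome table.  For a single binary arm
indicator the closed-form 2×2 odds ratio is algebraically identical to
exp(beta) from a binomial GLM with a logit link, which is how the odds
ratios are defined; the GLM route is exercised as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ContractError

__all__ = ["KSResult", "ORResult", "ks_two_sample", "odds_ratio", "average_odds_ratio"]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class KSResult:
    d: float
    p: float
    n1: int
    n2: int


@dataclass(frozen=True)
class ORResult:
    or_point: float
    ci_low: float
    ci_high: float
    #: 2×2 counts (events, non-events) × (XR, IR)
    table: tuple[float, float, float, float]
    corrected: bool = False  # Haldane–Anscombe +0.5 applied


def ks_two_sample(x, y) -> KSResult:
    """Two-sample KS statistic and asymptotic p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ContractError("KS test needs at least two observations per sample")
    res = sps.ks_2samp(x, y, method="asymp")
    return KSResult(d=float(res.statistic), p=float(res.pvalue), n1=x.size, n2=y.size)


def odds_ratio(events_xr: int, n_xr: int, events_ir: int, n_ir: int) -> ORResult:
    """Odds ratio of the outcome on XR versus IR, with a Wald 95 % CI.

    A Haldane–Anscombe correction (+0.5 to every cell) is applied when any
    cell of the 2×2 table is zero.
    """
    if n_xr < 1 or n_ir < 1:
        raise ContractError("arm sizes must be at least 1")
    if not (0 <= events_xr <= n_xr and 0 <= events_ir <= n_ir):
        raise ContractError("event counts must lie within their arm sizes")
    a, b = float(events_xr), float(n_xr - events_xr)
    c, d = float(events_ir), float(n_ir - events_ir)
    if (a + c == 0 and b + d == 0):
        raise ContractError("degenerate all-zero table")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_point) + np.array([-1, 1]) * _Z975 * se)
    return ORResult(
        or_point=float(or_point),
        ci_low=float(lo),
        ci_high=float(hi),
        table=(a, b, c, d),
        corrected=corrected,
    )


def average_odds_ratio(results: list[ORResult]) -> ORResult:
    """Mean odds ratio and mean CI bounds across replicate virtual trials."""
    if not results:
        raise ContractError("no replicate odds ratios to average")
    table = tuple(float(np.mean([r.table[i] for r in results])) for i in range(4))
    return ORResult(
        or_point=float(np.mean([r.or_point for r in results])),
        ci_low=float(np.mean([r.ci_low for r in results])),
        ci_high=float(np.mean([r.ci_high for r in results])),
        table=table,  # type: ignore[arg-type]
        corrected=any(r.corrected for r in results),
    )
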