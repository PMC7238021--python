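"""Virtual patient population sampling.

Each virtual patient carries a full set of one-compartment PK parameters
(elimination rate ``ke``, formulation-specific absorption rates ``ka_ir`` /
``ka_xr``, distribution volume ``v``) and BPRS response parameters (baseline
score ``bprs0``, placebo slope ``alpha``, maximum drug effect ``emax``,
half-maximal concentration ``ec50``).  Between-subject variability is
log-normal on every parameter except the placebo slope, which is normal;
all random effects are drawn independently.

The printed population volume term admits two readings, selected by
``v_mode``:

``cl_derived`` (default)
    The printed 73.7 is interpreted as an apparent clearance (L/h); the
    typical volume is ``73.7 / 0.12`` ≈ 614.2 L, which reproduces the
    reported typical plasma concentrations (single-dose IR peak ≈ 260 µg/L,
    steady-state IR range ≈ 110–350 µg/L).
``as_printed``
    The typical volume is taken literally as 73.7 L.

All percent-change (Δ) metrics downstream are invariant to this choice;
absolute concentrations and therefore the PD-linked metrics are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = [
    "PKPopulationSpec",
    "PDPopulationSpec",
    "Patient",
    "sample_patients",
    "typical_patient",
    "patients_to_frame",
]


@dataclass(frozen=True)
class PKPopulationSpec:
    """Population PK hyperparameters: log-scale medians and between-subject SDs."""

    mu_ke: float = 0.12          # 1/h
    mu_ka_ir: float = 1.46       # 1/h
    mu_ka_xr: float = 0.15       # 1/h
    mu_v: float = 73.7           # printed value; interpretation set by v_mode
    sd_ln_ke: float = 0.40
    sd_ln_ka_ir: float = 0.75
    sd_ln_ka_xr: float = 1.50
    sd_ln_v: float = 0.47
    v_mode: str = "cl_derived"

    def __post_init__(self) -> None:
        for name in ("mu_ke", "mu_ka_ir", "mu_ka_xr", "mu_v"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("sd_ln_ke", "sd_ln_ka_ir", "sd_ln_ka_xr", "sd_ln_v"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.v_mode not in ("cl_derived", "as_printed"):
            raise ConfigError(f"unknown v_mode {self.v_mode!r}")

    @property
    def typical_v(self) -> float:
        """Typical distribution volume in litres under the selected v_mode."""
        if self.v_mode == "cl_derived":
            return self.mu_v / self.mu_ke
        return self.mu_v


@dataclass(frozen=True)
class PDPopulationSpec:
    """Population BPRS-response hyperparameters.

    ``bprs0``, ``emax`` and ``ec50`` are log-normal (parameters on the
    natural-log scale); the placebo slope ``alpha`` is normal in points/h
    and may be negative (symptoms improving under placebo).

    The default SDs are the square roots of the source model's
    between-subject variance terms (0.27, 0.0001, 0.41, 1.77), following
    the variance (omega-squared) reporting convention of nonlinear
    mixed-effects PD models.  Reading those numbers directly as SDs is
    possible by overriding the fields (it makes the placebo slope nearly
    deterministic, CV ≈ 1 %, and greatly over-disperses EC50).
    """

    mu_ln_bprs0: float = 3.65
    sd_ln_bprs0: float = 0.5196152422706632    # sqrt(0.27)
    mu_alpha: float = -0.008     # points/h
    sd_alpha: float = 0.01       # points/h, sqrt(0.0001)
    mu_ln_emax: float = 2.2
    sd_ln_emax: float = 0.6403124237432849     # sqrt(0.41)
    mu_ln_ec50: float = 4.42     # ln(µg/L)
    sd_ln_ec50: float = 1.3304134695650072     # sqrt(1.77)

    def __post_init__(self) -> None:
        for name in ("sd_ln_bprs0", "sd_alpha", "sd_ln_emax", "sd_ln_ec50"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Patient:
    """One virtual subject's parameter set, shared across formulations
    except for the absorption rate constant."""

    id: int
    ke: float        # 1/h
    ka_ir: float     # 1/h
    ka_xr: float     # 1/h
    v: float         # L
    bprs0: float     # points
    alpha: float     # points/h
    emax: float      # points
    ec50: float      # µg/L

    def ka(self, formulation: str) -> float:
        """Absorption rate constant for the given formulation ('IR' or 'XR')."""
        if formulation == "IR":
            return self.ka_ir
        if formulation == "XR":
            return self.ka_xr
        raise ConfigError(f"unknown formulation {formulation!r}")


# Sampling order is part of the reproducibility contract: changing it would
# silently change every seeded trial.
_SAMPLING_ORDER = ("ke", "ka_ir", "ka_xr", "v", "bprs0", "alpha", "emax", "ec50")


def sample_parameter_arrays(
    pk_spec: PKPopulationSpec,
    pd_spec: PDPopulationSpec,
    n: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Sample ``n`` patients' parameters as a dict of float arrays.

    Vectorised workhorse behind :func:`sample_patients`; the trial runner
    consumes the arrays directly.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    lognormals = {
        "ke": (np.log(pk_spec.mu_ke), pk_spec.sd_ln_ke),
        "ka_ir": (np.log(pk_spec.mu_ka_ir), pk_spec.sd_ln_ka_ir),
        "ka_xr": (np.log(pk_spec.mu_ka_xr), pk_spec.sd_ln_ka_xr),
        "v": (np.log(pk_spec.typical_v), pk_spec.sd_ln_v),
        "bprs0": (pd_spec.mu_ln_bprs0, pd_spec.sd_ln_bprs0),
        "emax": (pd_spec.mu_ln_emax, pd_spec.sd_ln_emax),
        "ec50": (pd_spec.mu_ln_ec50, pd_spec.sd_ln_ec50),
    }
    for name in _SAMPLING_ORDER:
        if name == "alpha":
            out[name] = rng.normal(pd_spec.mu_alpha, pd_spec.sd_alpha, size=n)
        else:
            mu, sd = lognormals[name]
            out[name] = np.exp(rng.normal(mu, sd, size=n))
    return out


def sample_patients(
    pk_spec: PKPopulationSpec,
    pd_spec: PDPopulationSpec,
    n: int,
    seed: int,
) -> list[Patient]:
    """Draw ``n`` independent virtual patients (deterministic given ``seed``)."""
    arrays = sample_parameter_arrays(pk_spec, pd_spec, n, seed)
    return [
        Patient(id=i, **{k: float(arrays[k][i]) for k in _SAMPLING_ORDER})
        for i in range(n)
    ]


def typical_patient(
    pk_spec: PKPopulationSpec | None = None,
    pd_spec: PDPopulationSpec | None = None,
) -> Patient:
    """The zero-random-effect patient (all parameters at their typical values)."""
    pk_spec = pk_spec or PKPopulationSpec()
    pd_spec = pd_spec or PDPopulationSpec()
    return Patient(
        id=-1,
        ke=pk_spec.mu_ke,
        ka_ir=pk_spec.mu_ka_ir,
        ka_xr=pk_spec.mu_ka_xr,
        v=pk_spec.typical_v,
        bprs0=float(np.exp(pd_spec.mu_ln_bprs0)),
        alpha=pd_spec.mu_alpha,
        emax=float(np.exp(pd_spec.mu_ln_emax)),
        ec50=float(np.exp(pd_spec.mu_ln_ec50)),
    )


def patients_to_frame(patients: list[Patient]) -> pd.DataFrame:
    """One row per patient, columns as in :class:`Patient` (CSV-exportable)."""
    cols = [f.name for f in fields(Patient)]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in patients])
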