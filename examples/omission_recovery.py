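"""Recovery of the steady state after a completely missed dose.

Simulates the omission of the last day-8 dose (IR 180 h, XR 168 h) with
regular dosing resumed at 192 h, and measures how long each patient's
profile takes to rejoin their own adherent steady-state profile within a
1% band.
"""

import numpy as np

from quetsim import (
    StudyConfig,
    build_regimen,
    concentration_profile,
    recovery_time,
    run_trial,
    typical_patient,
)
from quetsim.regimen import irregular_dose_time

patient = typical_patient()
for formulation in ("IR", "XR"):
    reg_a, _ = build_regimen(formulation, "adherence", horizon=504.0)
    reg_o, _ = build_regimen(formulation, "omission")
    conc_a = concentration_profile(reg_a, patient)
    conc_o = concentration_profile(reg_o, patient)
    t0 = irregular_dose_time(reg_a.tau)
    hours, _ = recovery_time(conc_a.times, conc_o.cp, conc_a.cp, t0, rel_tol=0.01)
    print(f"{formulation}: typical patient rejoins steady state {hours:.1f} h "
          f"after the omitted {t0:.0f} h dose")

result = run_trial(StudyConfig(n_patients=200, seed=11))
for _, row in result.outcomes.iterrows():
    print(f"{row.formulation}: {100 * row.prop_recovery_lt_48h:.1f}% of 200 patients "
          f"recover in <48 h (median {row.median_recovery_h:.0f} h)")

print("\nThe faster-absorbing IR formulation clears the perturbation of a "
      "missed dose much sooner; most XR patients need more than two days to "
      "re-establish their steady state.")
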