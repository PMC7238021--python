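# quetsim

Monte-Carlo virtual trials of quetiapine dose non-adherence: what happens,
pharmacokinetically and clinically, when a schizophrenia patient on
immediate-release (IR, 200 mg every 12 h) or extended-release (XR,
400 mg every 24 h) quetiapine delays, skips, doubles, or stops a dose?

The package is for pharmacometricians and drug-delivery researchers who
want to compare the *forgiveness* of dosing regimens by simulation rather
than by (infeasible) clinical experimentation. It simulates populations of
virtual patients from published population PK and PD models, perturbs a
single dose at steady state, and quantifies the consequences as summary
tables, risk odds ratios, and hangover/recovery-time distributions.

## Model

Plasma concentration follows a one-compartment model with first-order
absorption and elimination; multi-dose profiles are the superposition of
single-dose terms

```
Cp(t) = Σ_doses  D·ka / (V·(ka − ke)) · (e^{−ke·(t−td)} − e^{−ka·(t−td)})
```

with `ke = 0.12 h⁻¹`, `ka = 1.46 h⁻¹` (IR) or `0.15 h⁻¹` (XR), and
`V ≈ 614 L` for the typical patient. The clinical response (Brief
Psychiatric Rating Scale, BPRS) combines a linear placebo drift with an
Emax inhibition term:

```
BPRS(t) = BPRS₀ + α·t − Emax·Cp(t) / (EC50 + Cp(t))
```

with typical `BPRS₀ = e^{3.65} ≈ 38.5` points, `α = −0.008` points/h,
`Emax = e^{2.2} ≈ 9.0` points and `EC50 = e^{4.42} ≈ 83` µg/L. Virtual
patients get independent log-normal between-subject variability on every
parameter (normal for α). A reduction of BPRS ≥ 14 % from baseline counts
as a genuine therapeutic response; 50–500 µg/L is the plasma therapeutic
window.

Each virtual trial doses 1000 patients regularly to steady state (days
7–9), applies one dose irregularity on day 8, resumes regular dosing on
day 9, and evaluates peak/trough concentration and BPRS response in the
day-9 window against each patient's own adherent reference.

## Worked example

```python
from quetsim import StudyConfig, run_trial

result = run_trial(StudyConfig(n_patients=200, seed=7))
t = result.delay_table
row = t[(t.parameter == "delta_cmax") & (t.delay_fraction == 1.0)].iloc[0]
print(row.ir_label, row.xr_label, row.ks_p)
```

prints `51.1(0.3) 48.2(0.7) 1.88e-06`: delaying one dose by a full dosing
interval raises the day-9 peak concentration by ~51 % (mean, CV 0.3) on IR
and ~48 % on XR, and the two distributions differ significantly
(Kolmogorov–Smirnov p < 0.05). `examples/` contains one narrative script
per capability:

- `typical_profiles.py` — typical steady-state PK/PD landmarks,
- `dose_delay_table.py` — the delay table at small scale,
- `omission_recovery.py` — steady-state recovery after a missed dose,
- `discontinuation_hangover.py` — therapeutic duration and hangover,
- `risk_odds_panel.py` — XR-vs-IR odds ratios of leaving the window.

A thin CLI wraps the same pipeline: `quetsim simulate --n 1000 --seed 1
--out results/` writes all result tables as CSV; `quetsim profiles`
exports a typical-patient profile.

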