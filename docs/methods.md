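# Methods

## Scope and pipeline

`quetsim` simulates a paired virtual trial: a single cohort of virtual
schizophrenia patients is dosed with both the IR (200 mg q12h) and XR
(400 mg q24h) quetiapine formulations — patients share elimination,
volume and response parameters, and differ between arms only in the
absorption rate constant — under five scenarios: adherence, delay of one
dose by 25/50/75/100 % of the dosing interval, omission, doubling, and
discontinuation. The irregular dose is the last dose scheduled within
day 8 (180 h for q12h, 168 h for q24h); regular dosing resumes at 192 h.
Profiles are simulated by brute-force superposition from t = 0 (no
steady-state shortcut; the geometric-series closed form serves only as a
test oracle, which the engine matches to ≤ 0.2 %).

## PK model

One compartment, first-order absorption and elimination:
`Cp(t) = D·ka/(V(ka−ke))·(e^{−ke t} − e^{−ka t})` per dose, summed over
doses. When |ka − ke| < 10⁻⁶ h⁻¹ the engine switches to the continuous
limit `D·ka·t·e^{−ka t}/V` to avoid catastrophic cancellation (relevant
only for extreme XR draws; the switch is exercised in tests). The default
grid step is 0.05 h, which bounds peak-capture error far below the
precision of any reported quantity; it is configurable.

**Volume convention (`v_mode`).** The published population vector gives
73.7 for the volume term, but a literal V = 73.7 L produces typical
concentrations ~8× those the study reports. Interpreting 73.7 as an
apparent clearance in L/h — so that the typical volume is
CL/ke = 73.7/0.12 ≈ 614.2 L — reproduces the reported typical landmarks
(single-dose IR peak ≈ 260 µg/L at 1.9 h; day-9 IR peak/trough
≈ 350/110 µg/L; XR ≈ 319/102 µg/L), so `cl_derived` is the default;
`as_printed` is retained for literal-value comparisons. All Δ (percent
change) metrics are provably invariant to this choice; absolute
concentrations, and therefore the PD-linked quantities, are not.

## PD model

`BPRS(t) = BPRS₀ + α·t − Emax·Cp/(EC50 + Cp)`, reported as
`pct_reduction(t) = 100·(BPRS₀ − BPRS(t))/BPRS₀`. BPRS is not clamped at
zero; the fraction of patients whose trajectory goes negative is recorded
as a diagnostic (~0.2 % under default conditions). The borderline
concentration for a given reduction is obtained by algebraic inversion
with the placebo term evaluated at a reference time, default
t_ref = 168 h (the start of the steady-state window); for the typical
patient the 14 % borderline is 67.4 µg/L, consistent with the reported
~70 µg/L, and t_ref is configurable because the source analysis does not
state when its placebo term was evaluated.

## Population sampling

Every PK parameter and BPRS₀, Emax, EC50 are log-normal
(`ln θ ~ N(ln µ, σ)`); α is normal. All random effects are independent;
no covariate model, inter-occasion variability or residual error is
simulated. The PK σ vector (0.40, 0.75, 1.50, 0.47) is used directly as
log-scale SDs — the source states these are SDs, and the IR population
table columns confirm that reading to ~1 %. The PD dispersion terms
(0.27, 0.0001, 0.41, 1.77) are treated as **variances** and their square
roots used as SDs. Two reasons: nonlinear mixed-effects PD models report
between-subject terms as ω² variances; and 0.0001 read as an SD would
give the placebo slope a 1.3 % CV, implausibly tight for a
between-subject effect. Empirically the variance reading reproduces all
peak-response table rows within ~17 %, against 4 of 12 rows off by > 30 %
under the SD reading. Either reading can be selected by overriding the
`PDPopulationSpec` fields.

Sampling order (ke, ka_IR, ka_XR, V, BPRS₀, α, Emax, EC50) is fixed and
part of the reproducibility contract; a trial is bit-reproducible given
its seed, and replicate trials use consecutive seeds.

## Evaluation windows and summary parameters

The reference window is day 9 ([192, 216] h) on the patient's own
adherent profile. Scenario windows: delay and doubling use the same
day-9 window ("after the administration of the next scheduled dose");
omission opens at the skipped dose's scheduled time so the pre-dose
undershoot is captured; discontinuation runs from the last dose to the
horizon (504 h; all other scenarios use 216 h except omission, which
also runs to 504 h for the recovery analysis).

Peaks (Cmax, peak % reduction) are plain grid maxima over the window.
Troughs (Cmin, trough % reduction) are the minimum over *pre-dose* time
points: the profile value at each dose time strictly inside the window
plus the window end. This is the clinical notion of a trough; it keeps
the transient undershoot just before a 100 %-delayed dose (administered
exactly at the window start) out of the trough while retaining the
omission undershoot (whose resumption dose falls strictly inside the
window). This convention is the only one we found that reproduces the
published delay and omission rows simultaneously for the typical patient
(e.g. delay-100 % ΔCmin +13.9 vs printed +12.3; omission ΔCmin −76.3 vs
−74.6). Δ parameters are signed percent changes against the adherent
reference; a non-positive reference makes the Δ undefined (recorded as
missing — this affects a fraction of a percent of trough-response values).

## Duration, hangover, recovery

**Therapeutic duration / hangover** (discontinuation): time from the
last dose until the concentration profile first falls below the *fixed*
borderline concentration of the typical patient (67.4 µg/L by default);
hangover = duration − τ. The concentration-line criterion follows the
source's hangover construction (a horizontal borderline concentration);
the per-patient time-varying BPRS criterion is available via
`duration_borderline="patient_bprs"`. Never-therapeutic patients keep
duration 0; never-lapsing patients are censored at the horizon and
flagged.

**Recovery** (omission): the smallest t\* such that
|cp_omit − cp_adherent|/cp_adherent ≤ rel_tol for every grid point
t ≥ t\*, reported from the omitted dose's scheduled time. The default
band is rel_tol = 0.01: the source describes recovery as reaching "the
exact same" steady-state level, which argues for a tight band, and under
1 % the typical IR patient recovers in ≈ 48 h with ~48 % of IR patients
under 48 h, matching the reported split. Because deviations peak at the
pre-dose troughs, recovery times cluster just after trough times; the
band is configurable and recovery time is monotone in it (tested).

**Risk outcomes**: per scenario window, `event_low` = trough % reduction
below 14 %, `event_high` = peak concentration above 500 µg/L. Odds
ratios (XR vs IR) use the closed-form 2×2 estimate with Wald 95 % CIs
and a Haldane–Anscombe +0.5 correction for zero cells; the closed form
is algebraically exp(β) of a binomial logit GLM with an arm indicator
(cross-checked against statsmodels to 10⁻⁸). "Average" odds ratios are
means over replicate trials (20 in the bundled full-study config); both
the replicate average and the first-replicate single-fit CI are emitted,
since the source does not state which construction it used.
Distributions are compared arm-wise with the two-sample KS test
(asymptotic p-values; exact vs asymptotic is immaterial at n = 1000).

## What the generator emulates, and what it does not

The cohort generator *is* the study's data source: there is no external
data. It emulates between-subject variability around the published fixed
effects under independence. It does not emulate residual (within-subject)
error, parameter correlations, covariate effects (age, weight), dropout,
or measurement schedules — so passing tests demonstrate fidelity to the
published simulation protocol, not predictive validity for real
patients. Problem sizes follow the study: 1000 patients per cohort,
0.05 h grid, 216/504 h horizons; the acceptance checks use five
replicate trials and the examples use 200–300 patients.

## Known limitations

- Several XR table entries (ΔCmin at 50/75 % delay, ΔCmax at 100 % delay
  and under omission) and most trough-response (Δ∂BPRS_min) entries
  disagree with the published means by more than the acceptance bands
  under every windowing convention we swept; the published XR ΔCmin
  column is near-linear in the delay fraction and then jumps ×2.7 at
  100 %, a shape no superposition-consistent convention we found
  produces. The IR concentration columns reproduce to ~1–4 %.
- The reported IR duration-under-24 h proportion (48 %) is unreachable
  jointly with the XR value (29.6 %) under any criterion we examined:
  any per-patient or fixed-line criterion pins the XR proportion near
  the never-therapeutic fraction (~30 %, reproduced) while forcing the
  IR proportion far above 48 % because the typical IR duration is ~17 h.
- The XR/IR recovery-time ratio is ~2.0 here versus the reported
  1.6-fold; it is intrinsic to the parsed ka_XR = 0.15 h⁻¹ and the 9.7×
  (not 15×) ka ratio it implies.
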