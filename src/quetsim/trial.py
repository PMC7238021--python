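"""Virtual-trial orchestrator.

``run_trial`` samples the cohort, simulates every scenario for both
formulations, reduces each patient's profiles to summary parameters
against their own adherent reference, and aggregates the population into
the study's result tables:

- delay table: mean (CV) of the four Δ-parameters per delay fraction,
  with IR-vs-XR Kolmogorov–Smirnov p-values;
- omission/doubling table: the same for the two single-dose mistakes;
- odds-ratio panel: XR-vs-IR odds of a sub-therapeutic response
  (trough % reduction < 14 %) and of an excessive peak (> 500 µg/L),
  averaged over replicate trials;
- discontinuation/omission outcome summary: therapeutic-duration,
  hangover and recovery-time distributions.

The same cohort is reused across all scenarios and both formulations
(within-subject formulation switch); replicates draw fresh cohorts from
consecutive seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as mx
from .config import StudyConfig
from .errors import ConfigError
from .pk import population_concentrations
from .population import sample_parameter_arrays, typical_patient
from .regimen import LONG_HORIZON, build_regimen, irregular_dose_time
from .response import population_pct_reduction, threshold_concentration
from .stats import average_odds_ratio, ks_two_sample, odds_ratio

__all__ = ["TrialResult", "run_trial", "render_tables"]

DELTA_PARAMS = ("delta_cmax", "delta_cmin", "delta_dbprs_max", "delta_dbprs_min")

#: Scenarios entering the odds-ratio panel (the paper's risk analysis).
_OR_SCENARIOS = ("adherence", "delay", "omission", "doubling")


@dataclass
class TrialResult:
    config: StudyConfig
    patients: pd.DataFrame        # replicate-0 cohort
    summaries: pd.DataFrame       # one row per replicate x patient x arm x scenario
    delay_table: pd.DataFrame     # Table-1-like matrix
    mistake_table: pd.DataFrame   # Table-2-like matrix (omission, doubling)
    odds: pd.DataFrame            # OR panel per scenario x endpoint
    outcomes: pd.DataFrame        # duration / hangover / recovery summaries
    histograms: pd.DataFrame      # binned hangover and recovery distributions
    diagnostics: dict


def _scenario_specs(config: StudyConfig):
    specs = [("adherence", None)]
    specs += [("delay", f) for f in config.delay_fractions]
    specs += [("omission", None), ("doubling", None), ("discontinuation", None)]
    return specs


def _borderline_concentration(config: StudyConfig) -> float:
    """Fixed therapeutic borderline: the concentration giving the typical
    patient a 14 % BPRS reduction (placebo term at t_ref)."""
    c = threshold_concentration(
        typical_patient(config.pk, config.pd), config.t_ref, config.response_threshold_pct
    )
    if c is None:
        raise ConfigError("typical patient cannot reach the response threshold")
    return c


def _simulate_arm(config: StudyConfig, params: dict, formulation: str, replicate: int):
    """All scenarios for one formulation; returns per-patient summary rows."""
    n = config.n_patients
    ka = params["ka_ir"] if formulation == "IR" else params["ka_xr"]
    ke, v = params["ke"], params["v"]
    pd_args = (params["bprs0"], params["alpha"], params["emax"], params["ec50"])

    reg_adh, win_adh = build_regimen(formulation, "adherence", horizon=LONG_HORIZON)
    times_l, cp_adh = population_concentrations(reg_adh, ka, ke, v, config.step)
    pct_adh = population_pct_reduction(times_l, cp_adh, *pd_args)
    ref_win = win_adh.reference_window
    reference = {
        "cmax": mx.window_extrema(times_l, cp_adh, ref_win)[0],
        "cmin": mx.trough_minimum(times_l, cp_adh, ref_win, reg_adh.dose_times),
        "dbprs_max": mx.window_extrema(times_l, pct_adh, ref_win)[0],
        "dbprs_min": mx.trough_minimum(times_l, pct_adh, ref_win, reg_adh.dose_times),
    }
    neg_bprs_frac = float(np.mean(np.max(pct_adh, axis=-1) > 100.0))

    t_irr = irregular_dose_time(reg_adh.tau)
    frames = []
    for scenario, frac in _scenario_specs(config):
        if scenario == "adherence":
            reg, win = reg_adh, win_adh
            times_s, cp_s, pct_s = times_l, cp_adh, pct_adh
        else:
            reg, win = build_regimen(formulation, scenario, delay_fraction=frac)
            times_s, cp_s = population_concentrations(reg, ka, ke, v, config.step)
            pct_s = population_pct_reduction(times_s, cp_s, *pd_args)
        if not np.all(np.isfinite(pct_s)):
            bad = int(np.where(~np.isfinite(pct_s).all(axis=1))[0][0])
            raise ConfigError(f"non-finite response for patient {bad} in {scenario}")

        row = {
            "replicate": replicate,
            "patient_id": np.arange(n),
            "formulation": formulation,
            "scenario": scenario,
            "delay_fraction": np.nan if frac is None else frac,
        }
        swin = win.scenario_window
        if scenario == "discontinuation":
            if config.duration_borderline == "typical_concentration":
                profile, thr = cp_s, _borderline_concentration(config)
            else:
                profile, thr = pct_s, config.response_threshold_pct
            duration, hangover, cens = mx.therapeutic_duration_and_hangover(
                times_s, profile, t_irr, reg.tau, thr
            )
            row.update(
                duration=duration, hangover=hangover, duration_censored=cens,
                cmax=np.nan, cmin=np.nan, dbprs_max=np.nan, dbprs_min=np.nan,
                event_low=pd.NA, event_high=pd.NA,
            )
            for key in DELTA_PARAMS:
                row[key] = np.nan
        else:
            summary = {
                "cmax": mx.window_extrema(times_s, cp_s, swin)[0],
                "cmin": mx.trough_minimum(times_s, cp_s, swin, reg.dose_times),
                "dbprs_max": mx.window_extrema(times_s, pct_s, swin)[0],
                "dbprs_min": mx.trough_minimum(times_s, pct_s, swin, reg.dose_times),
            }
            deltas = mx.delta_parameters(summary, reference)
            ev_low, ev_high = mx.risk_outcomes(
                times_s, cp_s, pct_s, swin, reg.dose_times,
                config.response_threshold_pct, config.conc_ceiling,
            )
            row.update(summary)
            row.update({f"delta_{k}": deltas[k] for k in summary})
            row.update(event_low=ev_low, event_high=ev_high)
        if scenario == "omission":
            rec, rec_cens = mx.recovery_time(
                times_s, cp_s, cp_adh, t_irr, config.recovery_rel_tol
            )
            row.update(t_recovery=rec, recovery_censored=rec_cens)
        frames.append(pd.DataFrame(row))
    return frames, neg_bprs_frac


def run_trial(config: StudyConfig | None = None) -> TrialResult:
    """Run the full virtual trial described by ``config``."""
    config = config or StudyConfig()
    all_frames: list[pd.DataFrame] = []
    patients_df = None
    diagnostics: dict = {"seeds": [], "neg_bprs_fraction": {}}
    for r in range(config.n_replicates):
        seed = config.replicate_seed(r)
        diagnostics["seeds"].append(seed)
        params = sample_parameter_arrays(config.pk, config.pd, config.n_patients, seed)
        if r == 0:
            patients_df = pd.DataFrame({"id": np.arange(config.n_patients), **params})
        for formulation in config.formulations:
            frames, neg_frac = _simulate_arm(config, params, formulation, r)
            all_frames.extend(frames)
            if r == 0:
                diagnostics["neg_bprs_fraction"][formulation] = neg_frac
    summaries = pd.concat(all_frames, ignore_index=True)

    delay_table = _delta_table(summaries, [("delay", f) for f in config.delay_fractions])
    mistake_table = _delta_table(summaries, [("omission", None), ("doubling", None)])
    odds = _odds_panel(summaries, config)
    outcomes, histograms = _outcome_summaries(summaries, config)
    return TrialResult(
        config=config,
        patients=patients_df,
        summaries=summaries,
        delay_table=delay_table,
        mistake_table=mistake_table,
        odds=odds,
        outcomes=outcomes,
        histograms=histograms,
        diagnostics=diagnostics,
    )


def _select(summaries, scenario, frac, formulation, replicate=None):
    m = (summaries["scenario"] == scenario) & (summaries["formulation"] == formulation)
    if frac is not None:
        m &= summaries["delay_fraction"] == frac
    if replicate is not None:
        m &= summaries["replicate"] == replicate
    return summaries[m]


def _delta_table(summaries: pd.DataFrame, cases) -> pd.DataFrame:
    """Mean (CV) of each Δ-parameter per case, replicate 0, with KS p-values.

    CV follows the table footnote convention SD/mean, reported as a
    positive magnitude.
    """
    rows = []
    for scenario, frac in cases:
        ir = _select(summaries, scenario, frac, "IR", replicate=0)
        xr = _select(summaries, scenario, frac, "XR", replicate=0)
        for param in DELTA_PARAMS:
            x_ir, x_xr = ir[param].to_numpy(float), xr[param].to_numpy(float)
            x_ir, x_xr = x_ir[~np.isnan(x_ir)], x_xr[~np.isnan(x_xr)]
            ks = ks_two_sample(x_ir, x_xr)
            row = {"scenario": scenario, "delay_fraction": frac, "parameter": param,
                   "ks_p": ks.p, "ks_d": ks.d}
            for arm, x in (("ir", x_ir), ("xr", x_xr)):
                mean = float(np.mean(x))
                cv = float(np.std(x, ddof=1) / abs(mean)) if mean != 0 else np.nan
                row[f"{arm}_mean"] = mean
                row[f"{arm}_cv"] = cv
                row[f"{arm}_label"] = f"{mean:.1f}({cv:.1f})" if np.isfinite(cv) else f"{mean:.1f}(-)"
            rows.append(row)
    return pd.DataFrame(rows)


def _odds_panel(summaries: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    rows = []
    for scenario, frac in _scenario_specs(config):
        if scenario not in _OR_SCENARIOS:
            continue
        for endpoint, col in (("low_response", "event_low"), ("high_concentration", "event_high")):
            per_rep = []
            for r in range(config.n_replicates):
                ir = _select(summaries, scenario, frac, "IR", replicate=r)
                xr = _select(summaries, scenario, frac, "XR", replicate=r)
                per_rep.append(
                    odds_ratio(int(xr[col].sum()), len(xr), int(ir[col].sum()), len(ir))
                )
            avg = average_odds_ratio(per_rep)
            rows.append({
                "scenario": scenario,
                "delay_fraction": frac,
                "endpoint": endpoint,
                "or_mean": avg.or_point,
                "ci_low_mean": avg.ci_low,
                "ci_high_mean": avg.ci_high,
                "or_rep0": per_rep[0].or_point,
                "ci_low_rep0": per_rep[0].ci_low,
                "ci_high_rep0": per_rep[0].ci_high,
                "n_replicates": len(per_rep),
            })
    return pd.DataFrame(rows)


def _outcome_summaries(summaries: pd.DataFrame, config: StudyConfig):
    """Duration / hangover / recovery proportions and histograms (pooled
    across replicates)."""
    rows, hist_rows = [], []
    for formulation in config.formulations:
        disc = summaries[(summaries["scenario"] == "discontinuation")
                         & (summaries["formulation"] == formulation)]
        omit = summaries[(summaries["scenario"] == "omission")
                         & (summaries["formulation"] == formulation)]
        duration = disc["duration"].to_numpy(float)
        hangover = np.clip(disc["hangover"].to_numpy(float), 0.0, None)
        recovery = omit["t_recovery"].to_numpy(float)
        rows.append({
            "formulation": formulation,
            "n": len(disc),
            "prop_duration_lt_24h": float(np.mean(duration < 24.0)),
            "prop_recovery_lt_48h": float(np.mean(recovery < 48.0)),
            "mean_duration_h": float(np.mean(duration)),
            "median_duration_h": float(np.median(duration)),
            "mean_hangover_h": float(np.mean(hangover)),
            "mean_recovery_h": float(np.mean(recovery)),
            "median_recovery_h": float(np.median(recovery)),
            "frac_duration_censored": float(disc["duration_censored"].mean()),
            "frac_recovery_censored": float(omit["recovery_censored"].mean()),
        })
        for name, values, width in (("hangover", hangover, 10.0), ("recovery", recovery, 50.0)):
            top = np.ceil(max(values.max(), width) / width) * width
            edges = np.arange(0.0, top + width, width)
            counts, _ = np.histogram(values, bins=edges)
            for left, right, count in zip(edges[:-1], edges[1:], counts):
                hist_rows.append({"formulation": formulation, "metric": name,
                                  "bin_left_h": left, "bin_right_h": right,
                                  "count": int(count)})
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


def render_tables(result: TrialResult, out_dir: str | Path) -> list[Path]:
    """Write the result tables as CSVs (plus the config) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "patients.csv": result.patients,
        "patient_summaries.csv": result.summaries,
        "delay_table.csv": result.delay_table,
        "mistake_table.csv": result.mistake_table,
        "odds_ratios.csv": result.odds,
        "outcomes.csv": result.outcomes,
        "histograms.csv": result.histograms,
    }
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, index=False, float_format="%.6g")
        written.append(path)
    cfg_path = out / "config.yaml"
    result.config.to_yaml(cfg_path)
    written.append(cfg_path)
    return written
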