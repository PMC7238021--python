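import dataclasses

import numpy as np
import pytest

from quetsim import (
    ContractError,
    build_regimen,
    concentration_profile,
    bprs_profile,
    delta_parameters,
    recovery_time,
    risk_outcomes,
    therapeutic_duration_and_hangover,
    threshold_concentration,
    trough_minimum,
    window_extrema,
)
from quetsim.pk import single_dose_cp
from quetsim.regimen import DoseEvent, Regimen


def _summary(profile, resp, window, dose_times):
    return {
        "cmax": window_extrema(profile.times, profile.cp, window)[0],
        "cmin": trough_minimum(profile.times, profile.cp, window, dose_times),
        "dbprs_max": window_extrema(profile.times, resp.pct_reduction, window)[0],
        "dbprs_min": trough_minimum(profile.times, resp.pct_reduction, window, dose_times),
    }


@pytest.fixture(scope="module")
def ir_reference(typical):
    reg, win = build_regimen("IR", "adherence")
    conc = concentration_profile(reg, typical)
    resp = bprs_profile(conc, typical)
    return _summary(conc, resp, win.reference_window, reg.dose_times)


def _scenario_deltas(typical, scenario, frac, reference):
    reg, win = build_regimen("IR", scenario, delay_fraction=frac)
    conc = concentration_profile(reg, typical)
    resp = bprs_profile(conc, typical)
    summary = _summary(conc, resp, win.scenario_window, reg.dose_times)
    return delta_parameters(summary, reference), summary, conc


def test_window_extrema_basic_properties():
    t = np.linspace(0, 10, 101)
    vmax, vmin, tmax, tmin = window_extrema(t, np.sin(t), (0.0, 10.0))
    assert vmax == pytest.approx(np.sin(t).max())
    assert vmin == pytest.approx(np.sin(t).min())
    # constant profile: max == min
    vmax, vmin, _, _ = window_extrema(t, np.full_like(t, 3.3), (2.0, 5.0))
    assert vmax == vmin == 3.3
    with pytest.raises(ContractError):
        window_extrema(t, np.sin(t), (5.0, 5.0))


def test_trough_excludes_pre_dose_undershoot_on_full_delay(typical, ir_reference):
    """Under a 100% delay the undershoot just before the coincident doses at
    the window start must not count as the steady-state trough."""
    reg, win = build_regimen("IR", "delay", delay_fraction=1.0)
    conc = concentration_profile(reg, typical)
    grid_min = window_extrema(conc.times, conc.cp, win.scenario_window)[1]
    trough = trough_minimum(conc.times, conc.cp, win.scenario_window, reg.dose_times)
    assert grid_min < 40.0          # the undershoot
    assert trough > ir_reference["cmin"]  # the trough is above the adherent one


def test_omission_window_keeps_the_undershoot(typical, ir_reference):
    reg, win = build_regimen("IR", "omission")
    conc = concentration_profile(reg, typical)
    trough = trough_minimum(conc.times, conc.cp, win.scenario_window, reg.dose_times)
    # undershoot right before the 192 h resumption dose, about a quarter of
    # the adherent trough
    assert trough == pytest.approx(26.1, abs=0.3)


@pytest.mark.parametrize("scenario,frac,param,expected", [
    ("delay", 1.0, "cmax", 54.9),     # vs printed population mean 53.4
    ("delay", 1.0, "cmin", 13.8),     # vs printed 12.3
    ("omission", None, "cmin", -76.3),  # vs printed -74.6
    ("omission", None, "cmax", -4.7),   # vs printed -5.6
    ("doubling", None, "cmax", 19.9),   # vs printed 19.5
    ("doubling", None, "cmin", 4.3),    # vs printed 5.1
])
def test_typical_patient_deltas_match_superposition_oracle(
    typical, ir_reference, scenario, frac, param, expected
):
    """Typical-patient Δ-parameters under the study windows, frozen from the
    independent single-dose superposition arithmetic."""
    deltas, _, _ = _scenario_deltas(typical, scenario, frac, ir_reference)
    assert deltas[param] == pytest.approx(expected, abs=0.15)


def test_adherence_deltas_are_exactly_zero(typical, ir_reference):
    deltas = delta_parameters(ir_reference, ir_reference)
    assert all(v == 0.0 for v in deltas.values())


def test_delta_undefined_for_nonpositive_reference():
    out = delta_parameters({"x": np.array([1.0])}, {"x": np.array([0.0])})
    assert np.isnan(out["x"][0])


def test_deltas_invariant_to_volume_and_dose_rescaling(typical, ir_reference):
    """Joint rescaling of V and all dose amounts leaves every Δ unchanged
    (linearity of the PK model)."""
    scaled_patient = dataclasses.replace(typical, v=typical.v * 3.7)
    reg_a, win_a = build_regimen("IR", "adherence")
    reg_s, win_s = build_regimen("IR", "omission")

    def scale(reg):
        return Regimen(formulation=reg.formulation, tau=reg.tau,
                       events=tuple(DoseEvent(e.time, e.amount * 3.7) for e in reg.events),
                       scenario=reg.scenario, delay_fraction=reg.delay_fraction,
                       horizon=reg.horizon)

    conc_a = concentration_profile(scale(reg_a), scaled_patient)
    conc_s = concentration_profile(scale(reg_s), scaled_patient)
    ref = {"cmax": window_extrema(conc_a.times, conc_a.cp, win_a.reference_window)[0],
           "cmin": trough_minimum(conc_a.times, conc_a.cp, win_a.reference_window,
                                  reg_a.dose_times)}
    scen = {"cmax": window_extrema(conc_s.times, conc_s.cp, win_s.scenario_window)[0],
            "cmin": trough_minimum(conc_s.times, conc_s.cp, win_s.scenario_window,
                                   reg_s.dose_times)}
    deltas = delta_parameters(scen, ref)

    conc_a0 = concentration_profile(reg_a, typical)
    conc_s0 = concentration_profile(reg_s, typical)
    ref0 = {"cmax": window_extrema(conc_a0.times, conc_a0.cp, win_a.reference_window)[0],
            "cmin": trough_minimum(conc_a0.times, conc_a0.cp, win_a.reference_window,
                                   reg_a.dose_times)}
    scen0 = {"cmax": window_extrema(conc_s0.times, conc_s0.cp, win_s.scenario_window)[0],
             "cmin": trough_minimum(conc_s0.times, conc_s0.cp, win_s.scenario_window,
                                    reg_s.dose_times)}
    unscaled = delta_parameters(scen0, ref0)
    assert deltas["cmax"] == pytest.approx(unscaled["cmax"], abs=1e-9)
    assert deltas["cmin"] == pytest.approx(unscaled["cmin"], abs=1e-9)


def test_time_shift_leaves_deltas_unchanged(typical):
    """Shifting every dose event and window by a whole day changes nothing
    about the Δ-metrics."""
    shift = 24.0
    reg_a, win_a = build_regimen("IR", "adherence")
    reg_o, win_o = build_regimen("IR", "omission")

    def shifted(reg):
        return Regimen(formulation=reg.formulation, tau=reg.tau,
                       events=tuple(DoseEvent(e.time + shift, e.amount) for e in reg.events),
                       scenario=reg.scenario, delay_fraction=reg.delay_fraction,
                       horizon=reg.horizon + shift)

    def deltas_for(reg_adh, reg_scn, ref_win, scn_win):
        conc_a = concentration_profile(reg_adh, typical)
        conc_o = concentration_profile(reg_scn, typical)
        ref = {"cmax": window_extrema(conc_a.times, conc_a.cp, ref_win)[0],
               "cmin": trough_minimum(conc_a.times, conc_a.cp, ref_win, reg_adh.dose_times)}
        scen = {"cmax": window_extrema(conc_o.times, conc_o.cp, scn_win)[0],
                "cmin": trough_minimum(conc_o.times, conc_o.cp, scn_win, reg_scn.dose_times)}
        return delta_parameters(scen, ref)

    base = deltas_for(reg_a, reg_o, win_a.reference_window, win_o.scenario_window)
    moved = deltas_for(
        shifted(reg_a), shifted(reg_o),
        tuple(np.array(win_a.reference_window) + shift),
        tuple(np.array(win_o.scenario_window) + shift),
    )
    for key in base:
        assert moved[key] == pytest.approx(base[key], abs=1e-9)


class TestRecoveryTime:
    def test_identical_profiles_recover_immediately(self):
        t = np.linspace(0, 100, 1001)
        cp = 100 + 10 * np.cos(t)
        hours, censored = recovery_time(t, cp, cp, t0=10.0)
        assert hours == 0.0 and not censored

    def test_typical_patient_recovery(self, typical):
        """Recovery ends one grid step after the last excursion outside the
        band; cross-checked against a continuous-time bisection oracle."""
        reg_a, _ = build_regimen("IR", "adherence", horizon=504.0)
        reg_o, _ = build_regimen("IR", "omission")
        conc_a = concentration_profile(reg_a, typical)
        conc_o = concentration_profile(reg_o, typical)
        hours, censored = recovery_time(conc_a.times, conc_o.cp, conc_a.cp, t0=180.0,
                                        rel_tol=0.01)
        assert not censored
        assert hours == pytest.approx(48.05, abs=0.1)

    def test_monotone_in_tolerance(self, typical):
        reg_a, _ = build_regimen("IR", "adherence", horizon=504.0)
        reg_o, _ = build_regimen("IR", "omission")
        conc_a = concentration_profile(reg_a, typical)
        conc_o = concentration_profile(reg_o, typical)
        times = [recovery_time(conc_a.times, conc_o.cp, conc_a.cp, 180.0, tol)[0]
                 for tol in (0.005, 0.01, 0.02, 0.05)]
        assert times == sorted(times, reverse=True)

    def test_never_recovering_profile_censored(self):
        t = np.linspace(0, 100, 1001)
        adh = np.full_like(t, 100.0)
        hours, censored = recovery_time(t, adh * 0.5, adh, t0=0.0, rel_tol=0.05)
        assert censored
        assert hours == pytest.approx(100.0)


class TestTherapeuticDuration:
    def test_typical_duration_against_continuous_oracle(self, typical):
        """Duration under the fixed borderline concentration, vs a bisection
        on the continuous superposed profile."""
        reg, _ = build_regimen("IR", "discontinuation")
        conc = concentration_profile(reg, typical)
        borderline = threshold_concentration(typical, 168.0)
        duration, hangover, censored = therapeutic_duration_and_hangover(
            conc.times, conc.cp, 180.0, 12.0, borderline
        )

        def cp_at(t):
            total = 0.0
            for e in reg.events:
                if e.time <= t:
                    total += single_dose_cp(t - e.time, e.amount, typical.ka_ir,
                                            typical.ke, typical.v)
            return total

        lo, hi = 180.0, 504.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if cp_at(mid) >= borderline:
                lo = mid
            else:
                hi = mid
        assert not censored
        assert duration == pytest.approx(hi - 180.0, abs=0.06)
        assert hangover == pytest.approx(duration - 12.0)

    def test_subtherapeutic_patient_gets_zero_duration(self):
        t = np.linspace(0, 100, 101)
        profile = np.full_like(t, 5.0)  # % reduction always below threshold
        duration, hangover, censored = therapeutic_duration_and_hangover(
            t, profile, 50.0, 12.0, 14.0
        )
        assert duration == 0.0 and hangover == -12.0 and not censored

    def test_everlasting_response_is_censored(self):
        t = np.linspace(0, 100, 101)
        duration, hangover, censored = therapeutic_duration_and_hangover(
            t, np.full_like(t, 20.0), 40.0, 12.0, 14.0
        )
        assert censored and duration == pytest.approx(60.0)

    def test_duration_monotone_in_threshold(self, typical):
        reg, _ = build_regimen("IR", "discontinuation")
        conc = concentration_profile(reg, typical)
        durations = [therapeutic_duration_and_hangover(conc.times, conc.cp, 180.0,
                                                       12.0, thr)[0]
                     for thr in (30.0, 50.0, 67.4, 90.0)]
        assert durations == sorted(durations, reverse=True)


class TestRiskOutcomes:
    def test_typical_adherent_stays_inside_window(self, typical):
        reg, win = build_regimen("IR", "adherence")
        conc = concentration_profile(reg, typical)
        resp = bprs_profile(conc, typical)
        low, high = risk_outcomes(conc.times, conc.cp, resp.pct_reduction,
                                  win.scenario_window, reg.dose_times)
        assert not high  # peak ~350 < 500
        assert not low   # trough reduction ~17% > 14%

    def test_full_delay_breaches_concentration_ceiling(self, typical):
        reg, win = build_regimen("IR", "delay", delay_fraction=1.0)
        conc = concentration_profile(reg, typical)
        resp = bprs_profile(conc, typical)
        low, high = risk_outcomes(conc.times, conc.cp, resp.pct_reduction,
                                  win.scenario_window, reg.dose_times)
        assert high  # peak ~540 > 500

    def test_zero_profile_is_subtherapeutic_only(self):
        t = np.linspace(0, 216, 1000)
        zeros = np.zeros_like(t)
        low, high = risk_outcomes(t, zeros, zeros, (192.0, 216.0), np.array([192.0, 204.0]))
        assert low and not high
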