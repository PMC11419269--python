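"""Tests for the 1:1 Langmuir model, referencing, and K_D fitting."""

import numpy as np
import pytest

from trem2map.kinetics import (
    FoldChange,
    KineticParams,
    PhaseSchedule,
    Sensorgram,
    SteadyStateSeries,
    double_reference_subtract,
    extract_Req,
    fit_kinetic_one_to_one,
    fit_steady_state,
    fold_change,
    simulate_one_to_one,
)
from trem2map.synth import GeneratorSpec, make_biphasic_family, make_sensorgram_family
from trem2map.variants import BindingSentinel


class TestSimulate:
    def test_half_saturation_plateau_at_kd(self, short_schedule):
        params = KineticParams(kon=1e6, koff=1e-2, rmax=1.0)
        long = PhaseSchedule(baseline=0, association=5000, dissociation=10, dt=1.0)
        sg = simulate_one_to_one(params, params.kd, long)
        assoc = sg.signal[sg.phase == "association"]
        assert assoc[-1] == pytest.approx(0.5, rel=1e-6)

    def test_zero_concentration_is_flat_zero(self, short_schedule):
        sg = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 0.0, short_schedule)
        assert np.all(sg.signal == 0.0)

    def test_closed_form_value(self):
        # kon 1e5, koff 1e-2, conc 100 nM -> kobs 0.02/s, Req 0.5;
        # 50 s into association the response is 0.5 (1 - e^-1)
        params = KineticParams(kon=1e5, koff=1e-2, rmax=1.0)
        sched = PhaseSchedule(baseline=0, association=100, dissociation=10, dt=1.0)
        sg = simulate_one_to_one(params, 100e-9, sched)
        i = np.searchsorted(sg.time, 50.0)
        assert sg.signal[i] == pytest.approx(0.5 * (1 - np.exp(-1)), rel=1e-9)

    def test_negative_concentration_rejected(self, short_schedule):
        with pytest.raises(ValueError):
            simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), -1e-9, short_schedule)

    def test_association_monotone_bounded_dissociation_decays(self, short_schedule):
        params = KineticParams(kon=1e5, koff=1e-2, rmax=1.0)
        sg = simulate_one_to_one(params, 500e-9, short_schedule)
        assoc = sg.signal[sg.phase == "association"]
        dissoc = sg.signal[sg.phase == "dissociation"]
        req = params.rmax * 500e-9 / (500e-9 + params.kd)
        assert np.all(np.diff(assoc) >= 0)
        assert np.all(assoc <= req + 1e-12)
        assert np.all(np.diff(dissoc) <= 0)

    def test_kd_is_koff_over_kon(self):
        params = KineticParams(kon=3.3e5, koff=7.7e-3, rmax=2.0)
        assert params.kd == 7.7e-3 / 3.3e5
        with pytest.raises(ValueError):
            KineticParams(kon=-1, koff=1e-2, rmax=1.0)


class TestDoubleReference:
    def test_zero_references_leave_sample_unchanged(self, short_schedule):
        sg = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 500e-9, short_schedule)
        zero = Sensorgram(sg.time, np.zeros_like(sg.signal), sg.phase, 0.0)
        out = double_reference_subtract(sg, zero, zero)
        assert np.allclose(out.signal, sg.signal)

    def test_self_subtraction_is_exactly_zero(self, short_schedule):
        sg = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 500e-9, short_schedule)
        zero = Sensorgram(sg.time, np.zeros_like(sg.signal), sg.phase, 0.0)
        out = double_reference_subtract(sg, sg, zero)
        assert np.all(out.signal == 0.0)

    def test_recovers_signal_under_drift_and_offset(self, short_schedule):
        clean = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 500e-9, short_schedule)
        drift = 1e-4 * clean.time
        offset = 0.37
        sample = Sensorgram(clean.time, clean.signal + drift + offset, clean.phase, 500e-9)
        buffer_ref = Sensorgram(clean.time, drift, clean.phase, 0.0)
        analyte_ref = Sensorgram(clean.time, np.full_like(drift, offset), clean.phase, 500e-9)
        out = double_reference_subtract(sample, buffer_ref, analyte_ref)
        # baseline alignment removes constants; drift reference removes slope
        assert np.allclose(out.signal, clean.signal, atol=1e-9)

    def test_grid_mismatch_rejected(self, short_schedule):
        sg = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 500e-9, short_schedule)
        shifted = Sensorgram(sg.time + 0.5, sg.signal, sg.phase, 0.0)
        with pytest.raises(ValueError, match="grid"):
            double_reference_subtract(sg, shifted, shifted)


class TestExtractReq:
    def test_plateau_recovered_on_long_trace(self):
        params = KineticParams(kon=1e5, koff=1e-2, rmax=1.0)
        sched = PhaseSchedule(baseline=10, association=2000, dissociation=10, dt=1.0)
        sg = simulate_one_to_one(params, 200e-9, sched)
        req_true = params.rmax * 200e-9 / (200e-9 + params.kd)
        est = extract_Req(sg)
        assert est.equilibrated
        assert est.req == pytest.approx(req_true, rel=5e-3)

    def test_constant_trace_returns_value(self):
        time = np.arange(100.0)
        sg = Sensorgram(time, np.full(100, 0.42), np.array(["association"] * 100), 1e-9)
        est = extract_Req(sg)
        assert est.req == pytest.approx(0.42)
        assert est.equilibrated

    def test_short_association_flagged_not_equilibrated(self):
        # kobs * t_assoc < 1: still rising at the end
        params = KineticParams(kon=1e5, koff=1e-3, rmax=1.0)
        sched = PhaseSchedule(baseline=10, association=200, dissociation=10, dt=0.5)
        sg = simulate_one_to_one(params, 10e-9, sched)  # kobs = 2e-3 -> kobs*t = 0.4
        assert not extract_Req(sg).equilibrated

    def test_window_too_short_rejected(self):
        time = np.arange(10.0)
        sg = Sensorgram(time, np.ones(10), np.array(["association"] * 10), 1e-9)
        with pytest.raises(ValueError, match="too short"):
            extract_Req(sg, window_fraction=0.1)


class TestSteadyStateFit:
    def test_noiseless_roundtrip(self):
        kd, rmax = 281e-9, 1.7
        conc = np.array([12e-9 * 2**i for i in range(13)])
        series = SteadyStateSeries(conc, rmax * conc / (conc + kd))
        fit = fit_steady_state(series)
        assert fit.converged
        assert fit.kd == pytest.approx(kd, rel=1e-3)
        assert fit.rmax == pytest.approx(rmax, rel=1e-3)
        assert fit.stderr is not None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_steady_state(SteadyStateSeries(np.array([1e-9, 2e-9]), np.array([0.1, 0.2])))

    def test_linear_regime_reported_not_converged(self):
        # all concentrations far below KD: no curvature to pin the fit
        kd = 1e-3
        conc = np.array([1e-9, 2e-9, 4e-9, 8e-9, 16e-9])
        series = SteadyStateSeries(conc, conc / (conc + kd))
        fit = fit_steady_state(series)
        assert not fit.converged
        assert fit.stderr is None

    def test_noisy_recovery_is_unbiased(self, rng):
        kd, rmax = 281e-9, 1.0
        conc = np.array([12e-9 * 2**i for i in range(13)])
        truth = rmax * conc / (conc + kd)
        fitted = []
        for _ in range(60):
            noisy = truth + rng.normal(0, 0.01 * rmax, size=truth.size)
            fitted.append(fit_steady_state(SteadyStateSeries(conc, noisy)).kd)
        assert np.median(fitted) == pytest.approx(kd, rel=0.05)


class TestKineticFit:
    def test_noiseless_roundtrip_recovers_rates(self, short_schedule):
        params = KineticParams(kon=2e5, koff=5e-3, rmax=1.3)
        spec = GeneratorSpec(seed=0, schedule=short_schedule)
        family = [
            simulate_one_to_one(params, c, short_schedule) for c in spec.concentrations
        ]
        fit = fit_kinetic_one_to_one(family, check_biphasic=False)
        assert fit.converged
        assert fit.kon == pytest.approx(params.kon, rel=1e-3)
        assert fit.koff == pytest.approx(params.koff, rel=1e-3)
        assert fit.kd == pytest.approx(params.kd, rel=1e-3)

    def test_steady_state_agrees_with_kinetic_on_equilibrated_traces(self):
        kd = 100e-9
        sched = PhaseSchedule(baseline=10, association=3000, dissociation=100, dt=2.0)
        spec = GeneratorSpec(seed=0, schedule=sched)
        family = make_sensorgram_family(kd, spec, koff=0.01)
        kin = fit_kinetic_one_to_one(family, check_biphasic=False)
        conc = np.array([sg.analyte_conc for sg in family])
        req = np.array([extract_Req(sg).req for sg in family])
        ss = fit_steady_state(SteadyStateSeries(conc, req, "extracted"))
        assert ss.kd == pytest.approx(kin.kd, rel=0.02)

    def test_kobs_linearity_across_concentrations(self, short_schedule):
        # single-exponential rates regress on concentration with slope kon
        # and intercept koff
        import lmfit

        params = KineticParams(kon=1e5, koff=8e-3, rmax=1.0)
        concs = np.array([100e-9, 200e-9, 400e-9, 800e-9])
        kobs_fit = []
        for c in concs:
            sg = simulate_one_to_one(params, c, short_schedule)
            mask = sg.phase == "association"
            t = sg.time[mask] - sg.time[mask][0]
            y = sg.signal[mask]
            model = lmfit.Model(lambda t, req, kobs: req * (1 - np.exp(-kobs * t)))
            res = model.fit(y, t=t, req=y.max(), kobs=0.01)
            kobs_fit.append(res.params["kobs"].value)
        slope, intercept = np.polyfit(concs, kobs_fit, 1)
        assert slope == pytest.approx(params.kon, rel=1e-2)
        assert intercept == pytest.approx(params.koff, rel=1e-2)

    def test_single_concentration_rejected(self, short_schedule):
        sg = simulate_one_to_one(KineticParams(1e5, 1e-2, 1.0), 500e-9, short_schedule)
        with pytest.raises(ValueError, match="concentrations"):
            fit_kinetic_one_to_one([sg])

    def test_two_component_traces_flagged_biphasic(self, short_schedule):
        fast = KineticParams(kon=1e5, koff=0.1, rmax=0.5)
        slow = KineticParams(kon=1e5, koff=0.01, rmax=0.5)
        spec = GeneratorSpec(seed=2, schedule=short_schedule)
        family = make_biphasic_family(fast, slow, 0.5, spec)
        fit = fit_kinetic_one_to_one(family)
        assert fit.biphasic_flag

    def test_true_one_to_one_not_flagged(self, short_schedule):
        spec = GeneratorSpec(seed=2, schedule=short_schedule)
        family = make_sensorgram_family(100e-9, spec)
        fit = fit_kinetic_one_to_one(family)
        assert not fit.biphasic_flag


class TestFoldChange:
    @pytest.mark.parametrize(
        "kd_variant, kd_wt, printed, ndigits, direction",
        [
            (25e-9, 281e-9, 11.24, 2, "affinity-increase"),
            (79.8e-9, 16.5e-9, 4.8, 1, "affinity-decrease"),
            (120e-9, 281e-9, 2.3, 1, "affinity-increase"),
        ],
    )
    def test_table_arithmetic(self, kd_variant, kd_wt, printed, ndigits, direction):
        fc = fold_change(kd_variant, kd_wt)
        assert round(fc.factor, ndigits) == pytest.approx(printed, abs=1e-9)
        assert fc.direction == direction

    def test_identity(self):
        assert fold_change(1e-9, 1e-9) == FoldChange(1.0, "unchanged")

    def test_sentinel_is_not_computable(self):
        fc = fold_change(BindingSentinel.NO_BINDING_DETECTED, 281e-9)
        assert fc.factor is None
        assert fc.direction == "not-computable"

    def test_invalid_wt_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1e-9, 0.0)
        with pytest.raises(ValueError):
            fold_change(1e-9, BindingSentinel.NO_BINDING)
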