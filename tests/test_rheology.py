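import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import ode_creep_strain
from osmech import (
    CellGroundTruth,
    KVFit,
    active_kv_creep,
    classify_activity,
    elliptic_deformation,
    fit_kv,
    force_from_power,
    kv_creep,
    kv_relax,
    relative_deformation,
    shape_restoration,
    simulate_trace,
    stress_from_power,
)
from osmech.tracking import AxisTrace


class TestPowerMaps:
    @pytest.mark.parametrize(
        "power, stress, force",
        [(400.0, 0.38, 80.0), (800.0, 0.76, 160.0), (1200.0, 1.14, 240.0), (0.0, 0.0, 0.0)],
    )
    def test_linear_map(self, power, stress, force):
        assert stress_from_power(power) == pytest.approx(stress, abs=1e-12)
        assert force_from_power(power) == pytest.approx(force, abs=1e-12)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            stress_from_power(-1.0)
        with pytest.raises(ValueError):
            force_from_power(-1.0)


class TestCreepClosedForms:
    def test_passive_worked_example(self):
        # frozen from the numerical IVP oracle for E=100, eta=100, sigma0=1
        assert kv_creep(1.0, 100.0, 100.0, 1.0) == pytest.approx(0.0063212, abs=5e-8)

    def test_active_worked_example(self):
        assert active_kv_creep(1.0, 100.0, 100.0, 1.0, 0.1) == pytest.approx(
            0.0059533, abs=5e-8
        )

    def test_initial_condition_and_equilibrium(self):
        assert kv_creep(0.0, 100.0, 100.0, 1.0) == 0.0
        tau = 1.0
        assert kv_creep(50 * tau, 100.0, 100.0, 1.0) == pytest.approx(0.01, abs=1e-9)

    def test_active_reduces_to_passive(self):
        t = np.linspace(0, 10, 101)
        np.testing.assert_allclose(
            active_kv_creep(t, 50.0, 100.0, 0.8, 0.0), kv_creep(t, 50.0, 100.0, 0.8)
        )

    def test_closed_forms_match_ode_oracle(self):
        t = np.linspace(0.0, 10.0, 101)
        for E in (10.0, 100.0, 1000.0):
            for tau in (0.1, 1.0, 10.0):
                for a in (0.0, 0.1, 0.5):
                    got = active_kv_creep(t, E, E * tau, 1.0, a)
                    want = ode_creep_strain(t, E, E * tau, 1.0, a)
                    assert np.max(np.abs(got - want)) < 1e-8

    def test_clamped_strain_decays_after_peak(self):
        # once contraction has cancelled the stress, strain can only decay
        E, tau, sigma0, a = 100.0, 1.0, 1.0, 0.5
        t = np.linspace(sigma0 / a + 3 * tau, 10.0, 50)
        g = active_kv_creep(t, E, E * tau, sigma0, a)
        assert np.all(np.diff(g) <= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            kv_creep(1.0, 0.0, 100.0, 1.0)
        with pytest.raises(ValueError):
            active_kv_creep(1.0, 100.0, 100.0, 1.0, -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        E=st.floats(10.0, 1000.0),
        tau=st.floats(0.1, 10.0),
        a=st.floats(0.001, 0.5),
        t=st.floats(0.01, 10.0),
    )
    def test_active_never_exceeds_passive(self, E, tau, a, t):
        assert active_kv_creep(t, E, E * tau, 1.0, a) <= kv_creep(t, E, E * tau, 1.0) + 1e-15

    @settings(derandomize=True, max_examples=50)
    @given(E=st.floats(10.0, 1000.0), tau=st.floats(0.1, 10.0))
    def test_passive_creep_monotone_in_time_and_stiffness(self, E, tau):
        # strictly increasing until saturation reaches float resolution
        t = np.linspace(0.01, 5 * tau, 50)
        g = kv_creep(t, E, E * tau, 1.0)
        assert np.all(np.diff(g) > 0)
        assert kv_creep(1.0, 2 * E, 2 * E * tau, 1.0) < kv_creep(1.0, E, E * tau, 1.0)


class TestRelaxation:
    def test_worked_example(self):
        assert kv_relax(1.5, 0.006, 1.0) == pytest.approx(0.0013388, abs=5e-8)

    def test_continuity_and_full_recovery(self):
        assert kv_relax(0.0, 0.0123, 2.0) == 0.0123
        assert kv_relax(1e4, 0.0123, 2.0) == pytest.approx(0.0, abs=1e-12)


def _flat_trace(protocol, L=10.5, S=9.5):
    n = protocol.n_frames
    time = np.arange(n) / protocol.frame_rate
    from osmech.tracking import phase_marks_from_protocol

    return AxisTrace(
        cell_id="flat",
        time=time,
        long_um=np.full(n, L),
        short_um=np.full(n, S),
        orientation_deg=np.zeros(n),
        brightness=np.ones(n),
        phase_marks=phase_marks_from_protocol(protocol, time),
        protocol=protocol,
    )


class TestDeformationCurves:
    def test_relative_deformation_definition(self, default_protocol):
        tr = _flat_trace(default_protocol, L=10.0, S=10.0)
        tr.long_um = tr.long_um.copy()
        tr.long_um[tr.phase_marks[0] :] = 10.3
        d = relative_deformation(tr)
        assert d.value[0] == pytest.approx(0.0)
        assert d.end_of_stretch_value == pytest.approx(0.03)

    def test_constant_trace_is_zero(self, default_protocol):
        d = relative_deformation(_flat_trace(default_protocol))
        np.testing.assert_allclose(d.value, 0.0, atol=1e-14)

    def test_elliptic_deformation_definition(self, default_protocol):
        tr = _flat_trace(default_protocol, L=10.0, S=10.0)
        tr.long_um = tr.long_um.copy()
        tr.short_um = tr.short_um.copy()
        tr.long_um[tr.phase_marks[0] :] = 10.5
        tr.short_um[tr.phase_marks[0] :] = 9.5
        eps = elliptic_deformation(tr)
        assert eps.value[0] == pytest.approx(0.0)
        assert eps.end_of_stretch_value == pytest.approx(10.5 / 9.5 - 1.0, rel=1e-12)

    def test_zero_poisson_coupling_makes_signals_agree(self, default_protocol):
        truth = CellGroundTruth(
            cell_id="nu0", class_label="PBMC", elastic_modulus=30.0, viscosity=75.0,
            activity=0.0, radius=5.0, initial_ellipticity=1.0, brightness=1.0,
            rotation_rate=0.0, poisson_ratio=0.0,
        )
        tr = simulate_trace(truth, default_protocol, axis_noise_sd=0.0, seed=0)
        np.testing.assert_allclose(
            elliptic_deformation(tr).value, relative_deformation(tr).value, atol=1e-12
        )

    def test_noise_free_passive_matches_closed_form(self, noise_free_passive_trace):
        truth, tr = noise_free_passive_trace
        d = relative_deformation(tr)
        i0, i1 = d.phase_marks
        t = d.time[i0 : i1 + 1] - d.time[i0]
        want = kv_creep(t, truth.elastic_modulus, truth.viscosity, tr.protocol.step_stress)
        np.testing.assert_allclose(d.value[i0 : i1 + 1], want, atol=1e-9)


class TestFitKV:
    def test_passive_round_trip(self, noise_free_passive_trace):
        truth, tr = noise_free_passive_trace
        fit = fit_kv(relative_deformation(tr), window="full", model="passive")
        assert fit.converged
        assert fit.E == pytest.approx(truth.elastic_modulus, rel=1e-3)
        assert fit.tau == pytest.approx(truth.tau, rel=1e-3)
        assert fit.eta == pytest.approx(fit.E * fit.tau, rel=1e-9)
        assert fit.fit_error < 1e-8

    def test_active_round_trip(self, default_protocol):
        truth = CellGroundTruth(
            cell_id="act", class_label="PBMC", elastic_modulus=40.0, viscosity=60.0,
            activity=0.1, radius=5.0, initial_ellipticity=1.0, brightness=1.0,
            rotation_rate=0.0, poisson_ratio=0.45,
        )
        tr = simulate_trace(truth, default_protocol, axis_noise_sd=0.0, seed=0)
        fit = fit_kv(relative_deformation(tr), window="full", model="active")
        assert fit.converged
        assert fit.a == pytest.approx(0.1, rel=1e-2)
        assert fit.E == pytest.approx(40.0, rel=1e-2)

    def test_first2s_window_round_trip(self, noise_free_passive_trace):
        truth, tr = noise_free_passive_trace
        fit = fit_kv(relative_deformation(tr), window="first2s", model="passive")
        assert fit.converged
        assert fit.E == pytest.approx(truth.elastic_modulus, rel=1e-2)

    def test_flat_curve_flagged_not_converged(self, default_protocol):
        fit = fit_kv(relative_deformation(_flat_trace(default_protocol)), model="passive")
        assert not fit.converged
        assert np.isnan(fit.E)

    def test_too_few_samples_rejected(self, default_protocol):
        tr = _flat_trace(default_protocol)
        curve = relative_deformation(tr)
        curve.phase_marks = (curve.phase_marks[0], curve.phase_marks[0] + 3)
        with pytest.raises(ValueError):
            fit_kv(curve, window="full")


class TestRestorationAndActivity:
    def test_restoration_arithmetic_identity(self):
        from osmech import RestorationResult

        r = RestorationResult(elongation_end_stretch=0.03, elongation_1p5s_after=0.01)
        assert r.shape_restoration == pytest.approx(0.02)

    def test_restoration_closed_form(self, noise_free_passive_trace):
        truth, tr = noise_free_passive_trace
        d = relative_deformation(tr)
        r = shape_restoration(d)
        gT = d.value[d.phase_marks[1]]
        assert r.shape_restoration == pytest.approx(
            gT * (1 - np.exp(-1.5 / truth.tau)), rel=1e-6
        )

    def test_no_recovery_means_zero_restoration(self, default_protocol):
        tr = _flat_trace(default_protocol)
        r = shape_restoration(relative_deformation(tr))
        assert r.shape_restoration == pytest.approx(0.0)

    def test_short_relaxation_rejected(self, default_protocol):
        from dataclasses import replace

        proto = replace(default_protocol, relax_duration=1.0)
        truth = CellGroundTruth(
            cell_id="x", class_label="PBMC", elastic_modulus=30.0, viscosity=75.0,
            activity=0.0, radius=5.0, initial_ellipticity=1.0, brightness=1.0,
            rotation_rate=0.0, poisson_ratio=0.45,
        )
        tr = simulate_trace(truth, proto, axis_noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            shape_restoration(relative_deformation(tr))

    @pytest.mark.parametrize(
        "a, label",
        [(0.079, "active"), (0.0005, "non_active"), (0.001, "non_active")],
    )
    def test_activity_threshold_strict(self, a, label):
        fit = KVFit(30.0, 75.0, 2.5, a, 0.0, "full", "relative", "active", True)
        assert classify_activity(fit) == label

    def test_nonconverged_fit_undetermined(self):
        fit = KVFit.failed("full", "relative", "active")
        assert classify_activity(fit) == "undetermined"
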