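import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import bisect

from rwgkinetics import (
    AdhesionKineticParams,
    FitFailure,
    InitialState,
    KineticTrace,
    SignalCalibration,
    derived_quantities,
    equilibrium_B_no_recruitment,
    fit_kinetics,
    predict_signal,
    simulate,
    steady_state_B,
)
from rwgkinetics.kinetic_model import _smoothed_argmax, k1_2d_to_kon3d


class TestSimulate:
    def test_null_dynamics(self, init):
        p = AdhesionKineticParams(0, 0, 0, 0.3)
        traj = simulate(p, init, np.linspace(0, 50, 100))
        assert np.allclose(traj.L, init.L0)
        assert np.allclose(traj.I, init.I0)
        assert np.allclose(traj.B, init.B0)

    def test_ligand_conservation(self, baseline_params, init):
        traj = simulate(baseline_params, init, np.linspace(0, 100, 500))
        total = traj.L + traj.B
        assert np.max(np.abs(total - (init.L0 + init.B0))) < 1e-6 * (
            init.L0 + init.B0
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        kd=st.floats(300, 3000),
        k2=st.floats(0.01, 1.0),
        k3=st.floats(0.0, 5.0),
        i_max=st.floats(0.05, 2.0),
        i0=st.floats(0.0, 1.0),
    )
    def test_conservation_and_nonnegativity_randomized(self, kd, k2, k3, i_max, i0):
        p = AdhesionKineticParams(k1=k2 / kd, k2=k2, k3=k3, I_max=i_max)
        init = InitialState(L0=15000.0, I0=i0, B0=0.0)
        traj = simulate(p, init, np.linspace(0, 120, 200))
        assert np.max(np.abs(traj.L + traj.B - init.L0)) < 1e-6 * init.L0
        assert np.all(traj.L >= 0) and np.all(traj.I >= 0) and np.all(traj.B >= 0)

    def test_invalid_grid(self, baseline_params, init):
        with pytest.raises(ValueError):
            simulate(baseline_params, init, [10.0, 5.0])


class TestEquilibriumOracles:
    def test_quadratic_root_against_bisection(self):
        # independent oracle: solve B^2 - (L+I+kd)B + L*I = 0 by bisection
        L, I, kd = 15000.0, 0.1, 600.0
        f = lambda b: b * b - (L + I + kd) * b + L * I
        expected = bisect(f, 0.0, min(L, I), xtol=1e-12)
        assert expected == pytest.approx(0.09615, rel=1e-3)
        assert equilibrium_B_no_recruitment(L, I, kd) == pytest.approx(
            expected, rel=1e-9
        )

    def test_limits(self):
        assert equilibrium_B_no_recruitment(100.0, 5.0, 1e12) < 1e-9
        assert equilibrium_B_no_recruitment(100.0, 5.0, 0.0) == pytest.approx(5.0)
        assert equilibrium_B_no_recruitment(3.0, 100.0, 0.0) == pytest.approx(3.0)

    def test_long_horizon_simulation_matches_quadratic(self, init):
        p = AdhesionKineticParams(k1=0.1 / 600, k2=0.1, k3=0.0, I_max=0.3)
        traj = simulate(p, init, np.linspace(0, 600, 301))
        expected = equilibrium_B_no_recruitment(
            init.L0 + init.B0, init.I0 + init.B0, 600.0
        )
        assert traj.B[-1] == pytest.approx(expected, rel=1e-6)

    def test_steady_state_closed_form(self, baseline_params, init):
        # B_max = (L0+B0) I_max / (Kd + I_max) = 15000*0.3/600.3
        b = steady_state_B(baseline_params, init)
        assert b == pytest.approx(7.4963, rel=1e-4)
        traj = simulate(baseline_params, init, np.linspace(0, 600, 301))
        assert traj.B[-1] == pytest.approx(b, rel=1e-6)

    def test_steady_state_limits(self, init):
        tiny = steady_state_B(
            AdhesionKineticParams(0.1 / 600, 0.1, 0.7, 1e-9), init
        )
        assert tiny < 1e-7
        irreversible = steady_state_B(
            AdhesionKineticParams(1e3, 1e-9, 0.7, 0.3), init
        )
        assert irreversible == pytest.approx(init.L0 + init.B0, rel=1e-6)

    def test_steady_state_requires_active_rates(self, init):
        with pytest.raises(ValueError):
            steady_state_B(AdhesionKineticParams(0.0, 0.1, 0.7, 0.3), init)
        with pytest.raises(ValueError):
            steady_state_B(AdhesionKineticParams(1e-4, 0.1, 0.0, 0.3), init)


class TestPredictSignal:
    def test_calibration_statement(self, baseline_params, init, cal):
        traj = simulate(baseline_params, init, np.linspace(0, 600, 200))
        signal = predict_signal(traj, cal)
        assert signal[-1] == pytest.approx(traj.B[-1] * 200.0)
        # B = 6 µm⁻² corresponds to 1200 pm
        assert 6.0 * 1 / cal.alpha == pytest.approx(1200.0)

    def test_linearity(self, baseline_params, init, cal):
        traj = simulate(baseline_params, init, np.linspace(0, 100, 50))
        doubled = type(traj)(t=traj.t, L=traj.L, I=traj.I, B=2 * traj.B)
        assert np.allclose(predict_signal(doubled, cal), 2 * predict_signal(traj, cal))


class TestFitKinetics:
    def test_noiseless_round_trip(self, clean_triplicate, baseline_params, init, cal):
        fit = fit_kinetics(clean_triplicate, init, cal, n_starts=1, multi_start=False)
        p, true = fit.params, baseline_params
        for name in ("k2", "k3", "I_max"):
            assert getattr(p, name) == pytest.approx(getattr(true, name), rel=0.01)
        assert p.kd2d == pytest.approx(true.kd2d, rel=0.01)
        assert fit.r_squared > 1 - 1e-9

    def test_noisy_fit_quality(self, noisy_triplicate, init, cal):
        fit = fit_kinetics(noisy_triplicate, init, cal, n_starts=2, seed=0)
        assert fit.r_squared > 0.99

    def test_flat_trace_rejected(self, init, cal):
        t = np.linspace(0, 100, 60)
        flat = KineticTrace(t=t, dlambda=np.full_like(t, 3.0))
        with pytest.raises(FitFailure):
            fit_kinetics(flat, init, cal)

    def test_smoothed_argmax_ignores_spike(self):
        y = np.concatenate([np.linspace(0, 10, 50), np.full(50, 10.0)])
        y_spiked = y.copy()
        y_spiked[20] = 50.0  # single-sample noise spike
        assert _smoothed_argmax(y_spiked) > 40

    def test_monotone_k3_family_preserved(self, init, cal, time_grid):
        # decreasing true recruitment rate -> decreasing fitted rate
        k3_true = [1.2, 0.7, 0.35, 0.18]
        fitted = []
        for k3 in k3_true:
            p = AdhesionKineticParams(0.1 / 600, 0.1, k3, 0.3)
            y = predict_signal(simulate(p, init, time_grid), cal)
            tr = KineticTrace(t=time_grid, dlambda=y)
            fit = fit_kinetics(tr, init, cal, n_starts=1, multi_start=False)
            fitted.append(fit.params.k3)
        assert all(a > b for a, b in zip(fitted, fitted[1:]))


class TestDerivedQuantities:
    def test_values(self, baseline_params, init, cal):
        dq = derived_quantities(baseline_params, init, cal)
        assert dq.kd2d_kinetic == pytest.approx(600.0, rel=1e-9)
        assert dq.kd3d_kinetic == pytest.approx(9.96, rel=0.01)
        assert dq.B_max == pytest.approx(7.4963, rel=1e-4)
        assert dq.I_total_sat == pytest.approx(dq.B_max + 0.6, rel=1e-9)

    def test_monotone_in_imax(self, baseline_params, init, cal):
        doubled = AdhesionKineticParams(
            baseline_params.k1, baseline_params.k2, baseline_params.k3,
            2 * baseline_params.I_max,
        )
        assert (
            derived_quantities(doubled, init, cal).I_total_sat
            > derived_quantities(baseline_params, init, cal).I_total_sat
        )

    def test_k1_zero_flagged(self, init, cal):
        with pytest.raises(ValueError):
            derived_quantities(AdhesionKineticParams(0, 0.1, 0.7, 0.3), init, cal)


class TestRateUnitHelpers:
    def test_kon_conversion_linear(self):
        # k1 µm²/min over a 100 nm zone: ×0.1 µm ×1e-15 L/µm³ /60 s ×N_A
        assert k1_2d_to_kon3d(1.667e-4, 100.0) == pytest.approx(
            1.667e-4 * 0.1 * 1e-15 / 60 * 6.02214076e23, rel=1e-9
        )
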