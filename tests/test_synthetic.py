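import numpy as np
import pytest

from rwgkinetics import (
    DEFAULT_CONCENTRATIONS,
    NoiseSpec,
    SignalCalibration,
    default_profile,
    fit_isotherm,
    generate_kinetic_dataset,
    generate_saturation_dataset,
    predict_signal,
    simulate,
)
from rwgkinetics.synthetic import params_at_concentration


class TestDoseProfile:
    def test_grid_contains_control_and_span(self):
        assert DEFAULT_CONCENTRATIONS[0] == 0.0
        assert DEFAULT_CONCENTRATIONS[1] == pytest.approx(6.25e-5)
        assert DEFAULT_CONCENTRATIONS[-1] == pytest.approx(1.25)
        assert len(DEFAULT_CONCENTRATIONS) == 11

    def test_baseline_anchor(self):
        p = params_at_concentration(0.0)
        assert p.kd2d == pytest.approx(600.0)
        assert p.I_max == pytest.approx(0.3)

    def test_k2_constant_across_doses(self):
        prof = default_profile()
        k2 = {prof.params_at(c).k2 for c in prof.concentrations}
        assert len(k2) == 1

    def test_k3_non_increasing(self):
        prof = default_profile()
        k3 = [prof.params_at(c).k3 for c in prof.concentrations]
        assert all(a >= b - 1e-12 for a, b in zip(k3, k3[1:]))

    def test_k1_bump_then_decline(self):
        prof = default_profile()
        cs = prof.concentrations
        k1 = [prof.params_at(c).k1 for c in cs]
        base = k1[0]
        assert k1[1] > base and k1[2] > base  # two mildest doses
        assert all(v < base for v in k1[3:])  # stronger digestion

    def test_imax_step(self):
        prof = default_profile()
        i = {c: prof.params_at(c).I_max for c in prof.concentrations}
        assert i[6.25e-5] == pytest.approx(0.3, rel=1e-6)
        assert i[6.25e-3] == pytest.approx(0.3, rel=0.05)
        assert i[1.25] == pytest.approx(0.6, rel=1e-6)

    def test_kd_ratio_top_to_baseline(self):
        prof = default_profile()
        ratio = prof.params_at(1.25).kd2d / prof.params_at(0.0).kd2d
        assert ratio == pytest.approx(1700.0 / 600.0, rel=0.02)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            default_profile((0.0, -1.0))
        with pytest.raises(ValueError):
            default_profile((0.1, 1.0))  # control missing


class TestKineticDatasetGenerator:
    def test_deterministic_given_seed(self, init, cal):
        prof = default_profile((0.0, 1.25))
        noise = NoiseSpec(sigma=10.0, n_replicates=2, sampling_dt=60.0, seed=42)
        a = generate_kinetic_dataset(prof, init, cal, noise)
        b = generate_kinetic_dataset(prof, init, cal, noise)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.dlambda, tb.dlambda)

    def test_zero_noise_equals_model(self, init, cal):
        prof = default_profile((0.0,))
        noise = NoiseSpec(sigma=0.0, n_replicates=1, sampling_dt=60.0, seed=0)
        (trace,) = generate_kinetic_dataset(prof, init, cal, noise)
        clean = predict_signal(simulate(prof.params_at(0.0), init, trace.t), cal)
        assert np.allclose(trace.dlambda, clean)

    def test_replicate_mean_converges_to_model(self, init, cal):
        # CLT: mean of 100 replicates within 3σ/sqrt(100) pointwise, away
        # from the clipped-at-zero start of the curve
        prof = default_profile((0.0,))
        noise = NoiseSpec(sigma=10.0, n_replicates=100, sampling_dt=60.0, seed=3)
        traces = generate_kinetic_dataset(prof, init, cal, noise)
        stack = np.vstack([tr.dlambda for tr in traces])
        clean = predict_signal(simulate(prof.params_at(0.0), init, traces[0].t), cal)
        mask = clean > 5 * noise.sigma  # clipping negligible here
        dev = np.abs(stack.mean(axis=0) - clean)[mask]
        assert np.mean(dev <= 3 * noise.sigma / 10) > 0.99

    def test_sampling_resolution(self, init, cal):
        prof = default_profile((0.0,))
        noise = NoiseSpec(sigma=0.0, n_replicates=1, sampling_dt=3.0, seed=0)
        (trace,) = generate_kinetic_dataset(prof, init, cal, noise, duration=10.0)
        assert np.allclose(np.diff(trace.t), 3.0 / 60.0)

    def test_noise_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            NoiseSpec(n_replicates=0)
        with pytest.raises(ValueError):
            NoiseSpec(sampling_dt=0.0)


class TestSaturationGenerator:
    def test_noiseless_round_trip(self, cal):
        noise = NoiseSpec(sigma=0.0, n_replicates=3, seed=0)
        data = generate_saturation_dataset(4708.0, 1400.0, noise=noise)
        fit = fit_isotherm(data, cal)
        assert fit.kd2d_static == pytest.approx(4708.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1400.0, rel=1e-6)

    def test_control_surface_signal_is_noise(self):
        noise = NoiseSpec(sigma=15.0, n_replicates=3, seed=1)
        data = generate_saturation_dataset(4708.0, 1400.0, noise=noise)
        # Q=0 (pure antifouling polymer, cell-repellent): only noise remains
        assert abs(data.dlambda_max[data.L0 == 0.0][0]) < 5 * noise.sigma

    def test_noiseless_signal_monotone_in_density(self):
        noise = NoiseSpec(sigma=0.0, n_replicates=1, seed=0)
        data = generate_saturation_dataset(4708.0, 1400.0, noise=noise)
        order = np.argsort(data.L0)
        assert np.all(np.diff(data.dlambda_max[order]) >= 0)

    def test_seeded_determinism(self):
        noise = NoiseSpec(sigma=10.0, n_replicates=3, seed=11)
        a = generate_saturation_dataset(4708.0, 1400.0, noise=noise)
        b = generate_saturation_dataset(4708.0, 1400.0, noise=noise)
        assert np.array_equal(a.dlambda_max, b.dlambda_max)
        assert np.array_equal(a.sd, b.sd)
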