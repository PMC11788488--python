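"""Synthetic-data generator: layouts, latent fields, signal synthesis."""

import numpy as np
import pytest

from vemap import synthdata as sd
from vemap.datatypes import AcquisitionConfig
from vemap.links import softplus
from vemap.signals import fit_sinusoid_baseline, synchronize_and_subsample


class TestProbeLayout:
    def test_counts_and_bounds(self):
        probes = sd.sample_probe_layout(7, 30, (600, 600), seed=1)
        assert len(probes) == 37
        assert sum(p.is_magnetic for p in probes) == 7
        locs = np.array([p.location for p in probes])
        assert np.all(locs >= 0) and np.all(locs <= 600)

    def test_reference_only_layout(self):
        probes = sd.sample_probe_layout(0, 5, (100, 100), seed=3)
        assert len(probes) == 5 and not any(p.is_magnetic for p in probes)

    def test_radii_model(self):
        probes = sd.sample_probe_layout(500, 0, (5000, 5000), seed=4)
        true_r = np.array([p.true_radius for p in probes])
        meas_err = np.array([p.measured_radius - p.true_radius for p in probes])
        assert np.mean(true_r) == pytest.approx(6.14, abs=0.06)
        assert np.std(true_r) == pytest.approx(0.36, abs=0.05)
        assert np.std(meas_err) == pytest.approx(0.1, abs=0.02)
        assert np.all(true_r > 1.0)

    def test_seed_reproducibility(self):
        a = sd.sample_probe_layout(5, 5, (200, 200), seed=9)
        b = sd.sample_probe_layout(5, 5, (200, 200), seed=9)
        assert all(
            np.array_equal(p.location, q.location) and p.measured_radius == q.measured_radius
            for p, q in zip(a, b)
        )

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            sd.sample_probe_layout(1, 1, (0, 100), seed=0)


class TestTrueFields:
    def test_zero_amplitude_gives_mean_field(self):
        locs = np.random.default_rng(0).uniform(0, 500, (20, 2))
        f = sd.sample_true_fields(
            locs, kernel_g={"amplitude": 0.0, "length_scales": (100, 100)}, mean_gstar_link=50.0
        )
        assert np.allclose(f.gstar, softplus(50.0))

    def test_zero_latent_phase_is_pi_over_six(self):
        f = sd.sample_true_fields(
            [[0.0, 0.0]],
            kernel_h={"amplitude": 0.0, "length_scales": (100, 100)},
            mean_phi_link=0.0,
        )
        assert f.phi[0] == pytest.approx(np.pi / 6)

    def test_latent_correlation_matches_kernel(self):
        # two points 100 um apart, l = 100 um: corr = exp(-0.5)
        locs = np.array([[0.0, 0.0], [100.0, 0.0]])
        draws = np.array(
            [
                sd.sample_true_fields(
                    locs,
                    kernel_g={"amplitude": 1.0, "length_scales": (100.0, 100.0)},
                    seed=s,
                ).latent_g
                for s in range(500)
            ]
        )
        r = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        expected = np.exp(-0.5)
        se = (1 - expected**2) / np.sqrt(500 - 3)
        assert abs(r - expected) < 3 * se

    def test_range_invariants_many_draws(self):
        # >= 1e4 values across wide-amplitude draws stay in physical range
        rng = np.random.default_rng(5)
        total = 0
        for s in range(5):
            locs = rng.uniform(0, 600, (2000, 2))
            f = sd.sample_true_fields(
                locs,
                kernel_g={"amplitude": 20.0, "length_scales": (50, 50), "white_noise_sd": 1.0},
                kernel_h={"amplitude": 2.0, "length_scales": (50, 50), "white_noise_sd": 0.1},
                seed=s,
            )
            assert np.all(f.gstar > 0)
            assert np.all((f.phi >= 0) & (f.phi <= np.pi / 2))
            total += len(f.gstar)
        assert total >= 10_000


class TestSynthesizeDisplacements:
    def _one_probe_setup(self, gstar=50.0, radius=6.14):
        probe = sd.Probe("m0", "magnetic", [50.0, 50.0], measured_radius=radius, true_radius=radius)
        fields = sd.TrueFieldSample(
            locations=[[50.0, 50.0]],
            gstar=[gstar],
            phi=[0.3],
            latent_g=[0.0],
            latent_h=[0.0],
        )
        return probe, fields

    def test_amplitude_and_noiseless_roundtrip(self):
        probe, fields = self._one_probe_setup()
        sig = sd.synthesize_displacements(
            fields, [probe], fv=316_039.3, noise_sd=0.0, seed=0
        )[0]
        est = fit_sinusoid_baseline(sig, fv=316_039.3, r=6.14)
        assert est.amplitude == pytest.approx(52.96, abs=0.05)
        assert est.gstar == pytest.approx(50.0, rel=1e-8)
        assert est.phi == pytest.approx(0.3, abs=1e-8)

    def test_amplitude_scalings(self):
        def amp(gstar, radius):
            probe, fields = self._one_probe_setup(gstar, radius)
            sig = sd.synthesize_displacements(fields, [probe], fv=280_000.0, noise_sd=0.0)[0]
            return fit_sinusoid_baseline(sig, fv=280_000.0, r=radius).amplitude

        base = amp(50.0, 6.14)
        assert amp(100.0, 6.14) == pytest.approx(base / 2, rel=1e-9)
        assert amp(50.0, 12.28) == pytest.approx(4 * base, rel=1e-9)

    def test_replicates_per_matched_reference(self):
        probes = sd.sample_probe_layout(2, 10, (300, 300), seed=2)
        mag_locs = np.array([p.location for p in probes if p.is_magnetic])
        fields = sd.sample_true_fields(mag_locs, seed=0)
        signals = sd.synthesize_displacements(fields, probes, seed=1)
        per_probe = {}
        for s in signals:
            per_probe.setdefault(s.magnetic_probe_id, set()).add(s.reference_probe_id)
        assert all(len(refs) == 3 for refs in per_probe.values())

    def test_prior_predictive_amplitude_range(self):
        # amplitudes under the default priors bracket the 25-140 nm range
        rng = np.random.default_rng(42)
        n = 2000
        mu = rng.normal(50.0, 15.0, n)
        r = rng.normal(6.14, 0.36, n)
        fv = rng.normal(280_000.0, 14_000.0, n)
        g = np.maximum(softplus(mu), 1e-3)
        amps = 2.0 * fv * (r * 1e-6) ** 2 / (9.0 * g) * 1e9
        assert np.mean((amps > 10) & (amps < 200)) >= 0.90


class TestCalibrationSignals:
    def test_amplitude_closed_form_and_linearity(self):
        probe = sd.Probe("m0", "magnetic", [0, 0], measured_radius=6.14, true_radius=6.14)
        acq = AcquisitionConfig()

        def amp(fv):
            sig = sd.synthesize_calibration_signals(
                [probe], fv=fv, viscosity=29.2, acq=acq, offset_sd_nm=0.0, noise_sd_nm=0.0
            )[0]
            return np.ptp(sig.displacements) / 2.0

        assert amp(280_000.0) == pytest.approx(255.7, abs=0.5)
        assert amp(560_000.0) == pytest.approx(2 * amp(280_000.0), rel=1e-9)

    def test_invalid_viscosity(self):
        probe = sd.Probe("m0", "magnetic", [0, 0], measured_radius=6.14)
        with pytest.raises(ValueError):
            sd.synthesize_calibration_signals([probe], viscosity=0.0)


def test_dataset_roundtrip_recovery(acq_short):
    """Zero-noise FOV: baseline fits recover the true fields to 1e-8."""
    fov, truth = sd.make_fov_dataset(
        "f0", n_magnetic=3, n_reference=10, acq=acq_short, noise_sd=0.0, seed=3
    )
    fov.signals = [synchronize_and_subsample(s, factor=10) for s in fov.signals]
    for i, p in enumerate(fov.magnetic_probes()):
        est = fit_sinusoid_baseline(fov.signals_for(p.id)[0], fv=280_000.0, r=p.true_radius)
        assert est.gstar == pytest.approx(truth.gstar[i], rel=1e-8)
        assert est.phi == pytest.approx(truth.phi[i], abs=1e-8)
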