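"""Preprocessing and the deterministic least-squares baseline."""

import numpy as np
import pytest

from vemap.datatypes import DisplacementSignal, Probe
from vemap.signals import (
    fit_sinusoid_baseline,
    match_references,
    pointwise_fv,
    subtract_reference,
    synchronize_and_subsample,
)


def _signal(times, disp, f=0.05):
    return DisplacementSignal("m0", "raw", times, disp, f)


def _sinusoid(amplitude=50.0, phi=0.3, f=0.05, n=240, dt=0.25, noise=None, rng=None):
    t = np.arange(n) * dt
    d = amplitude * np.sin(2 * np.pi * f * t - phi)
    if noise is not None:
        d = d + rng.normal(0.0, noise, n)
    return _signal(t, d, f)


class TestMatchReferences:
    def _setup(self, distances):
        mag = Probe("m0", "magnetic", [0.0, 0.0], measured_radius=6.0)
        refs = [Probe(f"r{i}", "reference", [d, 0.0]) for i, d in enumerate(distances)]
        return mag, refs

    @pytest.mark.parametrize(
        "distances, expected",
        [
            ([40, 60, 100, 250], ["r1", "r2"]),  # window [50, 200] forces selection
            ([30, 30, 30], []),
            ([55, 60, 65, 70, 75], ["r0", "r1", "r2"]),  # three nearest of five
        ],
    )
    def test_window_and_k(self, distances, expected):
        mag, refs = self._setup(distances)
        matched = match_references(mag, refs, 50.0, 200.0, k=3)
        assert [r.id for r in matched] == expected

    def test_invalid_window(self):
        mag, refs = self._setup([60])
        with pytest.raises(ValueError):
            match_references(mag, refs, 200.0, 50.0)


class TestSubtractReference:
    def test_removes_common_mode_exactly(self):
        t = np.arange(100) * 0.25
        clean = 30 * np.sin(2 * np.pi * 0.05 * t)
        common = np.random.default_rng(0).normal(0, 10, 100)
        mag = DisplacementSignal("m0", "raw", t, clean + common, 0.05)
        ref = DisplacementSignal("r0", "raw", t, common, 0.05)
        out = subtract_reference(mag, ref)
        assert np.allclose(out.displacements, clean)
        assert out.reference_probe_id == "r0"

    def test_antisymmetry(self):
        t = np.arange(50) * 0.25
        rng = np.random.default_rng(1)
        a = DisplacementSignal("a", "raw", t, rng.normal(size=50), 0.05)
        b = DisplacementSignal("b", "raw", t, rng.normal(size=50), 0.05)
        assert np.allclose(
            subtract_reference(a, b).displacements, -subtract_reference(b, a).displacements
        )

    def test_mismatched_grids_rejected(self):
        t = np.arange(50) * 0.25
        a = DisplacementSignal("a", "raw", t, np.zeros(50), 0.05)
        b = DisplacementSignal("b", "raw", t + 0.1, np.zeros(50), 0.05)
        with pytest.raises(ValueError):
            subtract_reference(a, b)


class TestSynchronizeSubsample:
    def test_tenfold_subsample(self):
        sig = _signal(np.arange(2400) * 0.025, np.zeros(2400))
        out = synchronize_and_subsample(sig, factor=10)
        assert len(out) == 240
        assert np.all(np.diff(out.times) > 0)

    def test_factor_one_identity(self):
        sig = _sinusoid()
        out = synchronize_and_subsample(sig, factor=1)
        assert np.array_equal(out.displacements, sig.displacements)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            synchronize_and_subsample(_sinusoid(), factor=0)


class TestBaselineFit:
    def test_noiseless_recovery(self):
        est = fit_sinusoid_baseline(_sinusoid(50.0, 0.3), fv=280_000.0, r=6.14)
        assert est.amplitude == pytest.approx(50.0, rel=1e-10)
        assert est.phase == pytest.approx(0.3, abs=1e-10)
        assert est.flag == "ok"

    def test_stiffness_inversion(self):
        # A = 52.96 nm at fv=316039.3, r=6.14 should invert to 50 Pa
        from vemap.units import displacement_amplitude_nm

        a = float(displacement_amplitude_nm(316_039.3, 6.14, 50.0))
        est = fit_sinusoid_baseline(_sinusoid(a, 0.1), fv=316_039.3, r=6.14)
        assert est.gstar == pytest.approx(50.0, rel=1e-9)

    def test_pure_cosine_phase_convention(self):
        t = np.arange(240) * 0.25
        sig = _signal(t, 40 * np.cos(2 * np.pi * 0.05 * t))
        est = fit_sinusoid_baseline(sig, fv=280_000.0, r=6.14)
        assert est.phase == pytest.approx(-np.pi / 2, abs=1e-9)
        assert est.flag == "phase-out-of-range"

    def test_degenerate_signal_rejected(self):
        sig = _signal(np.arange(240) * 0.25, np.zeros(240))
        with pytest.raises(ValueError):
            fit_sinusoid_baseline(sig, fv=280_000.0, r=6.14)

    def test_unbiased_under_noise(self):
        """Mean amplitude/phase errors over 1000 noisy replicates are ~0."""
        rng = np.random.default_rng(8)
        amps, phis = [], []
        for _ in range(1000):
            est = fit_sinusoid_baseline(
                _sinusoid(50.0, 0.3, noise=5.0, rng=rng), fv=280_000.0, r=6.14
            )
            amps.append(est.amplitude)
            phis.append(est.phase)
        for err, vals in ((np.mean(amps) - 50.0, amps), (np.mean(phis) - 0.3, phis)):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(err) < 3 * se + 1e-3


class TestPointwiseFv:
    def _oil_signal(self, amplitude, drift=2.0, f=0.05):
        t = np.arange(240) * 0.25
        x = -amplitude * np.cos(2 * np.pi * f * t) + 100.0 + drift * t
        return _signal(t, x, f)

    def test_closed_form_inversion(self):
        # A = 255.7 nm, r=6.14, eta=29.2, f=0.05 -> fv = 280000
        fv = pointwise_fv(self._oil_signal(255.7), r=6.14, eta=29.2)
        assert fv == pytest.approx(280_000.0, rel=2e-3)

    def test_linear_in_amplitude(self):
        f1 = pointwise_fv(self._oil_signal(100.0), 6.14, 29.2)
        f2 = pointwise_fv(self._oil_signal(200.0), 6.14, 29.2)
        assert f2 == pytest.approx(2 * f1, rel=1e-6)
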