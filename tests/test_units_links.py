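"""Unit conversions, link functions and kernel identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vemap import links, units


class TestUnits:
    def test_displacement_amplitude_matches_closed_form(self):
        # 2 * fv * r^2 / (9 |G*|) at fv=316039.3 N/m^3, r=6.14 um, 50 Pa
        a = units.displacement_amplitude_nm(316_039.3, 6.14, 50.0)
        assert a == pytest.approx(52.96, abs=0.05)
        # inside the instrument's working range
        assert 25.0 < a < 140.0

    def test_amplitude_proportionalities(self):
        a = units.displacement_amplitude_nm(316_039.3, 6.14, 50.0)
        assert units.displacement_amplitude_nm(316_039.3, 6.14, 100.0) == pytest.approx(a / 2)
        assert units.displacement_amplitude_nm(316_039.3, 12.28, 50.0) == pytest.approx(4 * a)

    def test_gstar_inverts_amplitude(self):
        a = units.displacement_amplitude_nm(316_039.3, 6.14, 50.0)
        assert units.gstar_from_amplitude_pa(316_039.3, 6.14, a) == pytest.approx(50.0)

    def test_calibration_amplitude_closed_form(self):
        # 2 r^2 fv / (9 eta omega) at fv=280000, r=6.14 um, eta=29.2 Pa s, f=0.05 Hz
        a = units.calibration_amplitude_nm(280_000.0, 6.14, 29.2, 0.05)
        assert a == pytest.approx(255.7, abs=0.5)
        assert units.fv_from_calibration_amplitude(a, 6.14, 29.2, 0.05) == pytest.approx(280_000.0)

    def test_force_amplitude(self):
        # fv * (4/3) pi r^3, printed as 0.3 nN
        f_n = units.force_amplitude_n(316_039.3, 6.14)
        assert f_n * 1e9 == pytest.approx(0.3, abs=0.01)

    def test_nonpositive_gstar_rejected(self):
        with pytest.raises(ValueError):
            units.displacement_amplitude_nm(280_000.0, 6.14, 0.0)


class TestLinks:
    def test_softplus_identities(self):
        assert links.softplus(0.0) == pytest.approx(np.log(2))
        assert links.softplus(50.0) == pytest.approx(50.0, abs=1e-20)
        assert links.stiffness_link(0.0, 0.0) == pytest.approx(0.6931, abs=1e-4)

    def test_phase_link_identities(self):
        assert links.phase_link(0.0, 0.0) == pytest.approx(np.pi / 6)
        assert links.phase_link(40.0, 0.0) == pytest.approx(np.pi / 2, abs=1e-10)
        assert links.phase_link(-40.0, 0.0) == pytest.approx(0.0, abs=1e-10)

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=50)
    def test_softplus_roundtrip(self, x):
        assert links.inv_softplus(links.softplus(x)) == pytest.approx(x, abs=1e-10)

    @given(st.floats(-12, 12))
    @settings(deadline=None, max_examples=50)
    def test_phase_roundtrip_safe_range(self, x):
        # beyond |x| ~ 12 the sigmoid saturates in double precision
        assert links.inv_phase_link(links.phase_link(x, 0.0), 0.0) == pytest.approx(x, abs=1e-10)

    @given(st.floats(-20, 20), st.floats(-20, 20))
    @settings(deadline=None, max_examples=50)
    def test_links_monotone(self, a, b):
        lo, hi = min(a, b), max(a, b)
        if hi - lo > 1e-9:
            assert links.softplus(hi) > links.softplus(lo)
            assert links.phase_link(hi, 0.0) > links.phase_link(lo, 0.0)


class TestExpQuadCov:
    def test_diagonal_and_offdiagonal(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0]])
        k = links.exp_quad_cov(x, amplitude=1.0, length_scales=(1.0, 1.0), white_noise_sd=0.5)
        assert k[0, 0] == pytest.approx(1.0 + 0.25)
        assert k[0, 1] == pytest.approx(np.exp(-0.5), abs=1e-4)

    def test_long_length_scale_limit(self):
        x = np.array([[0.0, 0.0], [100.0, 50.0]])
        k = links.exp_quad_cov(x, 2.0, (1e8, 1e8))
        assert k[0, 1] == pytest.approx(4.0, rel=1e-6)

    @given(st.integers(2, 8), st.integers(0, 1000))
    @settings(deadline=None, max_examples=25)
    def test_symmetric_positive_definite_with_jitter(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 300, size=(n, 2))
        k = links.exp_quad_cov(x, 3.0, (80.0, 120.0), white_noise_sd=0.1)
        assert np.allclose(k, k.T)
        chol = links.chol_with_jitter(k)
        assert np.allclose(chol @ chol.T, k, atol=1e-6 * 9.0)

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            links.exp_quad_cov(np.array([[0.0, np.inf]]), 1.0, (1.0, 1.0))
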