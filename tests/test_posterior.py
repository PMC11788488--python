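"""Field maps, cross-sections, population means and condition contrasts."""

import numpy as np
import pytest

from vemap.links import softplus
from vemap.posterior import (
    ContrastResult,
    cross_section,
    exceedance_probability,
    fov_variability_contrast,
    heterogeneity_contrast,
    population_means,
    predict_field,
)
from vemap.spatial import SpatialPosterior


def _hand_built_posterior(
    latent_g=None, alpha=3.0, length=150.0, sigma_sigma=1e-4, mu_g=50.0, n_draws=400, seed=0
):
    """Single-FOV posterior with hand-chosen, draw-constant parameters."""
    rng = np.random.default_rng(seed)
    locs = np.array([[100.0, 100.0], [300.0, 300.0], [500.0, 200.0]])
    n = locs.shape[0]
    latent_g = np.zeros(n) if latent_g is None else np.asarray(latent_g, dtype=float)
    shape = (4, n_draws // 4)

    def tile(vals, extra=()):
        vals = np.asarray(vals, dtype=float)
        return np.broadcast_to(vals, shape + vals.shape).copy()

    draws = {
        "latent_g": tile(latent_g),
        "latent_h": tile(np.zeros(n)),
        "g": tile(softplus(latent_g + mu_g)),
        "h": tile(np.full(n, np.pi / 6)),
        "alpha_g": tile([alpha]),
        "alpha_h": tile([0.3]),
        "l_g": tile([[length, length]]),
        "l_h": tile([[length, length]]),
        "mu_g": tile([mu_g]),
        "mu_h": tile([0.0]),
        "M_g": tile([mu_g]),
        "M_h": tile([0.0]),
        "alpha_mu_g": tile([2.0]),
        "alpha_mu_h": tile([0.1]),
        "alpha_sigma_g": tile([1.0]),
        "alpha_sigma_h": tile([0.5]),
        "sigma_sigma": np.full(shape, sigma_sigma),
        "nu": np.full(shape, 5.0),
        "fv": np.full(shape, 280_000.0),
        "sigma_i": tile(np.full(n, 5.0)),
        "r_star": tile(np.full(n, 6.14)),
        "r_mu": np.full(shape, 6.14),
        "r_sigma": np.full(shape, 0.36),
        "l_sigma": np.full(shape, 1.0),
        "noise_mu": np.full(shape, np.log(5.0)),
        "noise_scale": np.full(shape, 0.5),
    }
    return SpatialPosterior(
        draws=draws,
        probe_ids=["p0", "p1", "p2"],
        locations_um=locs,
        fov_ids=["f0"],
        fov_of_probe=np.zeros(n, dtype=np.intp),
        conditions=["only"],
        condition_of_fov=np.zeros(1, dtype=np.intp),
        coord_scale=100.0,
    )


class TestPredictField:
    def test_interpolates_probe_values_when_white_noise_vanishes(self):
        post = _hand_built_posterior(latent_g=[1.0, -2.0, 0.5])
        probe = post.locations_um[1]
        fmap = predict_field(
            post, "f0", grid=([probe[0]], [probe[1]]), kind="stiffness", seed=1
        )
        expected = post.flat("g")[:, 1].mean()
        assert fmap.mean[0, 0] == pytest.approx(expected, rel=0.01)
        assert fmap.sd[0, 0] < 0.05

    def test_constant_field_maps_flat(self):
        post = _hand_built_posterior(latent_g=[0.0, 0.0, 0.0], alpha=0.5)
        fmap = predict_field(post, "f0", kind="stiffness", n_grid=12, seed=2)
        assert np.ptp(fmap.mean) < 3 * fmap.sd.max()
        assert np.all(fmap.mean > 0)

    def test_uncertainty_grows_away_from_probes(self, fitted_spatial):
        post, _, _ = fitted_spatial
        fov_id = post.fov_ids[0]
        idx = post.probe_indices(fov_id)
        locs = post.locations_um[idx]
        far = locs.mean(axis=0) + np.array([900.0, 900.0])
        near = locs[0]
        fmap = predict_field(
            post,
            fov_id,
            grid=([near[0], far[0]], [near[1], far[1]]),
            kind="stiffness",
            seed=3,
        )
        assert fmap.sd[1, 1] > fmap.sd[0, 0]

    def test_phase_map_respects_range(self, fitted_spatial):
        post, _, _ = fitted_spatial
        fmap = predict_field(post, post.fov_ids[0], kind="phase", n_grid=10, seed=4)
        assert np.all((fmap.mean >= 0) & (fmap.mean <= np.pi / 2))

    def test_grid_refinement_stability(self):
        post = _hand_built_posterior(latent_g=[1.0, -1.0, 0.5])
        idx = post.probe_indices("f0")
        locs = post.locations_um[idx]
        x_coarse = np.linspace(locs[:, 0].min(), locs[:, 0].max(), 5)
        y = np.array([200.0])
        coarse = predict_field(post, "f0", grid=(x_coarse, y), max_draws=400, seed=5)
        fine_x = np.linspace(locs[:, 0].min(), locs[:, 0].max(), 9)  # includes coarse nodes
        fine = predict_field(post, "f0", grid=(fine_x, y), max_draws=400, seed=5)
        assert np.allclose(coarse.mean[0], fine.mean[0, ::2], rtol=0.01, atol=0.05)

    def test_empty_grid_rejected(self):
        post = _hand_built_posterior()
        with pytest.raises(ValueError):
            predict_field(post, "f0", grid=([], []))


class TestCrossSection:
    def test_flat_field_flat_profile(self):
        post = _hand_built_posterior(latent_g=[0.0, 0.0, 0.0], alpha=0.5)
        cs = cross_section(post, "f0", axis="x", kind="stiffness", seed=6)
        assert np.ptp(cs.mean) < 0.2 * np.mean(cs.hi - cs.lo)
        assert np.all(cs.lo <= cs.mean) and np.all(cs.mean <= cs.hi)

    def test_band_contains_probe_interval(self, fitted_spatial):
        post, _, _ = fitted_spatial
        fov_id = post.fov_ids[0]
        idx = post.probe_indices(fov_id)
        xp = posterior_locs = post.locations_um[idx]
        cs = cross_section(post, fov_id, axis="x", at=xp[0, 1], kind="stiffness", seed=7)
        # at the probe's x position the profile sits inside the probe's own interval
        node = np.argmin(np.abs(cs.coords - xp[0, 0]))
        g_draws = post.flat("g")[:, idx[0]]
        lo, hi = np.percentile(g_draws, [0.5, 99.5])
        assert lo - 1.0 <= cs.mean[node] <= hi + 1.0


class TestPopulationMeans:
    def test_link_consistency(self, fitted_spatial):
        post, _, _ = fitted_spatial
        cond = post.conditions[0]
        pm = population_means(post, cond)
        c = post.conditions.index(cond)
        assert pm["stiffness"]["mean"] == pytest.approx(
            softplus(post.flat("M_g")[:, c]).mean()
        )
        assert 0 <= pm["phase"]["mean"] <= np.pi / 2

    def test_unknown_condition_rejected(self, fitted_spatial):
        post, _, _ = fitted_spatial
        with pytest.raises(ValueError):
            population_means(post, "no-such-condition")


class TestContrasts:
    def _two_condition_posterior(self, shift=0.0, seed=0):
        post = _hand_built_posterior(seed=seed)
        rng = np.random.default_rng(seed)
        shape = post.draws["nu"].shape
        for name in ("alpha_mu_g", "alpha_mu_h", "alpha_sigma_g", "alpha_sigma_h", "M_g", "M_h"):
            a = rng.normal(0.0, 1.0, shape)
            b = rng.normal(-shift, 1.0, shape)
            post.draws[name] = np.stack([a, b], axis=-1)
        post.conditions = ["caf", "ctrl"]
        post.condition_of_fov = np.zeros(1, dtype=np.intp)
        return post

    def test_exchangeable_conditions_give_half(self):
        post = self._two_condition_posterior(shift=0.0, seed=1)
        res = heterogeneity_contrast(post, "caf", "ctrl")
        assert res["stiffness"].probability_positive == pytest.approx(0.5, abs=0.1)
        assert abs(res["stiffness"].mean) < 0.2

    def test_shifted_condition_detected_and_antisymmetric(self):
        post = self._two_condition_posterior(shift=3.0, seed=2)
        ab = heterogeneity_contrast(post, "caf", "ctrl")
        ba = heterogeneity_contrast(post, "ctrl", "caf")
        assert ab["stiffness"].probability_positive > 0.95
        assert np.allclose(ab["stiffness"].difference_draws, -ba["stiffness"].difference_draws)
        assert ab["stiffness"].probability_positive + ba["stiffness"].probability_positive == pytest.approx(1.0)

    def test_variability_contrast_uses_alpha_sigma(self):
        post = self._two_condition_posterior(shift=3.0, seed=3)
        res = fov_variability_contrast(post, "caf", "ctrl")
        assert res["stiffness"].probability_positive > 0.95

    def test_unknown_condition_rejected(self):
        post = self._two_condition_posterior()
        with pytest.raises(ValueError):
            heterogeneity_contrast(post, "caf", "nope")


class TestExceedance:
    def test_deterministic_shift(self):
        a = np.arange(100.0)
        assert exceedance_probability(a + 1.0, a) == 1.0

    def test_identical_distributions(self):
        rng = np.random.default_rng(4)
        p = exceedance_probability(rng.normal(size=20_000), rng.normal(size=20_000))
        assert p == pytest.approx(0.5, abs=0.02)

    def test_closed_form_gaussian_case(self):
        from scipy.stats import norm

        rng = np.random.default_rng(5)
        p = exceedance_probability(
            rng.normal(1.0, 1.0, 100_000), rng.normal(0.0, 1.0, 100_000)
        )
        assert p == pytest.approx(norm.cdf(1 / np.sqrt(2)), abs=0.005)

    def test_all_pairs_mode_matches_paired(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.5, 1.0, 40_000)
        b = rng.normal(0.0, 1.0, 30_000)  # unequal lengths -> all-pairs
        p_pairs = exceedance_probability(a, b)
        p_paired = exceedance_probability(a[:30_000], b)
        assert p_pairs == pytest.approx(p_paired, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exceedance_probability([], [1.0])
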