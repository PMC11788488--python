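"""Hierarchical spatial model: densities, diagnostics, recovery."""

import numpy as np
import pytest

from vemap import synthdata as sd
from vemap._dists import normal_logpdf, studentt_logpdf
from vemap._mcmc import MCMCSettings, diagnostics_from_draws
from vemap.signals import baseline_estimates
from vemap.spatial import (
    PriorConfig,
    build_spatial_model,
    fit_spatial,
    mcmc_diagnostics,
    signal_mean,
)
from tests.conftest import FV_TRUE, subsample_fov


class TestSignalMean:
    def test_peak_amplitude_shared_oracle(self):
        # peak displacement = 2 fv r^2 / (9 gstar) = 52.96 nm
        t_peak = (0.25 / 0.05) + 0.0  # quarter period, phi = 0
        val = signal_mean(t_peak, 316_039.3, 6.14, 50.0, 0.0, 0.05)
        assert val == pytest.approx(52.96, abs=0.05)

    def test_phase_shift_turns_sine_into_minus_cosine(self):
        t = np.linspace(0, 40, 100)
        a = signal_mean(t, FV_TRUE, 6.14, 50.0, np.pi / 2, 0.05)
        b = signal_mean(t, FV_TRUE, 6.14, 50.0, 0.0, 0.05)
        amp = 2 * FV_TRUE * (6.14e-6) ** 2 / (9 * 50.0) * 1e9
        assert a[0] == pytest.approx(-amp, rel=1e-9)
        assert b[0] == pytest.approx(0.0, abs=1e-9)

    def test_invalid_gstar(self):
        with pytest.raises(ValueError):
            signal_mean(0.0, FV_TRUE, 6.14, -1.0, 0.0, 0.05)


class TestStudentTLimit:
    def test_converges_to_gaussian(self):
        """t log density approaches the normal one as dof -> infinity."""
        x = np.array([-2.0, -0.5, 0.0, 1.3, 2.7])
        t_ld = studentt_logpdf(x, 1e6, 0.3, 1.7)
        n_ld = normal_logpdf(x, 0.3, 1.7)
        assert np.max(np.abs(t_ld - n_ld)) < 1e-6


class TestModelDensity:
    def test_finite_at_prior_draws(self, small_fov_pair):
        fovs, _ = small_fov_pair
        model = build_spatial_model(fovs, FV_TRUE)
        for seed in range(5):
            theta = model.sample_prior_vector(seed)
            assert np.isfinite(model(theta[None, :])[0])

    def test_finite_at_initial_point(self, small_fov_pair):
        fovs, _ = small_fov_pair
        model = build_spatial_model(fovs, FV_TRUE)
        assert np.isfinite(model(model.initial_point()[None, :])[0])

    def test_prior_predictive_phase_mass_near_solid(self, small_fov_pair):
        """Under mu_phi ~ N(0, 0.3) the prior favours elastic-solid phases."""
        fovs, _ = small_fov_pair
        model = build_spatial_model(fovs, FV_TRUE)
        medians = []
        for seed in range(20):
            _, _, truth = model.simulate_from_prior(seed)
            medians.append(np.median(truth["h"]))
        assert np.median(medians) < np.pi / 4

    def test_fv_uncertainty_mode_adds_parameter(self, small_fov_pair):
        fovs, _ = small_fov_pair
        fixed = build_spatial_model(fovs, FV_TRUE)
        prop = build_spatial_model(fovs, (FV_TRUE, 5000.0))
        assert prop.dim == fixed.dim + 1


class TestDiagnostics:
    def test_identical_chains_rhat_one(self):
        one = np.random.default_rng(0).normal(size=(1, 400))
        rep = {"x": np.repeat(one, 4, axis=0)}
        assert diagnostics_from_draws(rep)["x"]["rhat"] == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(10 * c, 1, 400) for c in range(4)])
        assert diagnostics_from_draws({"x": chains})["x"]["rhat"] > 1.5

    def test_independent_draws_full_ess(self):
        rng = np.random.default_rng(2)
        draws = rng.normal(size=(4, 500))
        ess = diagnostics_from_draws({"x": draws})["x"]["ess_bulk"]
        assert ess == pytest.approx(2000, rel=0.25)

    def test_report_accessor(self, fitted_spatial):
        post, _, _ = fitted_spatial
        report = mcmc_diagnostics(post)
        assert "max_rhat" in report and report["max_rhat"] < 1.1


class TestFit:
    def test_recovery_of_latent_fields(self, fitted_spatial):
        """Posterior g means track the simulated stiffness values."""
        post, fovs, truths = fitted_spatial
        g_true = np.concatenate([t.gstar for t in truths])
        g_post = post.flat("g").mean(axis=0)
        assert np.corrcoef(g_true, g_post)[0, 1] > 0.7
        assert np.median(np.abs(g_post - g_true) / g_true) < 0.15
        # range invariants on the draws themselves
        assert np.all(post.flat("g") > 0)
        h = post.flat("h")
        assert np.all((h >= 0) & (h <= np.pi / 2))

    def test_radius_error_model_is_conservative(self, fitted_spatial):
        post, fovs, _ = fitted_spatial
        r_meas = np.concatenate(
            [[p.measured_radius for p in f.magnetic_probes()] for f in fovs]
        )
        r_post = post.flat("r_star").mean(axis=0)
        assert np.all(np.abs(r_post - r_meas) <= 3 * 0.1)

    def test_radius_error_model_widens_field_uncertainty(self, small_fov_pair):
        """Freeing the radii must not shrink the stiffness-field uncertainty."""
        fovs, _ = small_fov_pair
        sds = {}
        for fixed in (True, False):
            model = build_spatial_model(
                fovs, FV_TRUE, PriorConfig(radius_fixed=fixed)
            )
            post = fit_spatial(model, MCMCSettings(chains=4, draws=300, warmup=500, seed=17))
            sds[fixed] = np.mean(post.flat("g").std(axis=0))
        assert sds[False] > sds[True]

    def test_near_noiseless_matches_baseline_within_one_percent(self, acq_short):
        """With negligible noise the Bayesian means equal the LS inversion."""
        fov, _ = sd.make_fov_dataset(
            "f0", n_magnetic=4, n_reference=12, acq=acq_short, noise_sd=0.05, seed=33
        )
        fov = subsample_fov(fov)
        # radii treated as exact so the comparison isolates the likelihood
        model = build_spatial_model([fov], FV_TRUE, PriorConfig(radius_fixed=True))
        post = fit_spatial(model, MCMCSettings(chains=4, draws=300, warmup=500, seed=34))
        ests = {
            e.probe_id: e
            for e in baseline_estimates(fov.signals, fov.probes, fv=FV_TRUE)
        }
        g_post = post.flat("g").mean(axis=0)
        for i, pid in enumerate(post.probe_ids):
            assert g_post[i] == pytest.approx(ests[pid].gstar, rel=0.01)
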