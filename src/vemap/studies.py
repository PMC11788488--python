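"""Self-contained validation studies.

Each function simulates a study with the package's own generator, runs the
corresponding estimator end to end, and returns summary numbers.  They back
both the acceptance test suite and ``scripts/acceptance.py``; problem sizes
are reduced-scale versions of the full protocol chosen to finish on a single
CPU in minutes (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from . import synthdata as sd
from ._mcmc import MCMCSettings
from .calibration import CalibrationConfig, fit_calibration, summarize_calibration
from .datatypes import AcquisitionConfig, FOVDataset, Probe, TrueFieldSample
from .pointpattern import layout_is_homogeneous
from .posterior import cross_section
from .signals import baseline_estimates, pointwise_fv, synchronize_and_subsample
from .spatial import PriorConfig, build_spatial_model, fit_spatial
from .units import force_amplitude_n

FV_TRUE = 280_000.0
OIL_VISCOSITY = 29.2


def worked_examples() -> dict:
    """Deterministic instrument-arithmetic identities.

    Force amplitude at the fitted fv and mean radius, the camera pixel size in
    the sample plane, the Abbe diffraction limit of the 0.3-NA objective, the
    radius uncertainty in micrometres, and the coefficient of variation of the
    published-style raw calibration summary.
    """
    return {
        "force_amplitude_nN": force_amplitude_n(316_039.3, 6.14) * 1e9,
        "pixel_size_um": 6.5 / 20.0,
        "abbe_resolution_um": 0.5 / (2.0 * 0.3),
        "radius_error_um": 0.78 * (6.5 / 20.0),
        "raw_calibration_cv_percent": 100.0 * 36_712.1 / 317_616.3,
    }


def calibration_precision_study(
    seed: int = 0,
    n_probes: int = 40,
    mcmc: MCMCSettings | None = None,
    subsample: int = 10,
) -> dict:
    """Matched oil-calibration simulation: joint model vs per-probe pipeline.

    True radii are drawn from the probe batch's Normal(6.14, 0.36^2) um, the
    per-probe radius measurement carries a 0.1 um error, and the true force
    constant is 280,000 N/m^3.  The conventional pipeline inverts each
    signal's fitted amplitude at the *nominal* batch radius — it has no
    per-probe radius information — so its spread reflects the unmodelled
    probe-size dispersion; a measured-radius variant is reported alongside.
    The joint posterior shares fv across probes and absorbs radius dispersion
    through the measurement-error model.
    """
    rng = np.random.default_rng(seed)
    mcmc = mcmc or MCMCSettings(chains=4, draws=500, warmup=800, seed=int(rng.integers(2**31)))
    acq = AcquisitionConfig()
    probes = sd.sample_probe_layout(n_probes, 0, acq.fov_extent, seed=rng)
    signals = sd.synthesize_calibration_signals(
        probes, fv=FV_TRUE, viscosity=OIL_VISCOSITY, acq=acq,
        drift_nm_per_s=1.0, noise_sd_nm=5.0, seed=rng,
    )
    signals = [synchronize_and_subsample(s, factor=subsample) for s in signals]

    nominal_radius = float(np.mean([p.measured_radius for p in probes]))
    fv_nominal = np.array([pointwise_fv(s, nominal_radius, OIL_VISCOSITY) for s in signals])
    fv_measured = np.array(
        [pointwise_fv(s, p.measured_radius, OIL_VISCOSITY) for s, p in zip(signals, probes)]
    )

    post = fit_calibration(signals, probes, CalibrationConfig(), mcmc)
    model = summarize_calibration(post)
    lo, hi = np.percentile(post.fv_flat, [2.5, 97.5])

    def cv(x):
        return 100.0 * np.std(x, ddof=1) / np.mean(x)

    return {
        "raw_cv_percent": cv(fv_nominal),
        "raw_cv_measured_radii_percent": cv(fv_measured),
        "model_cv_percent": model["cv_percent"],
        "cv_ratio": model["cv_percent"] / cv(fv_nominal),
        "fv_posterior_mean": model["mean"],
        "fv_true_in_ci": float(lo <= FV_TRUE <= hi),
        "converged": post.converged,
        "n": n_probes,
    }


def _two_region_fov(seed, n_left=4, n_right=3, g_left=50.0, g_right=100.0, acq=None):
    """One FOV with a twofold stiffness step at x = 300 um."""
    rng = np.random.default_rng(seed)
    acq = acq or AcquisitionConfig()
    locs = np.vstack(
        [
            np.column_stack([rng.uniform(40, 240, n_left), rng.uniform(50, 550, n_left)]),
            np.column_stack([rng.uniform(360, 560, n_right), rng.uniform(50, 550, n_right)]),
        ]
    )
    probes = []
    for i, loc in enumerate(locs):
        true_r = rng.normal(6.14, 0.36)
        probes.append(
            Probe(
                id=f"m{i}",
                kind="magnetic",
                location=loc,
                measured_radius=float(true_r + rng.normal(0, 0.1)),
                true_radius=float(true_r),
            )
        )
    gstar = np.where(locs[:, 0] < 300.0, g_left, g_right)
    fields = TrueFieldSample(
        locations=locs,
        gstar=gstar,
        phi=np.full(len(locs), 0.2),
        latent_g=np.zeros(len(locs)),
        latent_h=np.zeros(len(locs)),
    )
    signals = sd.synthesize_displacements(
        fields, probes, fv=FV_TRUE, acq=acq, noise_sd=5.0, noise_df=5.0,
        n_replicates=1, seed=rng,
    )
    fov = FOVDataset("step", "step-gel", 1, probes, signals)
    return fov, gstar, locs


def gradient_detection_study(
    seed: int = 0,
    mcmc: MCMCSettings | None = None,
    subsample: int = 10,
) -> dict:
    """Two-collagen-region verification: recover a twofold stiffness step.

    Seven probes straddle an interface where the true stiffness doubles
    (50 -> 100 Pa).  After fitting, the x cross-section at the FOV centre must
    rise monotonically (within the Monte-Carlo error of the profile nodes)
    and its 95% band must contain the true step outside the unprobed
    interface zone; the posterior ratio of region means should bracket 2.
    """
    rng = np.random.default_rng(seed)
    mcmc = mcmc or MCMCSettings(chains=4, draws=500, warmup=2000, seed=int(rng.integers(2**31)))
    fov, g_true, locs = _two_region_fov(int(rng.integers(2**31)))
    fov.signals = [synchronize_and_subsample(s, factor=subsample) for s in fov.signals]
    model = build_spatial_model([fov], FV_TRUE)
    post = fit_spatial(model, mcmc)

    # transect across the interface: x runs between the two probe-cluster
    # centroids (inside the data support, where a gradient claim is
    # meaningful) and each x is averaged over the probes' y positions
    from .posterior import _linked_conditional_draws

    left = locs[:, 0] < 300.0
    xs = np.linspace(locs[left, 0].mean(), locs[~left, 0].mean(), 30)
    ys = locs[:, 1]
    pts = np.array([[x, y] for x in xs for y in ys])
    draws = _linked_conditional_draws(post, "step", pts, "stiffness",
                                      max_draws=400, seed=seed)
    profile_draws = draws.reshape(draws.shape[0], xs.size, ys.size).mean(axis=2)
    prof_mean = profile_draws.mean(axis=0)
    prof_lo, prof_hi = np.percentile(profile_draws, [2.5, 97.5], axis=0)
    node_se = profile_draws.std(axis=0, ddof=1) / np.sqrt(profile_draws.shape[0])
    diffs = np.diff(prof_mean)
    monotone = bool(np.all(diffs > -3.0 * (node_se[:-1] + node_se[1:])))

    # band containment on the centre-line cross-section, whose
    # pointwise 95% bands reflect the full single-location uncertainty
    cs = cross_section(post, "step", axis="x", kind="stiffness", n_points=40,
                       max_draws=400, seed=seed)
    true_cs = np.where(cs.coords < 300.0, 50.0, 100.0)
    outside_gap = (cs.coords < 250.0) | (cs.coords > 350.0)
    band_cover = float(
        np.mean(
            (cs.lo[outside_gap] <= true_cs[outside_gap])
            & (true_cs[outside_gap] <= cs.hi[outside_gap])
        )
    )

    g = post.flat("g")
    left = locs[:, 0] < 300.0
    ratio_draws = g[:, ~left].mean(axis=1) / g[:, left].mean(axis=1)
    r_lo, r_hi = np.percentile(ratio_draws, [2.5, 97.5])
    return {
        "monotone": monotone,
        "band_coverage_of_step": band_cover,
        "region_ratio_mean": float(np.mean(ratio_draws)),
        "region_ratio_ci": (float(r_lo), float(r_hi)),
        "ratio_ci_contains_2": float(r_lo <= 2.0 <= r_hi),
        "converged": post.converged,
        "n": len(locs),
    }


def sbc_coverage_study(
    seed: int = 0,
    n_replicates: int = 7,
    n_fovs: int = 2,
    n_probes_per_fov: int = 3,
    mcmc_draws: int = 500,
    mcmc_warmup: int = 4000,
    mcmc_thin: int = 4,
    subsample: int = 20,
) -> dict:
    """Simulation-based-calibration check of the stiffness-field intervals.

    For each replicate, parameters and data are drawn from the model's own
    joint prior (fixed fv) and the model is refitted to the simulated data;
    the 95% credible intervals for g(x_i) should then cover the simulated
    truth at 95% rate by construction, so the empirical coverage measures the
    fidelity of the whole inference machinery.
    """
    rng = np.random.default_rng(seed)
    acq = AcquisitionConfig(n_cycles=2)
    template_fovs = []
    for j in range(n_fovs):
        fov, _ = sd.make_fov_dataset(
            f"fov{j}", condition="sbc", n_magnetic=n_probes_per_fov, n_reference=10,
            acq=acq, fv=FV_TRUE, seed=rng,
        )
        fov.signals = [synchronize_and_subsample(s, factor=subsample) for s in fov.signals]
        template_fovs.append(fov)
    priors = PriorConfig()
    template = build_spatial_model(template_fovs, FV_TRUE, priors)

    covered, total = 0, 0
    for rep in range(n_replicates):
        _, fovs, truth = template.simulate_from_prior(int(rng.integers(2**31)))
        model = build_spatial_model(fovs, FV_TRUE, priors)
        post = fit_spatial(
            model,
            MCMCSettings(chains=4, draws=mcmc_draws, warmup=mcmc_warmup,
                         seed=int(rng.integers(2**31)), thin=mcmc_thin),
        )
        g = post.flat("g")
        lo, hi = np.percentile(g, [2.5, 97.5], axis=0)
        covered += int(np.sum((truth["g"] >= lo) & (truth["g"] <= hi)))
        total += g.shape[1]
    return {"coverage": covered / total, "n": total}


def noiseless_equivalence_study(seed: int = 0, subsample: int = 10) -> dict:
    """Near-noiseless signals: Bayesian means vs deterministic inversion.

    With negligible signal noise and radii treated as exact, the posterior
    mean stiffness at each probe must agree with the least-squares baseline
    to within 1% (likelihood dominance).
    """
    rng = np.random.default_rng(seed)
    acq = AcquisitionConfig(n_cycles=2)
    fov, _ = sd.make_fov_dataset(
        "f0", n_magnetic=4, n_reference=12, acq=acq, fv=FV_TRUE,
        noise_sd=0.05, seed=rng,
    )
    fov.signals = [synchronize_and_subsample(s, factor=subsample) for s in fov.signals]
    model = build_spatial_model([fov], FV_TRUE, PriorConfig(radius_fixed=True))
    post = fit_spatial(
        model, MCMCSettings(chains=4, draws=300, warmup=500, seed=int(rng.integers(2**31)))
    )
    ests = {e.probe_id: e.gstar for e in baseline_estimates(fov.signals, fov.probes, fv=FV_TRUE)}
    g_post = post.flat("g").mean(axis=0)
    rel = [
        abs(g_post[i] - ests[pid]) / ests[pid] for i, pid in enumerate(post.probe_ids)
    ]
    return {"max_relative_deviation_percent": 100.0 * float(np.max(rel)), "n": len(rel)}


def ripley_homogeneity_study(seed: int = 0, n_points: int = 200, extent=(1000.0, 1000.0)) -> dict:
    """Layout-generator sanity check against the homogeneous-process null."""
    probes = sd.sample_probe_layout(n_points, 0, extent, seed=seed)
    locs = np.array([p.location for p in probes])
    inside, curve = layout_is_homogeneous(locs, extent, n_sim=199, seed=seed + 1)
    ok = ~np.isnan(curve.g)
    max_dev = float(np.max(np.abs(curve.g[ok] - curve.theoretical[ok])))
    return {"inside_envelope": float(inside), "max_abs_deviation": max_dev, "n": n_points}
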