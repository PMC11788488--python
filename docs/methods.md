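# Methods

This note documents the models implemented in `vemap`, their priors and
numerical treatment, what the synthetic-data generator does and does not
emulate, and the design choices made where the problem left the design open.

## Measurement model

A magnetic microrheometer drives spherical probes (nominal diameter ~10 µm)
embedded in an ECM-mimicking gel with a sinusoidal magnetic force at
frequency f (default 0.05 Hz), while a camera records displacements at 25 ms
frames. In the linear viscoelastic regime the displacement of probe *i* is

    d_i(t) = (2 f_v r_i² / (9 |G*|(x_i))) sin(2π f t − φ(x_i)),

with `f_v` the volumetric force constant (N/m³), `r_i` the probe radius (µm),
`|G*|` the absolute complex shear modulus (Pa) and `φ ∈ [0, π/2]` the phase
angle. All public interfaces use µm/nm/Pa/s; the relation is evaluated in SI
internally, and every conversion passes through `vemap.units`.

Raw probe tracks contain common-mode motion (stage and objective vibration).
Preprocessing (`vemap.signals`) subtracts the tracks of nearby passive
reference probes (matching window 50–200 µm, up to the 3 nearest), aligns to
the force timeline through a shared phase origin, and subsamples tenfold.
Replicate subtracted signals (one per matched reference) are kept as
independent observations by default; a `max-amplitude` mode selecting the
single largest-displacement reference is available. The deterministic
baseline is a linear least-squares fit on {sin, cos, 1}; phases outside
[0, π/2] are flagged, never clamped, and per-probe replicates are aggregated
by the median.

## Force calibration

In a purely viscous silicone oil (η = 29.2 Pa·s: the 30,000 cSt grade at
0.975 g/mL; overridable) Stokes drag balances the magnetic force, giving

    x(t) = −(2 r² f_v)/(9 η ω) cos(ωt) + C.

The joint calibration model (`vemap.calibration`) shares one `f_v` across
probes with prior N(280 000, 14 000²) N/m³, treats each probe's true radius
as latent — `r_meas,i ~ N(r*_i, τ²)` with τ = 0.1 µm, `r*_i ~ N(r_µ, r_σ²)`,
`r_µ ~ N(6, 1)` µm, `r_σ ~ InvGamma(2, 0.5)` — and uses a single Gaussian
noise SD for all signals (tracking in oil is benign). The per-signal offset
`C` is marginalised analytically under a flat prior (mean-centred residuals
with n−1 effective samples). Small synchronisation errors are absorbed by a
per-signal phase nuisance with a tight N(0, (3°)²) prior. Probe
magnetization, volume and field-gradient amplitude are never modelled
separately: they are deliberately fused into `f_v`, because only the product
is identifiable and only `f_v` matters downstream; spatial variation of the
field gradient within a FOV is below half a percent and is not modelled.

The *conventional* pipeline this is compared against inverts each probe's
fitted amplitude at the nominal batch radius, `f_v,i = 9 η ω A_i / (2 r²)`.
Its probe-to-probe coefficient of variation is then dominated by the
unmodelled probe-size dispersion (2·r_σ/r_µ ≈ 12%), while the joint
posterior CV is set by the radius measurement error and pooling
(≈ 2τ/(r√n) ≈ 0.5% at n = 40) — an order-of-magnitude precision gain that
`studies.calibration_precision_study` reproduces. A variant using per-probe
measured radii (CV ≈ 2τ/r ≈ 3%) is reported alongside.

## Spatial model

Each signal sample enters a Student-t likelihood (robust to tracker pixel
switching):

    d_i(t) ~ StudentT(ν, 2 f_v r*_i²/(9 g(x_i)) · sin(2πft − h(x_i)), σ_i).

The fields are link-constrained Gaussian processes over each FOV:
`g = softplus(GP + µ_|G*|)` keeps stiffness positive,
`h = arcsin(sigmoid(GP + µ_φ))` keeps phase in (0, π/2). Kernels are
exponentiated-quadratic with per-dimension length scales plus white noise
σ_σ (which also makes duplicate probe locations well-posed). The hierarchy:

* kernel amplitudes, noncentered: `α_j = softplus(α_µ[c] + α_σ[c]·z_j)` with
  condition-level `α_µ` ~ Student-t(3, 0, 20) (stiffness) / N(0, 5) (phase)
  and `α_σ` ~ Half-N(0, 5) / Half-N(0, 1). `α_µ` is the condition's mean
  heterogeneity; `α_σ` the FOV-to-FOV variability of heterogeneity.
* length scales `l ~ GIG(p=2, a=15, b=l_σ)`, `l_σ ~ Half-N(0, 1)`, with
  coordinates rescaled to units of 100 µm before the prior (the GIG then
  concentrates on FOV-sized smoothness; a raw-µm mode is a config change).
  Whether the GIG scale refers to µm or rescaled coordinates was ambiguous;
  the rescaled reading gives physically sensible smoothness and is the
  default.
* FOV mean levels, noncentered around condition means: `µ_j = M[c] + s·z_j`,
  `M` ~ N(50, 15) (pre-softplus Pa scale, so softplus(M) ≈ M at 50 Pa —
  the prior is applied on the link scale by design) and N(0, 0.3) (logit
  scale, favouring elastic-solid phases), `s ~ Half-N(0, 1)`.
* per-probe noise, noncentered: `log σ_i = µ_σ + s_σ·z_i`,
  `µ_σ ~ N(ln 5 nm, 1)`, `s_σ ~ Half-N(0, 1)` (partial pooling).
* probe radii: the same measurement-error model as in calibration.
* `ν ~ InvGamma(3, 10)` (mass on ≈2–15, heavy-tail capable); the exact
  hyperprior was an open choice.
* `f_v`: either fixed, or a parameter with the calibration posterior's
  N(mean, sd) as prior. A strict "cut" (calibration not updated by gel
  data) is not expressible inside one joint sampler; the prior mode is the
  default and the update by gel data is in practice negligible because the
  prior is far tighter than the gel-data information. The fixed mode is the
  exact cut with a point mass.

Latent fields are whitened (`f = chol(K)·u`, `u ~ N(0, I)`) — the
noncentered parameterization throughout is what makes the posterior
geometry tractable for a gradient-free sampler.

A numerical floor of 1e−6 Pa on `g` keeps amplitudes finite for extreme
prior draws; covariance Cholesky factors get relative jitter (≤ 1e−6·α²),
and a walker whose covariance still fails factorisation receives −∞ density.

## Sampling

No gradient-based probabilistic-programming backend is available in this
stack, so both posteriors are sampled with an affine-invariant /
differential-evolution ensemble (emcee) over hand-written vectorised log
densities (a (walkers × dim) batch per call):

1. a data-driven start (baseline fits, measured radii) is refined to the MAP
   by L-BFGS with batched finite-difference gradients;
2. walkers are initialised from a self-checking Gaussian at the MAP: the full
   Laplace covariance if test draws from it stay within the log-density
   budget expected of a Gaussian (≈ dim/2), else a diagonal-Hessian
   covariance, shrunk until plausible — only the starting cloud depends on
   this, the sampler determines the posterior;
3. warmup combines a tempering ramp (β = 0.3 → 1 over the first half, only
   when the warmup budget affords re-equilibration) with block-wise
   adaptation of the differential-evolution step scale towards a ~25%
   acceptance rate; both are frozen before any draw is retained.
   Cached log-probabilities are never carried across β changes;
4. for the spatial model, a model-aware Metropolis "ridge move" is
   interleaved with the ensemble moves: the signal amplitude pins only
   r*²/g, so the posterior has a soft curved valley where a probe's radius
   and stiffness inflate together. The move proposes a radius shift with the
   exactly compensating stiffness rescaling (re-whitening the latent field
   through the current Cholesky factors) and accepts with the Metropolis
   ratio including the Jacobian of the companion map; it leaves the
   posterior invariant and is what makes the credible intervals for g and
   r* calibrated at these run lengths;
5. retained ensemble steps are regrouped into 4 pseudo-chains for split
   R-hat and bulk/tail ESS (arviz). R-hat > 1.05 flags the result as
   non-converged — it is returned flagged, never silently, and the pipeline
   maps the flag to a nonzero exit status. emcee's ensemble moves produce no
   divergences; the acceptance fraction is reported instead.

Full-fidelity settings are 4 chains × 1000–2000 draws with 2000+ adaptation
steps; the test suite and the validation studies use reduced settings
(4 × 300–500 draws, warmup 500–6000 chosen per study) so each fit takes
seconds to a minute on one CPU. emcee is explicitly seeded, so every fit is
a pure function of (data, seed).

## Posterior products

Field maps condition each draw's *latent* (pre-link) field on that draw's
latent probe values, sample the conditional at grid nodes (marginal
variances; the white-noise term is treated as observation-side, not part of
the smooth field), then apply the link — transform-then-average would bias
the means through the nonlinear links. The default grid is 50×50 over the
probe bounding box padded by the posterior-median length scale. Cross
sections report pointwise means and 2.5/97.5 percentiles (NumPy's default
type-7 empirical percentiles, for bit-reproducibility). Population means
are draw-wise link transforms of the condition-level mean parameters,
deliberately excluding heterogeneity (α) and FOV variability. Contrasts are
paired draw differences of `α_µ` (heterogeneity) or `α_σ` (FOV variability)
on the link scale, summarised by mean, 95% interval and the fraction of
positive draws; a 95% exceedance probability is the conventional cutoff for
claiming a difference.

## Synthetic data

`vemap.synthdata` generates what the models assume: uniformly scattered
probes (a fixed-count binomial process standing in for homogeneous Poisson,
since probe counts are fixed by experimental design), latent GP fields
through the same links, displacement signals with Student-t noise in the
tens-of-nm amplitude range, up to three replicate signals per probe sharing
its noise level, probe radii from N(6.14, 0.36²) µm (the batch estimate;
the nominal 5.24 µm value is attributable to batch handling and is
configurable) with 0.1 µm measurement error, and oil-calibration signals
with offset, linear drift and Gaussian noise. Recording duration is not
fixed by the protocol; the default is 3 cycles at 0.05 Hz with 25 ms frames
(2400 frames), subsampled tenfold downstream.

What it does **not** emulate: video, tracking artifacts beyond heavy-tailed
noise, fibre architecture, cell-generated active forces, probe-probe
magnetic interactions, or optical aberrations. Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions — simulation-based calibration in the strict sense — not
robustness to real-data pathologies outside the model class.

## Validation studies and problem sizes

`vemap.studies` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`):

* **Calibration precision** — n = 40 oil probes, 4×500 draws: joint-model CV
  vs the nominal-radius per-probe CV; the ratio's expected value is ~0.05.
* **Instrument arithmetic** — closed-form identities (0.3 nN force
  amplitude, 0.325 µm pixel, 0.8 µm Abbe limit, 0.25 µm radius error,
  11.6% raw CV).
* **Gradient detection** — one FOV, 7 probes straddling a twofold stiffness
  step (50→100 Pa): monotone interface transect (y-averaged, compared
  within Monte-Carlo error of the profile nodes), centre-line 95% band
  containing the true step outside the unprobed interface zone, and the
  posterior region-ratio interval bracketing 2.
* **Simulation-based calibration** — 7 replicates of 2 FOVs × 3 probes drawn
  from the joint prior and refitted (4×500 draws, warmup 4000); the 95%
  intervals for g(x_i) are scored against the simulated truth (42
  intervals). The scale (3 probes/FOV rather than 7) keeps the
  per-replicate fit accurate at these sampler settings; at larger dimension
  the ensemble sampler's residual approximation error shows up directly as
  a few points of undercoverage.
* **Noiseless equivalence** — near-noiseless signals, radii fixed: posterior
  means vs the least-squares inversion (sub-0.1% agreement typical).
* **Point-pattern homogeneity** — the layout generator against the Poisson
  G-curve with a *global* (sup-norm) Monte-Carlo envelope at the 99% level;
  a global test avoids the multiplicity of pointwise envelopes.

## Known limitations

* The ensemble sampler is the main approximation: at ~50–90 parameters its
  posteriors carry a few percent residual error in interval endpoints that a
  gradient-based sampler would not; R-hat and the SBC study quantify this.
* A single `f_v` per instrument (no spatially varying field-gradient model).
* Stationary kernels only; no fibre-informed regularisation.
* Day-to-day dynamics are analysed by fitting days separately; no temporal
  model.
* The radius measurement error τ = 0.1 µm is treated as given even though it
  sits below the camera's 0.325 µm pixel size; the inconsistency is
  inherited from the protocol and preserved deliberately.
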