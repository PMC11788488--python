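# vemap — Bayesian spatial mapping of viscoelasticity from magnetic microrheometry

Magnetic microrheometry measures the mechanics of extracellular-matrix (ECM)
mimics — collagen gels, 3D cancer-cell cultures — from the inside, by driving
~10 µm magnetic probes with an oscillating magnetic field gradient and
tracking their nanometre-scale displacements under a microscope. Each probe
reports the local absolute complex shear modulus |G*| (stiffness, Pa) and
phase angle φ (0 = elastic solid, π/2 = viscous fluid) through the
displacement relation

    d_i(t) = (2 f_v r_i² / (9 |G*|(x_i))) · sin(2π f t − φ(x_i)),

where `f_v` is the volumetric force calibration constant (N/m³, magnetic
force per probe volume) and `r_i` the probe radius. Probes are sparse — about
seven per microscopy field of view (FOV) — so point estimates leave most of
the field unconstrained and ignore the dominant error sources (probe-radius
uncertainty, heavy-tailed tracking noise, calibration uncertainty).

`vemap` re-implements this measurement chain as a hierarchical Bayesian
model, working directly from the raw sinusoidal signals:

* **Calibration** (`vemap.calibration`) — joint inference of `f_v` from
  viscous-silicone-oil probe signals via Stokes drag,
  `x(t) = −(2 r² f_v)/(9 η ω)·cos(ωt) + C`, with a radius measurement-error
  model (`r_i ~ N(r*_i, τ²)`, τ = 0.1 µm) shared across probes.
* **Spatial model** (`vemap.spatial`) — Student-t likelihood on every signal
  sample; latent Gaussian-process fields for stiffness (softplus link) and
  phase (arcsin∘sigmoid link) with exponentiated-quadratic kernels;
  hierarchical kernel amplitudes across FOVs within a condition (the
  "heterogeneity" parameters α_µ, α_σ), generalized-inverse-Gaussian
  length-scale priors, partially pooled per-probe noise, and propagated
  calibration uncertainty.
* **Posterior products** (`vemap.posterior`) — gridded field maps with
  uncertainty, gradient cross-sections with 95% credible bands,
  population-level means, and condition contrasts with exceedance
  probabilities (e.g. P(α_µ,CAF > α_µ,control)).
* **Synthetic data** (`vemap.synthdata`) — layouts, latent fields and signals
  with the exact statistical structure the models assume, so every stage is
  testable without instrument data.
* **Diagnostics** (`vemap.pointpattern`) — Ripley's-G nearest-neighbour check
  of probe layouts against a homogeneous point process.

Sampling uses an adaptive differential-evolution ensemble (emcee) with
MAP-initialised walkers and tempered warmup; diagnostics (split R-hat,
effective sample size) come from arviz.

## Worked example

```python
import numpy as np
from vemap import (AcquisitionConfig, MCMCSettings, build_spatial_model,
                   fit_spatial, predict_field, synchronize_and_subsample)
from vemap import synthdata as sd

# simulate one field of view: 7 magnetic probes in a smooth stiffness field
fov, truth = sd.make_fov_dataset("demo", n_magnetic=7, n_reference=30, seed=1)
fov.signals = [synchronize_and_subsample(s, factor=10) for s in fov.signals]

model = build_spatial_model([fov], fv_source=280_000.0)
post = fit_spatial(model, MCMCSettings(chains=4, draws=500, warmup=2000, seed=1))

g_mean = post.flat("g").mean(axis=0)
print("true |G*| (Pa):", np.round(truth.gstar, 1))
print("post |G*| (Pa):", np.round(g_mean, 1))
print("max R-hat:", round(post.diagnostics["max_rhat"], 3))

fmap = predict_field(post, "demo", kind="stiffness")   # 50x50 posterior map
print("map mean range (Pa):", round(fmap.mean.min(), 1), "-", round(fmap.mean.max(), 1))
```

Output from this exact script:

```
true |G*| (Pa): [50.  54.4 55.4 57.4 54.5 51.4 46.8]
post |G*| (Pa): [48.4 55.3 56.1 58.9 54.4 51.9 46.2]
max R-hat: 1.063
map mean range (Pa): 46.5 - 58.6
```

The posterior per-probe stiffness tracks the simulated truth to within a few
percent, and the field map interpolates between probes with uncertainty that
grows away from them.

A command-line interface wraps the same library:

```bash
vemap simulate --config cfg.yaml --seed 1 --out data/
vemap calibrate --signals data/oil_signals.csv --probes data/oil_probes.csv --out cal.zarr
vemap fit --probes data/probes.csv --signals data/signals.csv --calibration cal.zarr --out spatial.zarr
vemap map --posterior spatial.zarr --fov control_fov0 --out map.csv --png map.png
vemap contrast --posterior spatial.zarr --condition-a caf --condition-b control
vemap gcheck --probes data/probes.csv --out gcurve.csv
```

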