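"""Synthetic magnetic-microrheometry datasets.

Everything the downstream models assume about real acquisitions is emulated
here: sparse magnetic probes and denser passive reference probes scattered
uniformly over a hundreds-of-micrometre field of view, smooth latent
stiffness/phase fields drawn from link-constrained Gaussian processes,
sinusoidal displacement responses in the tens-of-nanometre range with
heavy-tailed tracking noise, probe-radius measurement error, and viscous-oil
calibration signals with offsets and slow drift.

Default parameter values are the study conditions: 0.05 Hz drive, 25 ms
frames, ~7 magnetic probes per field of view, probe radii around 6.14 um with
0.36 um batch spread and 0.1 um measurement error, a volumetric force
constant near 2.8e5 N/m^3 and stiffness priors centred at 50 Pa.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    MAGNETIC,
    REFERENCE,
    AcquisitionConfig,
    DisplacementSignal,
    FOVDataset,
    Probe,
    TrueFieldSample,
)
from .links import chol_with_jitter, exp_quad_cov, phase_link, stiffness_link
from .units import calibration_amplitude_nm, displacement_amplitude_nm

# Probe-radius population: posterior batch estimate (mean, sd) in micrometres
# and the single-probe measurement error tau.
RADIUS_MEAN_UM = 6.14
RADIUS_SD_UM = 0.36
RADIUS_TAU_UM = 0.1
# Default volumetric force constant, N/m^3 (calibration prior centre).
DEFAULT_FV = 280_000.0
# Silicone oil dynamic viscosity: 30,000 cSt at 0.975 g/mL.
DEFAULT_OIL_VISCOSITY = 29.2  # Pa s


def sample_probe_layout(
    n_magnetic: int,
    n_reference: int,
    fov_extent=(600.0, 600.0),
    seed: int | np.random.Generator = 0,
    radius_mean: float = RADIUS_MEAN_UM,
    radius_sd: float = RADIUS_SD_UM,
    radius_tau: float = RADIUS_TAU_UM,
    id_prefix: str = "",
) -> list[Probe]:
    """Place probes uniformly and independently in the field of view.

    A binomial (fixed-count uniform) point process stands in for the
    homogeneous Poisson process: probe counts are fixed by the experimental
    design.  Magnetic probes receive true radii ~ Normal(radius_mean,
    radius_sd^2) truncated above 1 um and measured radii = true +
    Normal(0, radius_tau^2).
    """
    if n_magnetic < 0 or n_reference < 0:
        raise ValueError("probe counts must be non-negative")
    extent = np.asarray(fov_extent, dtype=float)
    if extent.shape != (2,) or np.any(extent <= 0):
        raise ValueError("fov_extent must be a positive 2-vector")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    probes: list[Probe] = []
    for i in range(n_magnetic):
        loc = rng.uniform(0.0, extent, size=2)
        true_r = rng.normal(radius_mean, radius_sd)
        while true_r <= 1.0:  # truncation; essentially never triggers at defaults
            true_r = rng.normal(radius_mean, radius_sd)
        measured_r = true_r + rng.normal(0.0, radius_tau)
        probes.append(
            Probe(
                id=f"{id_prefix}m{i}",
                kind=MAGNETIC,
                location=loc,
                measured_radius=float(measured_r),
                true_radius=float(true_r),
            )
        )
    for i in range(n_reference):
        loc = rng.uniform(0.0, extent, size=2)
        probes.append(Probe(id=f"{id_prefix}r{i}", kind=REFERENCE, location=loc))
    return probes


def sample_true_fields(
    locations,
    kernel_g: Optional[dict] = None,
    kernel_h: Optional[dict] = None,
    mean_gstar_link: float = 50.0,
    mean_phi_link: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> TrueFieldSample:
    """Draw ground-truth stiffness and phase fields at the given locations.

    Latent values come from zero-mean GPs with exponentiated-quadratic
    covariance; the stated means are added on the link scale and the links
    applied (softplus for stiffness, arcsin(sigmoid) for phase), so the
    outputs satisfy the physical range constraints by construction.

    ``kernel_g``/``kernel_h`` are dicts with keys ``amplitude``,
    ``length_scales`` (um) and optional ``white_noise_sd``.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    if locations.shape[0] < 1:
        raise ValueError("need at least one location")
    kernel_g = dict(kernel_g or {"amplitude": 10.0, "length_scales": (150.0, 150.0)})
    kernel_h = dict(kernel_h or {"amplitude": 0.3, "length_scales": (150.0, 150.0)})
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def draw(kernel):
        amp = float(kernel["amplitude"])
        if amp == 0.0:
            return np.zeros(locations.shape[0])
        k = exp_quad_cov(
            locations,
            amp,
            kernel["length_scales"],
            kernel.get("white_noise_sd", 0.0),
        )
        chol = chol_with_jitter(k)
        return chol @ rng.standard_normal(locations.shape[0])

    latent_g = draw(kernel_g)
    latent_h = draw(kernel_h)
    return TrueFieldSample(
        locations=locations,
        gstar=stiffness_link(latent_g, mean_gstar_link),
        phi=phase_link(latent_h, mean_phi_link),
        latent_g=latent_g,
        latent_h=latent_h,
        kernel_g=kernel_g,
        kernel_h=kernel_h,
        mean_gstar_link=mean_gstar_link,
        mean_phi_link=mean_phi_link,
    )


def synthesize_displacements(
    fields: TrueFieldSample,
    probes: Sequence[Probe],
    fv: float = DEFAULT_FV,
    acq: Optional[AcquisitionConfig] = None,
    noise_sd: float | Sequence[float] = 5.0,
    noise_df: float = 5.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[DisplacementSignal]:
    """Generate sinusoidal displacement signals for the magnetic probes.

    Each signal is A sin(2 pi f t - phi) plus Student-t(noise_df) noise scaled
    by ``noise_sd`` (nm), with A = 2 fv r^2 / (9 |G*|) evaluated at the
    probe's *true* radius.  Up to ``n_replicates`` replicate signals are
    emitted per magnetic probe — one per matched reference probe, all sharing
    the probe's noise level — mirroring the subtraction against the closest
    reference probes.
    """
    if fv <= 0:
        raise ValueError("fv must be positive")
    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    magnetic = [p for p in probes if p.is_magnetic]
    references = [p for p in probes if not p.is_magnetic]
    if np.any(fields.gstar <= 0):
        raise ValueError("gstar must be positive")

    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(magnetic),))
    t = acq.times()
    signals: list[DisplacementSignal] = []
    for i, probe in enumerate(magnetic):
        r = probe.true_radius if probe.true_radius is not None else probe.measured_radius
        if r is None:
            raise ValueError(f"magnetic probe {probe.id!r} has no radius")
        # field values at the probe's own location index
        idx = _location_index(fields.locations, probe.location)
        amp = float(displacement_amplitude_nm(fv, r, fields.gstar[idx]))
        phi = float(fields.phi[idx])
        clean = amp * np.sin(2.0 * np.pi * acq.drive_frequency * t - phi)
        if references:
            order = np.argsort([np.linalg.norm(q.location - probe.location) for q in references])
            matched = [references[k] for k in order[:n_replicates]]
        else:
            matched = [None]
        for ref in matched:
            noisy = clean
            if noise_sd[i] > 0:
                noisy = clean + noise_sd[i] * rng.standard_t(noise_df, size=t.size)
            signals.append(
                DisplacementSignal(
                    magnetic_probe_id=probe.id,
                    reference_probe_id=ref.id if ref is not None else "raw",
                    times=t,
                    displacements=noisy,
                    drive_frequency=acq.drive_frequency,
                )
            )
    return signals


def _location_index(locations: np.ndarray, loc: np.ndarray) -> int:
    d = np.linalg.norm(locations - loc[None, :], axis=1)
    idx = int(np.argmin(d))
    if d[idx] > 1e-6:
        raise ValueError("probe location missing from the field sample")
    return idx


def synthesize_calibration_signals(
    probes: Sequence[Probe],
    fv: float = DEFAULT_FV,
    viscosity: float = DEFAULT_OIL_VISCOSITY,
    acq: Optional[AcquisitionConfig] = None,
    drift_nm_per_s: float = 0.0,
    offset_sd_nm: float = 50.0,
    noise_sd_nm: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> list[DisplacementSignal]:
    """Viscous-oil calibration signals from the Stokes-drag solution.

    x(t) = -(2 r^2 fv)/(9 eta omega) cos(omega t) + C + drift * t + noise,
    one signal per magnetic probe, evaluated at the probe's true radius with
    Gaussian tracking noise (tracking in oil is benign, so no heavy tails).
    """
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    if fv <= 0:
        raise ValueError("fv must be positive")
    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = acq.times()
    omega = 2.0 * np.pi * acq.drive_frequency
    signals = []
    for probe in probes:
        if not probe.is_magnetic:
            continue
        r = probe.true_radius if probe.true_radius is not None else probe.measured_radius
        amp = float(calibration_amplitude_nm(fv, r, viscosity, acq.drive_frequency))
        offset = rng.normal(0.0, offset_sd_nm) if offset_sd_nm > 0 else 0.0
        x = -amp * np.cos(omega * t) + offset + drift_nm_per_s * t
        if noise_sd_nm > 0:
            x = x + rng.normal(0.0, noise_sd_nm, size=t.size)
        signals.append(
            DisplacementSignal(
                magnetic_probe_id=probe.id,
                reference_probe_id="raw",
                times=t,
                displacements=x,
                drive_frequency=acq.drive_frequency,
            )
        )
    return signals


def make_fov_dataset(
    fov_id: str,
    condition: str = "control",
    day: int = 1,
    n_magnetic: int = 7,
    n_reference: int = 30,
    fv: float = DEFAULT_FV,
    acq: Optional[AcquisitionConfig] = None,
    kernel_g: Optional[dict] = None,
    kernel_h: Optional[dict] = None,
    mean_gstar_link: float = 50.0,
    mean_phi_link: float = 0.0,
    noise_sd: float | Sequence[float] = 5.0,
    noise_df: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[FOVDataset, TrueFieldSample]:
    """Convenience: layout + fields + signals for one field of view.

    Returns the dataset together with its ground truth so tests can score
    recovery.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    acq = acq or AcquisitionConfig()
    probes = sample_probe_layout(
        n_magnetic, n_reference, acq.fov_extent, seed=rng, id_prefix=f"{fov_id}_"
    )
    mag_locs = np.array([p.location for p in probes if p.is_magnetic])
    fields = sample_true_fields(
        mag_locs,
        kernel_g=kernel_g,
        kernel_h=kernel_h,
        mean_gstar_link=mean_gstar_link,
        mean_phi_link=mean_phi_link,
        seed=rng,
    )
    signals = synthesize_displacements(
        fields, probes, fv=fv, acq=acq, noise_sd=noise_sd, noise_df=noise_df, seed=rng
    )
    dataset = FOVDataset(
        fov_id=fov_id, condition=condition, day=day, probes=probes, signals=signals
    )
    return dataset, fields
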