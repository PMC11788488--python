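"""Displacement-signal preprocessing and the deterministic baseline pipeline.

The conventional analysis path: match each magnetic probe to nearby reference
probes, subtract the common-mode reference track, align to the force timeline,
subsample, fit a single sinusoid by linear least squares, and invert the
displacement-modulus relation probe by probe.  This path deliberately ignores
the uncertainties the Bayesian models propagate; it serves both as the
preprocessing front end and as the comparison baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import DisplacementSignal, Probe
from .units import fv_from_calibration_amplitude, gstar_from_amplitude_pa

logger = logging.getLogger(__name__)


@dataclass
class PointEstimate:
    """Per-probe result of the deterministic baseline fit."""

    probe_id: str
    amplitude: float  # nm
    phase: float  # rad, as fitted
    gstar: float  # Pa
    phi: float  # rad, wrapped into [0, pi/2]
    residual_rms: float  # nm
    flag: str = "ok"  # "ok" | "phase-out-of-range"


def match_references(
    magnetic: Probe,
    references: Sequence[Probe],
    min_dist: float = 50.0,
    max_dist: float = 200.0,
    k: int = 3,
) -> list[Probe]:
    """Up to ``k`` nearest reference probes within the distance window (um).

    The window excludes references so close that they ride the magnetic
    probe's own strain field and ones so far that stage vibration is no
    longer common mode.  An empty result is valid and logged.
    """
    if not min_dist < max_dist:
        raise ValueError("min_dist must be smaller than max_dist")
    if k < 1:
        raise ValueError("k must be at least 1")
    dists = [
        (float(np.linalg.norm(ref.location - magnetic.location)), ref)
        for ref in references
        if not ref.is_magnetic
    ]
    eligible = sorted((d, ref.id, ref) for d, ref in dists if min_dist <= d <= max_dist)
    if not eligible:
        logger.info("no reference probe within [%g, %g] um of %s", min_dist, max_dist, magnetic.id)
    return [ref for _, _, ref in eligible[:k]]


def subtract_reference(
    raw_magnetic: DisplacementSignal, raw_reference: DisplacementSignal
) -> DisplacementSignal:
    """Element-wise subtraction of the reference track from the magnetic one."""
    if raw_magnetic.times.shape != raw_reference.times.shape or not np.allclose(
        raw_magnetic.times, raw_reference.times
    ):
        raise ValueError("signals must share an identical time grid")
    return DisplacementSignal(
        magnetic_probe_id=raw_magnetic.magnetic_probe_id,
        reference_probe_id=raw_reference.magnetic_probe_id,
        times=raw_magnetic.times.copy(),
        displacements=raw_magnetic.displacements - raw_reference.displacements,
        drive_frequency=raw_magnetic.drive_frequency,
    )


def synchronize_and_subsample(
    signal: DisplacementSignal,
    force_timeline: Optional[np.ndarray] = None,
    factor: int = 10,
) -> DisplacementSignal:
    """Align the signal to the force timeline and keep every ``factor``-th sample.

    The camera and force-drive clocks share a phase origin, so alignment is a
    constant shift of the time axis onto the force timeline's origin; the
    subsampling then thins the (heavily oversampled) 25 ms frames for
    computational economy.
    """
    if factor < 1:
        raise ValueError("subsampling factor must be >= 1")
    times = signal.times
    if force_timeline is not None:
        force_timeline = np.asarray(force_timeline, dtype=float)
        times = times - times[0] + force_timeline[0]
    sl = slice(None, None, int(factor))
    return DisplacementSignal(
        magnetic_probe_id=signal.magnetic_probe_id,
        reference_probe_id=signal.reference_probe_id,
        times=times[sl].copy(),
        displacements=signal.displacements[sl].copy(),
        drive_frequency=signal.drive_frequency,
    )


def _harmonic_lsq(times, displacements, f, extra_trend=False):
    """Least squares on {sin, cos, 1[, t]}; returns coefficients and residual rms."""
    w = 2.0 * np.pi * f
    cols = [np.sin(w * times), np.cos(w * times), np.ones_like(times)]
    if extra_trend:
        cols.append(times - times.mean())
    basis = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(basis, displacements, rcond=None)
    resid = displacements - basis @ coef
    return coef, float(np.sqrt(np.mean(resid**2)))


def fit_sinusoid_baseline(
    signal: DisplacementSignal,
    f: Optional[float] = None,
    fv: float = 280_000.0,
    r: float = 6.14,
) -> PointEstimate:
    """Least-squares sinusoid fit and pointwise inversion to (|G*|, phi).

    The harmonic coefficients (a, b) of d = a sin(wt) + b cos(wt) + c map to
    the convention d = A sin(2 pi f t - phi) via A = hypot(a, b) and
    phi = atan2(-b, a).  Stiffness follows from |G*| = 2 fv r^2 / (9 A) with
    ``r`` the probe's measured radius in micrometres.  Phases outside
    [0, pi/2] are flagged, not clamped.
    """
    f = f if f is not None else signal.drive_frequency
    if len(signal) < 8 or signal.times[-1] - signal.times[0] < 1.0 / f:
        raise ValueError("need at least 8 samples spanning one full cycle")
    coef, rms = _harmonic_lsq(signal.times, signal.displacements, f)
    a, b = coef[0], coef[1]
    amplitude = float(np.hypot(a, b))
    if amplitude <= np.finfo(float).eps:
        raise ValueError("degenerate signal: amplitude ~ 0, stiffness undefined")
    phase = float(np.arctan2(-b, a))
    gstar = float(gstar_from_amplitude_pa(fv, r, amplitude))
    if 0.0 <= phase <= np.pi / 2:
        phi, flag = phase, "ok"
    else:
        phi, flag = float(np.clip(phase, 0.0, np.pi / 2)), "phase-out-of-range"
    return PointEstimate(
        probe_id=signal.magnetic_probe_id,
        amplitude=amplitude,
        phase=phase,
        gstar=gstar,
        phi=phi,
        residual_rms=rms,
        flag=flag,
    )


def pointwise_fv(
    signal: DisplacementSignal,
    r: float,
    eta: float,
    f: Optional[float] = None,
) -> float:
    """Per-probe volumetric force constant from one oil-calibration signal.

    A linear drift term is removed jointly with the harmonic fit; the fitted
    quadrature amplitude A gives fv = 9 eta omega A / (2 r^2).
    """
    f = f if f is not None else signal.drive_frequency
    if len(signal) < 8 or signal.times[-1] - signal.times[0] < 1.0 / f:
        raise ValueError("need at least 8 samples spanning one full cycle")
    coef, _ = _harmonic_lsq(signal.times, signal.displacements, f, extra_trend=True)
    amplitude = float(np.hypot(coef[0], coef[1]))
    if amplitude <= np.finfo(float).eps:
        raise ValueError("degenerate signal: amplitude ~ 0")
    return float(fv_from_calibration_amplitude(amplitude, r, eta, f))


def baseline_estimates(
    signals: Sequence[DisplacementSignal],
    probes: Sequence[Probe],
    fv: float,
    f: Optional[float] = None,
    aggregate: str = "median",
) -> list[PointEstimate]:
    """Baseline fit per replicate signal, aggregated per probe by the median.

    The median across a probe's replicate (per-reference) fits is robust to a
    single bad reference track, matching how raw-data summaries are reported.
    """
    if aggregate not in ("median", "none"):
        raise ValueError("aggregate must be 'median' or 'none'")
    radius = {p.id: p.measured_radius for p in probes if p.is_magnetic}
    per_probe: dict[str, list[PointEstimate]] = {}
    for s in signals:
        if s.magnetic_probe_id not in radius:
            raise ValueError(f"signal for unknown magnetic probe {s.magnetic_probe_id!r}")
        est = fit_sinusoid_baseline(s, f=f, fv=fv, r=radius[s.magnetic_probe_id])
        per_probe.setdefault(s.magnetic_probe_id, []).append(est)
    if aggregate == "none":
        return [e for ests in per_probe.values() for e in ests]
    out = []
    for pid, ests in per_probe.items():
        flags = {e.flag for e in ests}
        out.append(
            PointEstimate(
                probe_id=pid,
                amplitude=float(np.median([e.amplitude for e in ests])),
                phase=float(np.median([e.phase for e in ests])),
                gstar=float(np.median([e.gstar for e in ests])),
                phi=float(np.median([e.phi for e in ests])),
                residual_rms=float(np.median([e.residual_rms for e in ests])),
                flag="ok" if flags == {"ok"} else "phase-out-of-range",
            )
        )
    return out
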