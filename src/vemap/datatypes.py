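"""Domain containers for probes, signals and fields of view.

These are light dataclasses: one :class:`Probe` per physical bead, one
:class:`DisplacementSignal` per noise-corrected (magnetic, reference) signal
pair, and one :class:`FOVDataset` per microscopy field of view.  Validation
happens at construction so downstream code can assume the invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MAGNETIC = "magnetic"
REFERENCE = "reference"


@dataclass
class Probe:
    """One spherical probe.

    Magnetic probes are actuated by the electromagnets and carry a measured
    radius (micrometres); reference probes are passive and only provide a
    common-mode displacement track.
    """

    id: str
    kind: str  # "magnetic" | "reference"
    location: np.ndarray  # (2,) micrometres
    measured_radius: Optional[float] = None  # micrometres, magnetic only
    true_radius: Optional[float] = None  # synthetic ground truth only

    def __post_init__(self):
        if self.kind not in (MAGNETIC, REFERENCE):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        self.location = np.asarray(self.location, dtype=float).reshape(2)
        if self.kind == MAGNETIC:
            if self.measured_radius is None or not self.measured_radius > 0:
                raise ValueError(
                    f"magnetic probe {self.id!r} requires a positive measured radius"
                )

    @property
    def is_magnetic(self) -> bool:
        return self.kind == MAGNETIC


@dataclass
class AcquisitionConfig:
    """Drive and camera settings for one acquisition.

    Defaults follow the instrument protocol: 0.05 Hz drive, 25 ms frames,
    three recorded cycles, a 600x600 um field of view, and a shared phase
    origin between the force drive and the camera clock.
    """

    drive_frequency: float = 0.05  # Hz
    phase_origin: float = 0.0  # rad
    frame_interval: float = 0.025  # s
    n_cycles: int = 3
    fov_extent: tuple = (600.0, 600.0)  # micrometres

    def __post_init__(self):
        if self.drive_frequency <= 0:
            raise ValueError("drive_frequency must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frame_interval * self.drive_frequency > 1.0 / 40.0:
            raise ValueError("need at least 40 frames per drive cycle")
        if any(e <= 0 for e in self.fov_extent):
            raise ValueError("fov_extent must be positive")

    def times(self) -> np.ndarray:
        """Frame timestamps in seconds for the configured duration."""
        n = int(round(self.n_cycles / self.drive_frequency / self.frame_interval))
        return np.arange(n) * self.frame_interval


@dataclass
class TrueFieldSample:
    """Ground-truth realisation of the latent viscoelastic fields."""

    locations: np.ndarray  # (n, 2) micrometres
    gstar: np.ndarray  # Pa
    phi: np.ndarray  # rad, in [0, pi/2]
    latent_g: np.ndarray  # pre-link latent (without mean)
    latent_h: np.ndarray
    kernel_g: dict = field(default_factory=dict)
    kernel_h: dict = field(default_factory=dict)
    mean_gstar_link: float = 0.0  # pre-softplus mean
    mean_phi_link: float = 0.0  # logit-scale mean

    def __post_init__(self):
        self.locations = np.atleast_2d(np.asarray(self.locations, dtype=float))
        self.gstar = np.asarray(self.gstar, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.gstar <= 0):
            raise ValueError("stiffness must be positive everywhere")
        if np.any((self.phi < 0) | (self.phi > np.pi / 2)):
            raise ValueError("phase must lie in [0, pi/2]")


@dataclass
class DisplacementSignal:
    """One noise-corrected displacement time series for a probe pair."""

    magnetic_probe_id: str
    reference_probe_id: str  # or "raw" for an uncorrected track
    times: np.ndarray  # s, strictly increasing, uniform
    displacements: np.ndarray  # nm
    drive_frequency: float  # Hz

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.times.shape != self.displacements.shape:
            raise ValueError("times and displacements must have equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacements must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FOVDataset:
    """All probes and signals of one microscopy field of view."""

    fov_id: str
    condition: str
    day: int
    probes: Sequence[Probe]
    signals: Sequence[DisplacementSignal]

    def __post_init__(self):
        ids = {p.id for p in self.probes}
        for s in self.signals:
            if s.magnetic_probe_id not in ids:
                raise ValueError(
                    f"signal references unknown probe {s.magnetic_probe_id!r}"
                )
            if s.reference_probe_id not in ids and s.reference_probe_id != "raw":
                raise ValueError(
                    f"signal references unknown reference {s.reference_probe_id!r}"
                )
        mags = self.magnetic_probes()
        if not mags:
            raise ValueError("a FOV requires at least one magnetic probe")
        with_signals = {s.magnetic_probe_id for s in self.signals}
        for p in mags:
            if p.id not in with_signals:
                raise ValueError(f"magnetic probe {p.id!r} has no signal")

    def magnetic_probes(self) -> list:
        return [p for p in self.probes if p.is_magnetic]

    def reference_probes(self) -> list:
        return [p for p in self.probes if not p.is_magnetic]

    def signals_for(self, probe_id: str) -> list:
        return [s for s in self.signals if s.magnetic_probe_id == probe_id]
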