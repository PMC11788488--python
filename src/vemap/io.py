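"""Readers and writers for the package's tabular and array artifacts.

Tables are UTF-8 comma-separated with a header row and unit-suffixed column
names (coordinates in um, displacements in nm, stiffness in Pa, phase in
rad).  Floats are written with 9 significant digits so identical inputs give
byte-identical files.  Posterior containers are zarr directory stores with
named dimensions and JSON-encoded config/diagnostics attributes.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from ._mcmc import MCMCSettings
from .calibration import CalibrationConfig, CalibrationPosterior
from .datatypes import AcquisitionConfig, DisplacementSignal, FOVDataset, Probe
from .spatial import PriorConfig, SpatialPosterior

FLOAT_FMT = "%.9g"


def _quiet_to_zarr(ds, path):
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="zarr")
        warnings.filterwarnings("ignore", category=UserWarning)
        ds.to_zarr(str(path), mode="w")

PROBE_COLUMNS = ["id", "kind", "x_um", "y_um", "measured_radius_um"]
SIGNAL_COLUMNS = ["magnetic_id", "reference_id", "time_s", "displacement_nm"]


class SchemaError(ValueError):
    """A table is missing a required column or holds an invalid value."""


# ---------------------------------------------------------------------------
# probe and signal tables
# ---------------------------------------------------------------------------

def write_probe_table(probes: Sequence[Probe], path, fov_id=None, condition=None, day=None):
    rows = []
    any_true = any(p.true_radius is not None for p in probes)
    for p in probes:
        row = {
            "id": p.id,
            "kind": p.kind,
            "x_um": p.location[0],
            "y_um": p.location[1],
            "measured_radius_um": "" if p.measured_radius is None else p.measured_radius,
        }
        if any_true:
            row["true_radius_um"] = "" if p.true_radius is None else p.true_radius
        if fov_id is not None:
            row["fov_id"] = fov_id
            row["condition"] = condition
            row["day"] = day
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_probe_table(path) -> list[Probe]:
    df = pd.read_csv(path)
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"probe table {path} is missing required column {col!r}")
    probes = []
    for i, row in df.iterrows():
        radius = row["measured_radius_um"]
        if pd.isna(radius) or radius == "":
            radius = None
        else:
            try:
                radius = float(radius)
            except (TypeError, ValueError):
                raise SchemaError(f"row {i}: malformed radius {radius!r}") from None
            if radius <= 0:
                raise SchemaError(f"row {i}: radius must be positive, got {radius}")
        true_r = row.get("true_radius_um")
        true_r = None if true_r is None or pd.isna(true_r) else float(true_r)
        try:
            probes.append(
                Probe(
                    id=str(row["id"]),
                    kind=str(row["kind"]),
                    location=np.array([row["x_um"], row["y_um"]], dtype=float),
                    measured_radius=radius,
                    true_radius=true_r,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from None
    return probes


def write_signal_table(signals: Sequence[DisplacementSignal], path):
    frames = []
    for s in signals:
        frames.append(
            pd.DataFrame(
                {
                    "magnetic_id": s.magnetic_probe_id,
                    "reference_id": s.reference_probe_id,
                    "time_s": s.times,
                    "displacement_nm": s.displacements,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_signal_table(path, drive_frequency: float = 0.05) -> list[DisplacementSignal]:
    df = pd.read_csv(path)
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"signal table {path} is missing required column {col!r}")
    signals = []
    for (mid, rid), grp in df.groupby(["magnetic_id", "reference_id"], sort=False):
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise SchemaError(f"signal ({mid}, {rid}): times are not strictly increasing")
        try:
            signals.append(
                DisplacementSignal(
                    magnetic_probe_id=str(mid),
                    reference_probe_id=str(rid),
                    times=times,
                    displacements=grp["displacement_nm"].to_numpy(dtype=float),
                    drive_frequency=drive_frequency,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"signal ({mid}, {rid}): {exc}") from None
    return signals


def write_truth_table(fields, probe_ids, path):
    """Ground-truth table (id, x_um, y_um, gstar_pa, phi_rad) for tests."""
    pd.DataFrame(
        {
            "id": probe_ids,
            "x_um": fields.locations[:, 0],
            "y_um": fields.locations[:, 1],
            "gstar_pa": fields.gstar,
            "phi_rad": fields.phi,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_estimates(estimates, path):
    pd.DataFrame(
        [
            {
                "probe_id": e.probe_id,
                "amplitude_nm": e.amplitude,
                "phase_rad": e.phase,
                "gstar_pa": e.gstar,
                "phi_rad": e.phi,
                "flag": e.flag,
            }
            for e in estimates
        ]
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_fov_datasets(fovs: Sequence[FOVDataset], probes_path, signals_path):
    probe_rows, signal_frames = [], []
    for fov in fovs:
        for p in fov.probes:
            probe_rows.append(
                {
                    "id": p.id,
                    "kind": p.kind,
                    "x_um": p.location[0],
                    "y_um": p.location[1],
                    "measured_radius_um": "" if p.measured_radius is None else p.measured_radius,
                    "true_radius_um": "" if p.true_radius is None else p.true_radius,
                    "fov_id": fov.fov_id,
                    "condition": fov.condition,
                    "day": fov.day,
                }
            )
        for s in fov.signals:
            signal_frames.append(
                pd.DataFrame(
                    {
                        "magnetic_id": s.magnetic_probe_id,
                        "reference_id": s.reference_probe_id,
                        "time_s": s.times,
                        "displacement_nm": s.displacements,
                    }
                )
            )
    pd.DataFrame(probe_rows).to_csv(probes_path, index=False, float_format=FLOAT_FMT)
    pd.concat(signal_frames, ignore_index=True).to_csv(
        signals_path, index=False, float_format=FLOAT_FMT
    )


def read_fov_datasets(probes_path, signals_path, drive_frequency: float = 0.05):
    """Load FOV datasets, grouping probes by the optional fov_id column."""
    df = pd.read_csv(probes_path)
    for col in PROBE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"probe table {probes_path} is missing required column {col!r}")
    if "fov_id" not in df.columns:
        df["fov_id"] = "fov0"
        df["condition"] = "default"
        df["day"] = 1
    signals = read_signal_table(signals_path, drive_frequency)
    by_probe: dict[str, list] = {}
    for s in signals:
        by_probe.setdefault(s.magnetic_probe_id, []).append(s)

    fovs = []
    for fov_id, grp in df.groupby("fov_id", sort=False):
        probes = []
        for i, row in grp.iterrows():
            radius = row["measured_radius_um"]
            radius = None if pd.isna(radius) else float(radius)
            true_r = row.get("true_radius_um")
            true_r = None if true_r is None or pd.isna(true_r) else float(true_r)
            probes.append(
                Probe(
                    id=str(row["id"]),
                    kind=str(row["kind"]),
                    location=np.array([row["x_um"], row["y_um"]], dtype=float),
                    measured_radius=radius,
                    true_radius=true_r,
                )
            )
        fov_signals = [s for p in probes if p.is_magnetic for s in by_probe.get(p.id, [])]
        fovs.append(
            FOVDataset(
                fov_id=str(fov_id),
                condition=str(grp["condition"].iloc[0]),
                day=int(grp["day"].iloc[0]),
                probes=probes,
                signals=fov_signals,
            )
        )
    return fovs


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class SynthConfig:
    """Synthetic-study design: conditions, fields of view, probe counts."""

    conditions: tuple = ("control",)
    n_fovs_per_condition: int = 2
    n_magnetic: int = 7
    n_reference: int = 30
    fv: float = 280_000.0
    mean_gstar_link: float = 50.0
    mean_phi_link: float = 0.0
    kernel_amplitude_g: float = 10.0
    kernel_amplitude_h: float = 0.3
    length_scale_um: float = 150.0
    noise_sd_nm: float = 5.0
    noise_df: float = 5.0
    n_oil_probes: int = 40
    oil_noise_sd_nm: float = 5.0
    oil_drift_nm_per_s: float = 0.0


@dataclass
class RunConfig:
    """Fully resolved configuration of one analysis run.

    Defaults mirror the measurement protocol: 0.05 Hz drive, 25 ms frames,
    10x subsampling, 50-200 um reference matching window, 4 chains, radius
    error 0.1 um and an fv prior of Normal(280000, 14000) N/m^3.
    """

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    synth: SynthConfig = field(default_factory=SynthConfig)
    match_min_dist: float = 50.0
    match_max_dist: float = 200.0
    match_k: int = 3
    subsample_factor: int = 10
    fixed_fv: Optional[float] = None
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        for name, sub_cls in (
            ("acquisition", AcquisitionConfig),
            ("calibration", CalibrationConfig),
            ("priors", PriorConfig),
            ("mcmc", MCMCSettings),
            ("synth", SynthConfig),
        ):
            sub = data.pop(name, {}) or {}
            known = {f.name for f in dataclasses.fields(sub_cls)}
            unknown = set(sub) - known
            if unknown:
                raise SchemaError(f"unknown {name} config keys: {sorted(unknown)}")
            for key in ("conditions", "fov_extent"):
                if key in sub and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            for key in list(sub):
                if key.endswith("_prior") and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            kwargs[name] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# posterior containers (zarr)
# ---------------------------------------------------------------------------

def save_calibration_posterior(post: CalibrationPosterior, path):
    ds = xr.Dataset(
        {
            "fv": (("chain", "draw"), post.fv),
            "r_mu": (("chain", "draw"), post.r_mu),
            "r_sigma": (("chain", "draw"), post.r_sigma),
            "noise_sd": (("chain", "draw"), post.noise_sd),
            "r_star": (("chain", "draw", "probe"), post.r_star),
        },
        coords={"probe": list(post.probe_ids)},
        attrs={
            "diagnostics": json.dumps(_plain(post.diagnostics)),
            "converged": int(post.converged),
            "warnings": json.dumps(list(post.warnings)),
            "config": json.dumps(_plain(dataclasses.asdict(post.config)))
            if post.config
            else "{}",
        },
    )
    _quiet_to_zarr(ds, path)


def load_calibration_posterior(path) -> CalibrationPosterior:
    ds = xr.open_zarr(str(path))
    cfg = json.loads(ds.attrs.get("config", "{}"))
    for key in ("r_mu_prior", "r_sigma_prior"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    return CalibrationPosterior(
        fv=ds["fv"].values,
        r_star=ds["r_star"].values,
        r_mu=ds["r_mu"].values,
        r_sigma=ds["r_sigma"].values,
        noise_sd=ds["noise_sd"].values,
        probe_ids=[str(p) for p in ds.coords["probe"].values],
        diagnostics=json.loads(ds.attrs.get("diagnostics", "{}")),
        converged=bool(ds.attrs.get("converged", 1)),
        warnings=json.loads(ds.attrs.get("warnings", "[]")),
        config=CalibrationConfig(**cfg) if cfg else None,
    )


_SPATIAL_DIMS = {
    "g": ("probe",),
    "h": ("probe",),
    "latent_g": ("probe",),
    "latent_h": ("probe",),
    "sigma_i": ("probe",),
    "r_star": ("probe",),
    "alpha_g": ("fov",),
    "alpha_h": ("fov",),
    "mu_g": ("fov",),
    "mu_h": ("fov",),
    "l_g": ("fov", "dim"),
    "l_h": ("fov", "dim"),
    "alpha_mu_g": ("condition",),
    "alpha_mu_h": ("condition",),
    "alpha_sigma_g": ("condition",),
    "alpha_sigma_h": ("condition",),
    "M_g": ("condition",),
    "M_h": ("condition",),
}


def save_spatial_posterior(post: SpatialPosterior, path):
    data_vars = {}
    for name, arr in post.draws.items():
        dims = ("chain", "draw") + _SPATIAL_DIMS.get(name, ())
        data_vars[name] = (dims, arr)
    ds = xr.Dataset(
        data_vars,
        coords={
            "probe": list(post.probe_ids),
            "fov": list(post.fov_ids),
            "condition": list(post.conditions),
            "dim": ["x", "y"],
        },
        attrs={
            "locations_um": json.dumps(post.locations_um.tolist()),
            "fov_of_probe": json.dumps(post.fov_of_probe.tolist()),
            "condition_of_fov": json.dumps(post.condition_of_fov.tolist()),
            "coord_scale": post.coord_scale,
            "diagnostics": json.dumps(_plain(post.diagnostics)),
            "converged": int(post.converged),
            "warnings": json.dumps(list(post.warnings)),
        },
    )
    _quiet_to_zarr(ds, path)


def load_spatial_posterior(path) -> SpatialPosterior:
    ds = xr.open_zarr(str(path))
    draws = {name: ds[name].values for name in ds.data_vars}
    return SpatialPosterior(
        draws=draws,
        probe_ids=[str(p) for p in ds.coords["probe"].values],
        locations_um=np.array(json.loads(ds.attrs["locations_um"])),
        fov_ids=[str(f) for f in ds.coords["fov"].values],
        fov_of_probe=np.array(json.loads(ds.attrs["fov_of_probe"]), dtype=np.intp),
        conditions=[str(c) for c in ds.coords["condition"].values],
        condition_of_fov=np.array(json.loads(ds.attrs["condition_of_fov"]), dtype=np.intp),
        coord_scale=float(ds.attrs["coord_scale"]),
        diagnostics=json.loads(ds.attrs.get("diagnostics", "{}")),
        converged=bool(ds.attrs.get("converged", 1)),
        warnings=json.loads(ds.attrs.get("warnings", "[]")),
    )


def write_field_map(fmap, path):
    gx, gy = np.meshgrid(fmap.x, fmap.y)
    pd.DataFrame(
        {
            "x_um": gx.ravel(),
            "y_um": gy.ravel(),
            "mean": fmap.mean.ravel(),
            "sd": fmap.sd.ravel(),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_gcurve(curve, path):
    cols = {"r_um": curve.radii, "g_empirical": curve.g}
    if curve.theoretical is not None:
        cols["g_theoretical"] = curve.theoretical
    if curve.envelope_lo is not None:
        cols["envelope_lo"] = curve.envelope_lo
        cols["envelope_hi"] = curve.envelope_hi
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
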