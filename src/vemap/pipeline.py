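"""End-to-end analysis pipeline: calibrate, preprocess, fit, summarise.

Sequences the stages a full run needs — oil calibration (when oil data are
present), signal preprocessing, the spatial fit, field maps and condition
contrasts — logging seeds, priors and diagnostics at each stage and writing a
reproducible artifact bundle (resolved config echo included).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from ._mcmc import MCMCSettings
from .calibration import fit_calibration, summarize_calibration
from .io import (
    RunConfig,
    load_calibration_posterior,
    read_fov_datasets,
    read_probe_table,
    read_signal_table,
    save_calibration_posterior,
    save_spatial_posterior,
    write_estimates,
    write_field_map,
)
from .posterior import heterogeneity_contrast, population_means, predict_field
from .signals import baseline_estimates, synchronize_and_subsample
from .spatial import build_spatial_model, fit_spatial

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """A sampling stage failed its convergence diagnostics."""

    def __init__(self, stage: str, report: dict):
        super().__init__(f"{stage}: convergence diagnostics failed: {report}")
        self.stage = stage
        self.report = report


def run_pipeline(config: RunConfig, outdir=None, strict: bool = True) -> dict:
    """Run calibrate -> preprocess -> fit -> map/contrast from a config.

    ``config.paths`` must name ``probes`` and ``signals`` tables and may name
    ``oil_probes``/``oil_signals`` (or a stored ``calibration`` posterior);
    without oil data a ``fixed_fv`` is required.  Returns the artifact bundle
    as a dict; with ``strict`` a failed convergence check raises
    :class:`ConvergenceError` (the CLI maps this to a nonzero exit status).
    """
    paths = config.paths
    outdir = Path(outdir or paths.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    bundle: dict = {"outdir": str(outdir)}
    f = config.acquisition.drive_frequency
    logger.info("pipeline seed=%d", config.seed)

    # --- calibration ------------------------------------------------------
    if paths.get("calibration"):
        cal = load_calibration_posterior(paths["calibration"])
        fv_source = cal
    elif paths.get("oil_signals") and paths.get("oil_probes"):
        oil_probes = read_probe_table(paths["oil_probes"])
        oil_signals = read_signal_table(paths["oil_signals"], drive_frequency=f)
        oil_signals = [
            synchronize_and_subsample(s, factor=config.subsample_factor) for s in oil_signals
        ]
        cal = fit_calibration(
            oil_signals,
            oil_probes,
            config.calibration,
            MCMCSettings(
                chains=config.mcmc.chains,
                draws=config.mcmc.draws,
                warmup=config.mcmc.warmup,
                seed=config.seed,
            ),
        )
        save_calibration_posterior(cal, outdir / "calibration.zarr")
        bundle["calibration"] = summarize_calibration(cal)
        if strict and not cal.converged:
            raise ConvergenceError("calibration", cal.diagnostics)
        fv_source = cal
    elif config.fixed_fv:
        cal = None
        fv_source = float(config.fixed_fv)
    else:
        raise ValueError("no calibration data and no fixed_fv configured")

    # --- preprocess + baseline -------------------------------------------
    if not (paths.get("probes") and paths.get("signals")):
        raise ValueError("config.paths must provide 'probes' and 'signals'")
    fovs = read_fov_datasets(paths["probes"], paths["signals"], drive_frequency=f)
    fv_value = (
        fv_source if isinstance(fv_source, float) else summarize_calibration(fv_source)["mean"]
    )
    estimates = []
    for fov in fovs:
        fov.signals = [
            synchronize_and_subsample(s, factor=config.subsample_factor) for s in fov.signals
        ]
        estimates.extend(baseline_estimates(fov.signals, fov.probes, fv=fv_value))
    write_estimates(estimates, outdir / "estimates.csv")
    bundle["n_fovs"] = len(fovs)
    bundle["n_probes"] = sum(len(f_.magnetic_probes()) for f_ in fovs)

    # --- spatial fit ------------------------------------------------------
    model = build_spatial_model(fovs, fv_source, config.priors)
    mcmc = MCMCSettings(
        chains=config.mcmc.chains,
        draws=config.mcmc.draws,
        warmup=config.mcmc.warmup,
        seed=config.seed + 1,
    )
    post = fit_spatial(model, mcmc)
    save_spatial_posterior(post, outdir / "spatial.zarr")
    bundle["spatial_diagnostics"] = post.diagnostics
    if strict and not post.converged:
        raise ConvergenceError("spatial", post.diagnostics)

    # --- maps and contrasts ----------------------------------------------
    for fov in fovs:
        for kind in ("stiffness", "phase"):
            fmap = predict_field(post, fov.fov_id, kind=kind, n_grid=25, seed=config.seed)
            write_field_map(fmap, outdir / f"map_{fov.fov_id}_{kind}.csv")
    bundle["population_means"] = {
        cond: {
            k: {kk: v[k][kk] for kk in ("mean", "sd", "ci95")} for k in ("stiffness", "phase")
        }
        for cond, v in ((c, population_means(post, c)) for c in post.conditions)
    }
    conds = post.conditions
    if len(conds) >= 2:
        contrasts = {}
        for a in conds:
            for b in conds:
                if a < b:
                    res = heterogeneity_contrast(post, a, b)
                    contrasts[f"{a}-{b}"] = {
                        kind: {
                            "probability_positive": r.probability_positive,
                            "mean": r.mean,
                            "ci95": r.ci95,
                        }
                        for kind, r in res.items()
                    }
        bundle["heterogeneity_contrasts"] = contrasts

    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
    bundle["posterior"] = post
    bundle["calibration_posterior"] = cal
    return bundle


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items() if k not in ("posterior",)}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
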