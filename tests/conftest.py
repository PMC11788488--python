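"""Shared fixtures: small synthetic studies and session-scoped fitted posteriors.

MCMC fits are expensive, so every test that only needs *a* fitted posterior
shares one; scale-sensitive checks build their own reduced datasets.
"""

import numpy as np
import pytest

from vemap import synthdata as sd
from vemap._mcmc import MCMCSettings
from vemap.calibration import CalibrationConfig, fit_calibration
from vemap.datatypes import AcquisitionConfig
from vemap.signals import synchronize_and_subsample
from vemap.spatial import build_spatial_model, fit_spatial

FV_TRUE = 280_000.0


def subsample_fov(fov, factor=20):
    fov.signals = [synchronize_and_subsample(s, factor=factor) for s in fov.signals]
    return fov


@pytest.fixture(scope="session")
def acq_short():
    return AcquisitionConfig(n_cycles=2)


@pytest.fixture(scope="session")
def small_fov_pair(acq_short):
    """Two fields of view (conditions ctrl/caf), 4 magnetic probes each."""
    fovs, truths = [], []
    for j, cond in enumerate(["ctrl", "caf"]):
        fov, truth = sd.make_fov_dataset(
            f"{cond}_fov0",
            condition=cond,
            n_magnetic=4,
            n_reference=12,
            acq=acq_short,
            fv=FV_TRUE,
            noise_sd=5.0,
            seed=100 + j,
        )
        fovs.append(subsample_fov(fov))
        truths.append(truth)
    return fovs, truths


@pytest.fixture(scope="session")
def fitted_spatial(small_fov_pair):
    fovs, truths = small_fov_pair
    model = build_spatial_model(fovs, FV_TRUE)
    post = fit_spatial(model, MCMCSettings(chains=4, draws=400, warmup=600, seed=7))
    return post, fovs, truths


@pytest.fixture(scope="session")
def oil_study(acq_short):
    """12 oil probes with drift and noise, plus their fitted posterior."""
    probes = sd.sample_probe_layout(12, 0, (600, 600), seed=11)
    signals = sd.synthesize_calibration_signals(
        probes, fv=FV_TRUE, acq=acq_short, drift_nm_per_s=1.0, noise_sd_nm=5.0, seed=12
    )
    signals = [synchronize_and_subsample(s, factor=20) for s in signals]
    post = fit_calibration(
        signals,
        probes,
        CalibrationConfig(),
        MCMCSettings(chains=4, draws=400, warmup=2000, seed=13, thin=5),
    )
    return probes, signals, post
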