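"""Shared fixtures: the default synthetic study is simulated once per session.

The default cube (60×40 pixels, m/z 700–3000 at 0.25 Da) and its
preprocessed feature matrix back most recovery tests; the miniature cube
backs I/O round-trips.
"""

from __future__ import annotations

import numpy as np
import pytest

from thyromsi import discovery as _discovery
from thyromsi import preprocess as _preprocess
from thyromsi import synthetic_msi as synth
from thyromsi.msi_data import HP, NIFTP


@pytest.fixture(scope="session")
def default_sim():
    """(cfg, dataset, roi, truth) for the default study conditions, seed 42."""
    cfg = synth.default_config(seed=42)
    ds, roi, truth = synth.simulate_dataset(cfg)
    return cfg, ds, roi, truth


@pytest.fixture(scope="session")
def feature_matrix(default_sim):
    _cfg, ds, _roi, _truth = default_sim
    return _preprocess.preprocess_dataset(ds)


@pytest.fixture(scope="session")
def niftp_hp_results(default_sim, feature_matrix):
    _cfg, _ds, roi, _truth = default_sim
    return _discovery.discover(feature_matrix, roi, (NIFTP, HP))


@pytest.fixture(scope="session")
def small_sim():
    cfg = synth.small_config(seed=42)
    ds, roi, truth = synth.simulate_dataset(cfg)
    return cfg, ds, roi, truth


def noise_free_single_peptide_config(seed: int = 0) -> synth.SimulationConfig:
    """One PPIA peptide in NIFTP only; no baseline, TIC variation or noise."""
    profile = {f"{NIFTP}:{synth.RAS_MUTANT}": 100.0}
    panel = (synth.PeptideSpec(1505.83, "PPIA", profile),)
    regions = (
        synth.RegionSpec(
            NIFTP, ("rect", 0, 0, 4, 9), nodule_id=1, profile=synth.RAS_MUTANT
        ),
        synth.RegionSpec(synth.THYP, ("rest",)),
    )
    return synth.SimulationConfig(
        grid=(10, 10),
        regions=regions,
        peptide_panel=panel,
        baseline=(0.0, 400.0),
        tic_variation=0.0,
        noise_sd=0.0,
        mz_axis=(1490.0, 1520.0, 0.25),
        nodule_classes={1: synth.RAS_MUTANT},
        seed=seed,
    )


def brute_force_auc(a, b) -> float:
    """O(n·m) pair-counting oracle with half credit for ties."""
    a, b = np.asarray(a), np.asarray(b)
    wins = sum(float(x > y) + 0.5 * float(x == y) for x in a for y in b)
    return wins / (len(a) * len(b))
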