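import numpy as np
import pandas as pd
import pytest

from morpharm import synthetic as syn


@pytest.fixture(scope="session")
def noiseless_plate():
    """Deterministic logistic plate with known EC50s and no noise."""
    cfg = syn.BretPlateConfig(seed=7, noise_sd=0.0)
    df, gt = syn.gen_bret_plate(cfg)
    return df, gt, cfg


@pytest.fixture(scope="session")
def apex_dataset():
    matrix, sheet, gt = syn.gen_apex_dataset(syn.ApexConfig(seed=11))
    return matrix, sheet, gt


@pytest.fixture(scope="session")
def small_kinetic_plate():
    """Two-pathway kinetic plate on a short 5-point grid (fast fits)."""
    tps = (2.0, 12.0, 24.0, 36.0, 46.0)
    cfg = syn.KineticBretConfig(
        seed=5, timepoints_min=tps,
        trajectories=syn.default_kinetic_trajectories(tps),
        noise_sd=0.0, n_replicates=2,
    )
    df, gt = syn.gen_kinetic_bret(cfg)
    return df, gt, cfg
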