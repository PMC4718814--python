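"""Shared fixtures: small seeded synthetic datasets.

Session-scoped fixtures are used for the more expensive generated datasets
so multiple tests can share them.
"""

import numpy as np
import pandas as pd
import pytest

from pfcdyn import pca, synthetic as syn


@pytest.fixture(scope="session")
def trials500():
    return syn.gen_trial_table(500, softmax_temperature=1.0, seed=11)


@pytest.fixture(scope="session")
def lfp_default(trials500):
    """Default-SNR LFP from one region, 4 electrodes, plus ground truth."""
    arrays, truth = syn.gen_lfp(
        trials500, n_electrodes_per_region=4, regions=("DLPFC",), seed=11
    )
    return arrays, truth


@pytest.fixture(scope="session")
def decomposition(lfp_default):
    arrays, truth = lfp_default
    stacked = pca.stack(arrays)
    mask = pca.artifact_mask(stacked)
    d = pca.decompose(stacked, k=10, mask=mask)
    return d, stacked, truth


def align_truth(decomp, truth, column):
    """Ground-truth latent values aligned to the retained rows of a
    decomposition."""
    t = truth.set_index(["electrode_id", "trial_id"])
    key = list(zip(decomp.row_index.electrode_id, decomp.row_index.trial_id))
    return t.loc[key, column].to_numpy()


@pytest.fixture(scope="session")
def multi_region_session():
    """Simultaneous three-region session with spikes coupled to the shared
    DLPFC latent (full mediation), for the coupling analyses."""
    trials = syn.gen_trial_table(400, seed=21)
    arrays, truth = syn.gen_lfp(
        trials, n_electrodes_per_region=2, regions=("DLPFC", "OFC", "ACC"), seed=21
    )
    model = syn.SpikeModel(mediation=1.0, cv_weight_hz=6.0)
    rasters, units = syn.gen_spikes(
        trials, model, truth, n_units=12, seed=21, region="DLPFC"
    )
    return trials, arrays, truth, rasters, units
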