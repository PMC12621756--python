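import numpy as np
import pytest

from immunotwin import GroundTruth, SyntheticConfig, generate_atlas


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_donors=4,
        n_cells=400,
        cell_types=("cMC", "NK"),
        stimulations=("LPS",),
        treatments=("SA",),
        markers=("pSTAT1", "pSTAT3", "pSTAT5", "pS6"),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    truth = GroundTruth.null(small_config, tau=0.3)
    stim = dict(truth.stim_effects)
    for ct in small_config.cell_types:
        for m in small_config.markers:
            stim[(ct, m, "LPS")] = (0.5, 1.0)
    drug = dict(truth.drug_effects)
    for ct in small_config.cell_types:
        for m in small_config.markers:
            drug[(ct, m, "SA")] = (-0.3, 1.0)
    truth.stim_effects = stim
    truth.drug_effects = drug
    return truth


@pytest.fixture(scope="session")
def small_atlas(small_config, small_truth):
    return generate_atlas(small_config, small_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
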