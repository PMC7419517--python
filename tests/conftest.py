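import numpy as np
import pytest

from randhe import annotations as annot_mod
from randhe import simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Standardized 200 x 300 genotype matrix with frequencies/positions."""
    block, freqs, positions = simulate.standardized_dataset(200, 300, seed=11)
    return block, freqs, positions


@pytest.fixture(scope="session")
def annot8(small_dataset):
    """The 8-bin MAF/LD partition on the small dataset."""
    block, freqs, _ = small_dataset
    scores = annot_mod.compute_ld_scores(block, window_bp=50_000).scores
    return annot_mod.make_maf_ld_partition(freqs, scores, (0.05,), 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
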