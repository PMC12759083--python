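import numpy as np
import pandas as pd
import pytest

from mitosense import synthetic_data as sd
from mitosense import screen_scoring as ss


@pytest.fixture(scope="session")
def small_screen():
    """One 100-gene screen with a strong planted depletion on GENE0001."""
    cfg = sd.ScreenSimConfig(n_genes=100, effect_table={"GENE0001": -3.0}, seed=11)
    high, low, truth = sd.simulate_screen(cfg)
    return high, low, truth


@pytest.fixture(scope="session")
def noiseless_image():
    """Noiseless rendered image with a 50/50 membrane-potential split."""
    cfg = sd.ImageSimConfig(
        shape=(256, 256), n_mito=20, frac_low_mmp=0.5, noise_sd=0.0, seed=4
    )
    channels, truth = sd.simulate_cell_image(cfg)
    return channels, truth


@pytest.fixture()
def full_frame_roi():
    return [(2, 2), (2, 253), (253, 253), (253, 2)]


def toy_count_pair(counts_high, counts_low, genes=None):
    """Build matched high/low count tables from per-guide replicate lists."""
    n = len(counts_high)
    guide_ids = [f"g{i:02d}" for i in range(n)]
    genes = genes or [f"GENE{i:02d}" for i in range(n)]
    reps = len(counts_high[0])
    cols = [f"rep{r + 1}" for r in range(reps)]
    high = pd.DataFrame({"guide_id": guide_ids, "gene": genes})
    low = high.copy()
    for r, col in enumerate(cols):
        high[col] = [c[r] for c in counts_high]
        low[col] = [c[r] for c in counts_low]
    return high, low


def score_six_screens(tables, **kwargs):
    """Gene-level scores for each screen of a simulate_six_screens output."""
    return {k: ss.score_screen(h, l, **kwargs)[1] for k, (h, l) in tables.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
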