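import warnings

import numpy as np
import pandas as pd
import pytest

from clgrow import defaults
from clgrow.synth import SimConfig

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture()
def grid_cohort():
    """168-plant cohort around the study cell means, plant values spread on
    a bounded regular grid within each block group: ground truth contains
    no natural Tukey extremes, so planted ones are the only outliers."""
    rows = []
    for blk in range(1, 5):
        for (tr, cv), m in defaults.HARVEST_CELL_MEANS.items():
            n = 11 if cv == "Danstar" else 10
            offs = np.linspace(-1.5, 1.5, n) * 2.0
            for i, off in enumerate(offs):
                rows.append((blk, tr, cv, i,
                             m["fresh_mass"] * (1 + 0.01 * blk) + off))
    return pd.DataFrame(rows, columns=["block", "treatment", "cultivar",
                                       "plant_id", "value"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture()
def zero_noise_config():
    return SimConfig(seed=11).with_zero_noise()
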