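import numpy as np
import pandas as pd
import pytest

import lofadapt as la
from lofadapt import footprint_stats as fs


@pytest.fixture(scope="session")
def small_footprint():
    """300-gene, one-condition dataset with known spiked effects."""
    cfg = la.FootprintSimConfig(
        seed=11,
        n_genes=300,
        replicates_per_condition={"ala": 3},
        frac_beneficial=0.05,
        frac_deleterious=0.05,
        effect_size={"fixed": 4.0},
    )
    return la.simulate_footprint_dataset(cfg)


@pytest.fixture(scope="session")
def normalized_small(small_footprint):
    data, _ = small_footprint
    return fs.normalize(data)


@pytest.fixture(scope="session")
def toy_models():
    return {v: la.make_toy_metabolic_model(v) for v in la.synthetic_data.TOY_VARIANTS}


def flat_dataset(n_genes: int = 120, n_ref: int = 3, n_sel: int = 2, spread: float = 2.0):
    """All arrays identical: per-gene baselines only, no noise."""
    rng = np.random.default_rng(5)
    base = np.exp2(rng.normal(0.0, spread, n_genes))
    cols = [("ref", "pre", f"r{i}") for i in range(n_ref)] + [
        ("sel", "ala", f"r{i}") for i in range(n_sel)
    ]
    values = pd.DataFrame(
        np.tile(base[:, None], (1, n_ref + n_sel)),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=pd.MultiIndex.from_tuples(cols, names=["role", "condition", "replicate"]),
    )
    return fs.FootprintDataset(values)
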