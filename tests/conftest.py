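import numpy as np
import pandas as pd
import pytest

import prediagtx as px


@pytest.fixture(scope="session")
def small_cohort():
    """20-pair cohort with a planted '123' trend block, generated once."""
    cfg = px.SyntheticConfig(
        n_pairs=20,
        n_genes=300,
        seed=7,
        exact_counts=True,
        planted_trends=(("123", 30, 0.5),),
    )
    return cfg, px.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    cfg, (raw, meta, signature, truth) = small_cohort
    expr = px.run_preprocess(raw)
    D, pair_meta = px.make_differences(expr, meta)
    return expr, D, pair_meta


@pytest.fixture(scope="session")
def make_cohort_differences():
    """Factory: generate a cohort and return its pair-difference matrix.

    Used by calibration/power simulations; a null cohort (no planted
    trends, no composition shift) is exchangeable within pairs, so the
    sign-flip null holds exactly.
    """

    def _make(seed, n_genes=500, n_pairs=100, planted_trends=(), neutrophil_shift=0.0,
              raw_transform=None):
        cfg = px.SyntheticConfig(
            n_pairs=n_pairs,
            n_genes=n_genes,
            seed=seed,
            exact_counts=True,
            planted_trends=planted_trends,
            neutrophil_shift=neutrophil_shift,
        )
        raw, meta, signature, truth = px.generate_cohort(cfg)
        if raw_transform is not None:
            raw_transform(raw, meta)
        expr = px.run_preprocess(raw)
        D, pair_meta = px.make_differences(expr, meta)
        return D, pair_meta, truth

    return _make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
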