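import numpy as np
import pandas as pd
import pytest

from altinet import SimConfig, log_transform, rpkm, simulate_counts


@pytest.fixture(scope="session")
def small_study():
    """A small simulated paired study shared by read-only tests."""
    cfg = SimConfig(n_genes=400, seed=11)
    counts, design, truth = simulate_counts(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def small_log_expr(small_study):
    _, counts, design, _ = small_study
    return log_transform(rpkm(counts)), design


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
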