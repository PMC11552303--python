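import numpy as np
import pandas as pd
import pytest

from cosegsel.simcross import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A scaled-down world for fast unit tests."""
    return SimConfig(
        seed=7,
        n_f1=40,
        n_genes=300,
        n_background_de=30,
        n_linked=5,
        n_proteins=150,
        n_protein_de=20,
        n_absent=10,
        lib_size_mean=100_000,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_count_df(rng: np.random.Generator, n_genes: int = 150) -> pd.DataFrame:
    """Deterministic 4-sample count table with one composition-biased library.

    Samples: S1 baseline, S2 double depth, S3 with 15 genes inflated 8x
    (composition bias), S4 half depth.
    """
    base = rng.lognormal(3, 1, n_genes)
    return pd.DataFrame({
        "S1": rng.poisson(base * 10),
        "S2": rng.poisson(base * 20),
        "S3": rng.poisson(base * 10 * np.where(np.arange(n_genes) < 15, 8, 1)),
        "S4": rng.poisson(base * 5),
    })
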