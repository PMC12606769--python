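from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import proacs as pa

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def grid():
    return pa.load_composite_grid()


@pytest.fixture(scope="session")
def oracle_grid() -> pd.DataFrame:
    """Frozen outputs of the ProAE toxScores reference implementation over
    every reachable (pattern, response tuple) combination."""
    return pd.read_csv(DATA_DIR / "proae_toxscores_oracle.csv")


@pytest.fixture(scope="session")
def lung_dataset():
    cfg = pa.preset_config("lung8", n_patients=400, seed=1)
    return cfg, pa.generate_dataset(cfg)


@pytest.fixture(scope="session")
def lung_composites(lung_dataset):
    cfg, ds = lung_dataset
    table = pa.compute_composites(ds.items, cfg.terms)
    return pa.compute_acs(table)


@pytest.fixture(scope="session")
def lung_cfa(lung_composites):
    poly = pa.polychoric_matrix(lung_composites)
    solution = pa.fit_cfa(poly, n=poly.n_effective)
    return poly, solution
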