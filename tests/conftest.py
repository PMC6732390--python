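import numpy as np
import pandas as pd
import pytest

from dimorphtrade import Phylogeny, read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tree3() -> Phylogeny:
    return read_newick("((A:1,B:1):1,C:2);")


def make_specimens(rows) -> pd.DataFrame:
    """Rows of (id, species, sex, sl, rakers tuple, d13C, d15N, mode)."""
    recs = []
    for sid, sp, sex, sl, rakers, c, n, mode in rows:
        rec = {"specimen_id": sid, "species": sp, "sex": sex,
               "standard_length": sl, "d13C": c, "d15N": n, "breeding_mode": mode}
        for i, r in enumerate(rakers, 1):
            rec[f"raker_{i}"] = r
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def specimen_csv(tmp_path):
    """Six-row table, one with SL = 0 (must be rejected)."""
    df = make_specimens([
        ("f1", "A", "female", 80.0, (0.50, 0.52, 0.54), -18.0, 7.0, "uniparental"),
        ("f2", "A", "male", 85.0, (0.40,), -18.5, 7.2, "uniparental"),
        ("f3", "B", "female", 90.0, (0.61, 0.63, 0.65), -16.0, 8.0, "biparental"),
        ("f4", "B", "male", 0.0, (0.62, 0.60, 0.64), -16.2, 8.1, "biparental"),
        ("f5", "C", "unknown", 100.0, (0.70, 0.72, 0.74), -14.0, 9.0, "nonmouthbrooding"),
        ("f6", "C", "female", 95.0, (0.68, 0.70, 0.69), -14.5, 8.8, "nonmouthbrooding"),
    ])
    path = tmp_path / "specimens.csv"
    df.to_csv(path, index=False)
    return path
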