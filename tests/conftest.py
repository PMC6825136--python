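import numpy as np
import pytest

import paleotf as pt


@pytest.fixture(scope="session")
def cal100():
    """A 100-site default synthetic calibration set (with truth)."""
    cal, truth = pt.gen_calibration(pt.default_preset(n_sites=100), seed=1)
    return cal, truth


@pytest.fixture(scope="session")
def cal60():
    """A smaller calibration set for per-fold oracle tests."""
    cal, truth = pt.gen_calibration(pt.default_preset(n_sites=60), seed=2)
    return cal, truth


@pytest.fixture()
def toy_tables(tmp_path):
    """A 5-site x 4-taxon CSV dataset written to disk."""
    rng = np.random.default_rng(5)
    ids = [f"s{i}" for i in range(5)]
    taxa = ["Pinus", "Betula", "Quercus", "Artemisia"]
    counts = rng.integers(1, 200, size=(5, 4)).astype(float)
    import pandas as pd
    pd.DataFrame(counts, columns=taxa).assign(site_id=ids)[
        ["site_id"] + taxa].to_csv(tmp_path / "taxa.csv", index=False)
    pd.DataFrame({"site_id": ids, "lon": rng.uniform(5, 25, 5),
                  "lat": rng.uniform(45, 60, 5),
                  "elevation": rng.uniform(0, 800, 5)}
                 ).to_csv(tmp_path / "meta.csv", index=False)
    pd.DataFrame({"site_id": ids, "T_jul": rng.uniform(10, 18, 5),
                  "water_balance": rng.uniform(-100, 200, 5)}
                 ).to_csv(tmp_path / "climate.csv", index=False)
    return tmp_path
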