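import numpy as np
import pandas as pd
import pytest

from pollenomics.lipid_model import default_registry
from pollenomics.synthetic_data import TruthConfig, gen_lipidome


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def noise_free_lipidome():
    """Deterministic lipidome with the default injected effects and CV=0."""
    cfg = TruthConfig(seed=7, cv=0.0)
    peaks, sheet, truth = gen_lipidome(cfg)
    return peaks, sheet, truth


@pytest.fixture()
def toy_peaks():
    """Hand-computable 3-species, 2-sample peak table (single subclass)."""
    rows = []
    for sample in ("A", "B"):
        scale = 1.0 if sample == "A" else 2.0
        for species, area, trans in [
            ("PC 16:0_16:0", 50.0, ["T1"]),
            ("PC 16:0_18:1", 30.0, ["T1", "T2"]),
            ("PC 16:0_18:2", 20.0, ["T1"]),
        ]:
            for i, t in enumerate(trans):
                frac = 1.0 if len(trans) == 1 else (0.6, 0.4)[i]
                rows.append(
                    {
                        "sample_id": sample,
                        "subclass": "PC",
                        "species": species,
                        "transition_id": t,
                        "area": area * frac * scale,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_sheet():
    return pd.DataFrame(
        {
            "sample_id": ["A", "B"],
            "condition": ["RT3", "HS3+3"],
            "replicate": [1, 1],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
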