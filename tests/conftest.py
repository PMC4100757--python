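import numpy as np
import pandas as pd
import pytest

from paircause.synthetic import PanelDataset


def make_panel(n, rng=None, **overrides) -> PanelDataset:
    """Minimal valid panel with independent noise in every column; individual
    columns can be overridden to construct targeted scenarios."""
    rng = rng or np.random.default_rng(0)
    cols = {
        "id": np.arange(1, n + 1),
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(42, 5, n),
        "tv1": rng.exponential(100, n), "tv2": rng.exponential(100, n),
        "tv3": rng.exponential(100, n),
        "waist1": rng.normal(85, 12, n), "waist2": rng.normal(88, 13, n),
        "waist3": rng.normal(92, 14, n),
        "bmi0": rng.normal(20, 2.5, n), "bmi1": rng.normal(25, 4, n),
        "bmi2": rng.normal(26, 4.5, n), "bmi3": rng.normal(26.5, 5, n),
        "pa_index": rng.normal(2.5, 0.6, n),
        "energy_intake": rng.normal(2200, 600, n).clip(800),
        "smoker": rng.integers(0, 2, n),
    }
    cols.update(overrides)
    return PanelDataset(frame=pd.DataFrame(cols))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
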