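import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from caprokin import FitConfig
from caprokin.growth_io import GrowthCurve


@pytest.fixture
def fast_config():
    """Fit configuration with a small bootstrap, for unit tests."""
    return FitConfig(seed=1291007, n_boot=50, n_mc=2000)


@pytest.fixture
def no_boot_config():
    return FitConfig(seed=1291007, n_boot=0)


@pytest.fixture
def curve_files(tmp_path):
    """A small curve CSV (2 conditions x 4 replicates x 60 rows) + conditions."""
    rng = np.random.default_rng(42)
    t = np.linspace(0.0, 120.0, 60)
    rows = []
    for cond in ("c1", "c2"):
        for rep in ("r1", "r2", "r3", "r4"):
            signal = 100.0 * np.exp(
                1.2 * np.exp(-np.exp(0.09 * (8.0 - t) + 1))
                + rng.normal(0, 0.01, t.size)
            )
            for ti, si in zip(t, signal):
                rows.append(
                    {"time_h": ti, "signal": si, "replicate": rep,
                     "condition_id": cond}
                )
    curves_path = tmp_path / "curves.csv"
    pd.DataFrame(rows).to_csv(curves_path, index=False)
    cond_path = tmp_path / "conditions.csv"
    pd.DataFrame(
        {
            "condition_id": ["c1", "c2"],
            "glucose_g_l": [2.0, 2.0],
            "caproate_g_l": [0.0, 4.0],
            "organism": ["LM", "LM"],
        }
    ).to_csv(cond_path, index=False)
    return curves_path, cond_path


def make_curve(times, signals, rep="r1", cond="c1", **meta):
    return GrowthCurve(
        replicate_id=rep, condition_id=cond,
        times=np.asarray(times, float), signals=np.asarray(signals, float),
        meta=meta,
    )
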