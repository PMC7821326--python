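import numpy as np
import pandas as pd
import pytest

from partnest.data import TrialDataset
from partnest.synthetic import ScenarioConfig, generate_trial


@pytest.fixture(scope="session")
def midsize_trial() -> TrialDataset:
    """One 200/arm trial with noncompliance, heteroscedasticity and clustering."""
    cfg = ScenarioConfig(
        n_per_arm=200,
        group_size=5,
        compliance_rate=0.8,
        gamma=0.75,
        tau=0.0,
        icc=0.1,
        variance_ratio=1.5,
        seed=42,
    )
    return generate_trial(cfg)


@pytest.fixture()
def toy_frame() -> pd.DataFrame:
    """Six subjects, two intervention groups, one noncomplier."""
    return pd.DataFrame(
        {
            "id": ["c1", "c2", "c3", "t1", "t2", "t3"],
            "y": [0.1, -0.4, 0.3, 1.2, 0.8, -0.1],
            "r": [0, 0, 0, 1, 1, 1],
            "t": [0, 0, 0, 1, 0, 1],
            "intended_group": ["c1", "c2", "c3", "g1", "g1", "g2"],
        }
    )


def make_backpain_like(path):
    """Synthetic stand-in shaped like the lower-back-pain trial data.

    203 subjects, 105 randomized to group therapy of whom 71 comply across
    17 actual groups; sqrt-VAS-scale outcome with a baseline covariate.
    This is a synthetic construction for loader tests, not the trial data.
    """
    rng = np.random.default_rng(8778)
    n0, n1, n_comp, n_groups = 98, 105, 71, 17
    sizes = np.full(n_groups, n_comp // n_groups)
    sizes[: n_comp % n_groups] += 1
    rows = []
    for i in range(n0):
        rows.append((f"s{i:03d}", 0, 0, ""))
    k = n0
    for g, size in enumerate(sizes):
        for _ in range(size):
            rows.append((f"s{k:03d}", 1, 1, f"g{g + 1:02d}"))
            k += 1
    for i in range(n1 - n_comp):
        rows.append((f"s{k:03d}", 1, 0, ""))
        k += 1
    df = pd.DataFrame(rows, columns=["id", "r", "t", "actual_group"])
    df["x"] = rng.normal(5.0, 1.5, len(df))
    df["y"] = 0.6 * df["x"] + rng.normal(0, 1.2, len(df)) - 0.4 * df["r"]
    df.loc[df["t"] == 1, "intended_group"] = df["actual_group"]
    df.to_csv(path, index=False)
    return path
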