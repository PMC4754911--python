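import numpy as np
import pandas as pd
import pytest


def make_oneway_table(
    n_genotypes: int,
    n_replicates: int,
    sigma_g: float,
    sigma_e: float,
    seed: int = 0,
    mu: float = 10.0,
) -> pd.DataFrame:
    """Balanced one-genotype-factor phenotype table with known variances."""
    rng = np.random.default_rng(seed)
    gidx = np.repeat(np.arange(n_genotypes), n_replicates)
    eff = rng.normal(0.0, sigma_g, n_genotypes)
    y = mu + eff[gidx] + rng.normal(0.0, sigma_e, gidx.size)
    return pd.DataFrame(
        {
            "genotype": [f"g{i:02d}" for i in gidx],
            "is_check": False,
            "experiment": "E1",
            "basin": "B1",
            "x": 0,
            "y": 0,
            "tile": np.arange(gidx.size),
            "x_within": 0,
            "y_within": 0,
            "time_h": 1.0,
            "trait": "trait",
            "value": y,
        }
    )


def oneway_anova_oracle(df: pd.DataFrame, n_replicates: int):
    """Closed-form balanced one-way ANOVA variance components."""
    y = df["value"].to_numpy()
    means = df.groupby("genotype")["value"].mean()
    k = len(means)
    ms_g = n_replicates * ((means - y.mean()) ** 2).sum() / (k - 1)
    ss_e = sum(
        ((df.loc[df["genotype"] == g, "value"] - m) ** 2).sum() for g, m in means.items()
    )
    ms_e = ss_e / (len(y) - k)
    return (ms_g - ms_e) / n_replicates, ms_e


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
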