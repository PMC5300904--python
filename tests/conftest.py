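import numpy as np
import pandas as pd
import pytest

from isletlnc.synthetic import (
    KnockdownSimConfig,
    TargetSpec,
    simulate_knockdown_experiment,
)


@pytest.fixture(scope="session")
def small_screen():
    """A 300-gene screen: one 2-amiRNA target with a planted 40-gene regulon
    (mixed-sign effects) next to five control groups."""
    rng = np.random.default_rng(7)
    regulon = sorted(rng.choice(np.arange(1, 300), size=40, replace=False).tolist())
    effects = list(rng.choice([-1.0, 1.0], size=40) * rng.uniform(1.2, 2.0, size=40))
    cfg = KnockdownSimConfig(
        n_genes=300,
        targets=[TargetSpec(name="LNC1", regulon=regulon, effect=effects, self_index=0)],
        n_controls=5,
        replicates_per_amirna=3,
        noise_sd=0.25,
        seed=11,
    )
    return simulate_knockdown_experiment(cfg)


@pytest.fixture()
def tiny_expr():
    """Two genes, two groups of three samples, exact values."""
    return pd.DataFrame(
        {
            "t1": [1.0, 5.0], "t2": [2.0, 5.0], "t3": [3.0, 5.0],
            "c1": [4.0, 5.0], "c2": [5.0, 5.0], "c3": [6.0, 5.0],
        },
        index=pd.Index(["gA", "gConst"], name="gene"),
    )
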