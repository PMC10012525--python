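import numpy as np
import pandas as pd
import pytest

from mahpselect import TrialDataset


def long_frame(cells):
    """Build a long-format frame from {(family, rep, condition, trait): value}."""
    rows = [
        {"family": f, "replicate": r, "condition": c, "trait": t, "value": v}
        for (f, r, c, t), v in cells.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def anova_fixture():
    """3 families x 2 replicates, one condition, one trait.

    Hand decomposition (grand mean 7): SS(rep) = 6, SS(fam) = 16,
    SS(err) = 0, MSf = 8.
    """
    cells = {
        ("A", "r1", "normal", "y"): 4.0,
        ("A", "r2", "normal", "y"): 6.0,
        ("B", "r1", "normal", "y"): 8.0,
        ("B", "r2", "normal", "y"): 10.0,
        ("C", "r1", "normal", "y"): 6.0,
        ("C", "r2", "normal", "y"): 8.0,
    }
    return TrialDataset(long_frame(cells))


def random_dataset(seed, g=5, r=3, conditions=("normal", "stress"), traits=("t1", "t2")):
    rng = np.random.default_rng(seed)
    cells = {
        (f"F{i}", f"R{j}", c, t): float(rng.normal(10, 3))
        for i in range(g)
        for j in range(r)
        for c in conditions
        for t in traits
    }
    return TrialDataset(long_frame(cells))


@pytest.fixture
def two_condition_ds():
    return random_dataset(seed=42)
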