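"""Bundled reference tables from a published tomato drought-stress trial.

A field case study evaluated 57 tomato families in 3 replicate blocks under
normal irrigation and drought stress, measuring 18 phenological,
morphological and physiological traits.  The package bundles the study's
printed summary tables as CSV so the estimators can be golden-tested
against published values without any raw-data download:

``case_anova_{normal,stress}.csv``
    Per-trait mean squares (replication / families / error), significance
    flags (``a`` = 5%, ``b`` = 1%), printed broad-sense heritability and
    expected genetic advance (% of mean).  Cells the study printed as
    "approximately zero" (negative raw genetic variance) are empty and
    load as NaN.
``case_stability.csv``
    The 15 retained traits' stability index (SI), heritability-stability
    ratio (SIBH), and genetic correlations with the two breeding targets
    (Yld, TSS) in each condition (capped to [-1, 1] as printed).
``case_weights.csv``
    Per-parameter eigenvector entries and final trait weights.
``case_scores.csv``
    Final family scores and the reported top-10 selection flags.

Three measured traits (H, CN, FN) were dropped by the study's trait filter
(no significant family differences in either condition), so the stability,
weight and score tables cover 15 traits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Trial dimensions of the bundled case study.
N_FAMILIES = 57
N_REPLICATES = 3

#: The study's breeding-target (dependent) traits.
DEPENDENT_TRAITS = ("Yld", "TSS")

#: Traits the study's filter removed (non-significant in both conditions).
FILTERED_TRAITS = ("H", "CN", "FN")


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.files("mahpselect.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, index_col=index_col)


def load_case_anova(condition: str) -> pd.DataFrame:
    """Mean squares and printed genetic parameters, indexed by trait."""
    if condition not in ("normal", "stress"):
        raise KeyError(f"condition must be 'normal' or 'stress' (got {condition!r})")
    df = _read(f"case_anova_{condition}.csv", index_col="trait")
    for col in ("sig_replication", "sig_families"):
        df[col] = df[col].fillna("")
    return df


def load_case_stability() -> pd.DataFrame:
    """SI, SIBH and capped genetic correlations, indexed by trait."""
    return _read("case_stability.csv", index_col="trait")


def load_case_weights() -> pd.DataFrame:
    """Printed eigenvector entries and final weights, indexed by trait."""
    return _read("case_weights.csv", index_col="trait")


def load_case_scores() -> pd.DataFrame:
    """Printed family scores and selection flags, indexed by family id."""
    df = _read("case_scores.csv", index_col="family")
    df.index = df.index.astype(str)
    df["selected"] = df["selected"].astype(bool)
    return df
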