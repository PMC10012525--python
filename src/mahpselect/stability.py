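"""Trait-stability statistics across a normal/stress condition pair.

Two statistics summarize how a trait behaves when the environment turns
hostile:

SI (stability index)
    The absolute ordinary-least-squares slope of the stress-condition
    family means regressed on the normal-condition family means.  A slope
    near zero means stress values barely track normal values, i.e. the
    trait expression is insensitive to which condition it is measured in —
    the smaller the SI the more stable the trait under this convention.
    This is the trait-level analog of the classical joint-regression
    stability analysis used for genotypes.

SIBH (stability index of broad-sense heritability)
    The ratio h2(stress) / h2(normal) of the *unclamped* family-mean
    heritabilities, reported in absolute value.  Values above 1 mean the
    genetic signal strengthens under stress, so selection on the trait
    remains (or becomes more) effective there.  The raw, possibly negative
    heritabilities must be used: a trait whose normal-condition family
    variance falls below the error expectation has a negative h2_raw, and
    only the signed ratio reproduces the intended small magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, UndefinedStatisticError
from .genetics import rcbd_anova, variance_components
from .trial_data import TrialDataset


@dataclass(frozen=True)
class StabilityParams:
    """Per-trait stability statistics across the condition pair."""

    trait: str
    si: float
    si_slope_raw: float
    sibh: float
    sibh_raw: float


def stability_index(normal_means, stress_means) -> tuple[float, float]:
    """OLS slope (with intercept) of stress on normal family means.

    Returns ``(si, slope)`` where ``si = |slope|``.
    """
    x = np.asarray(normal_means, dtype=float)
    y = np.asarray(stress_means, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("normal and stress mean vectors must be 1-D and equal length")
    if x.size < 3:
        raise DegenerateDataError(f"need >= 3 families for the SI regression (got {x.size})")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("normal-condition means are constant; slope undefined")
    slope = float(stats.linregress(x, y).slope)
    return abs(slope), slope


def sibh(h2_raw_normal: float, h2_raw_stress: float) -> tuple[float, float]:
    """Heritability-stability ratio from UNCLAMPED heritabilities.

    Returns ``(sibh, raw_ratio)`` with ``sibh = |raw_ratio|``.
    """
    if h2_raw_normal == 0:
        raise UndefinedStatisticError(
            "normal-condition raw heritability is zero; SIBH undefined"
        )
    raw = h2_raw_stress / h2_raw_normal
    return abs(raw), raw


def stability_table(
    ds: TrialDataset,
    normal: str = "normal",
    stress: str = "stress",
) -> list[StabilityParams]:
    """SI and SIBH for every trait of a two-condition dataset.

    Traits whose SIBH is undefined (zero normal-condition raw h2) get NaN
    entries rather than aborting the whole table.
    """
    mn = ds.family_means(normal)
    ms = ds.family_means(stress)
    out: list[StabilityParams] = []
    for trait in ds.traits:
        si, slope = stability_index(mn[trait].to_numpy(), ms[trait].to_numpy())
        h2n = variance_components(rcbd_anova(ds, trait, normal)).h2_raw
        h2s = variance_components(rcbd_anova(ds, trait, stress)).h2_raw
        try:
            s, raw = sibh(h2n, h2s)
        except UndefinedStatisticError:
            s, raw = float("nan"), float("nan")
        out.append(StabilityParams(trait=trait, si=si, si_slope_raw=slope,
                                   sibh=s, sibh_raw=raw))
    return out
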