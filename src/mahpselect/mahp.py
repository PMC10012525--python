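"""Eigenvector weighting and scoring (modified analytic hierarchy process).

Classical AHP elicits pairwise comparison matrices from expert judgment and
must police their consistency.  Here the matrices are *derived* from
measured parameter values: for a value vector ``v`` the comparison matrix
is ``A_ij = v_i / v_j``, which is reciprocal (``A_ij = 1/A_ji``), rank one,
and exactly consistent — its only non-zero eigenvalue is ``N`` and its
principal eigenvector is proportional to ``v`` itself.  This collapses the
eigenpair computation to a normalization, which is what the direct path
below implements (and what a dense eigensolver confirms in the tests).

Weighting proceeds in two mirrored stages:

1. *Trait weights* — each genetic parameter (stability indices, genetic
   correlations with the breeding targets, expected genetic advance per
   condition) supplies one value per trait; its unit-norm eigenvector is
   one column of the weight table and the final trait weight is the plain
   row sum across parameters.  Negative parameter values (correlations)
   pass through unchanged, so eigen entries and weights may be negative.
2. *Family scores* — each retained trait supplies one value per family
   (condition-averaged family means); the unit-norm eigenvectors are
   combined as a weighted sum with the final trait weights.

Parameters or traits where *small* is good are transformed first by
``max(values) - values`` so that the best entry gets the largest (and the
worst a zero) comparison value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DegenerateDataError
from .trial_data import TraitMeta


def transform_lower_better(values) -> np.ndarray:
    """Reflect a vector about its maximum: ``out_i = max(v) - v_i``.

    Used for traits/parameters where low values are desirable; the result
    is order-reversed and non-negative, with the maximum mapping to 0.  A
    constant vector maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return v.max() - v


@dataclass(frozen=True)
class ComparisonMatrix:
    """Exactly consistent pairwise comparison matrix ``A_ij = v_i / v_j``."""

    labels: tuple[str, ...]
    vector: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return np.outer(self.vector, 1.0 / self.vector)

    def __len__(self) -> int:
        return len(self.vector)


def build_comparison_matrix(
    values, labels: Sequence[str] | None = None
) -> ComparisonMatrix:
    """Build the consistency comparison matrix generated by ``values``.

    Every entry must be non-zero (a zero value has no finite reciprocal
    comparison; use :func:`principal_eigenpair` on the raw vector instead,
    which handles zeros).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if np.any(v == 0):
        raise ZeroDivisionError(
            "comparison matrix undefined for zero entries; "
            "use principal_eigenpair on the generating vector directly"
        )
    if labels is None:
        labels = tuple(str(i) for i in range(v.size))
    if len(labels) != v.size:
        raise AlignmentError("labels length does not match vector length")
    return ComparisonMatrix(labels=tuple(labels), vector=v)


def principal_eigenpair(obj) -> tuple[float, np.ndarray]:
    """Principal eigenvalue and unit-norm eigenvector of a consistency
    matrix or of the raw generating vector.

    For a consistency matrix of size N the principal eigenvalue is exactly
    N and the eigenvector is the generating vector scaled to unit
    Euclidean norm, with its sign oriented along the generating vector
    (``x . v > 0``).
    """
    if isinstance(obj, ComparisonMatrix):
        v = obj.vector
        n = len(obj)
    else:
        arr = np.asarray(obj, dtype=float)
        if arr.ndim == 2:
            if arr.shape[0] != arr.shape[1]:
                raise ValueError("matrix must be square")
            # rank-1 consistency matrix: column j is v / v_j
            v = arr[:, 0]
            n = arr.shape[0]
        elif arr.ndim == 1:
            v = arr
            n = arr.size
        else:
            raise ValueError("expected a vector or a square matrix")
    norm = float(np.linalg.norm(v))
    if norm == 0:
        raise DegenerateDataError("zero generating vector; eigenvector undefined")
    x = v / norm
    if float(x @ v) < 0:
        x = -x
    return float(n), x


@dataclass(frozen=True)
class WeightTable:
    """Per-parameter eigenvector entries and final trait weights.

    ``eigen_entries`` is traits x parameters with unit-Euclidean-norm
    columns; ``final_weight`` is its row sum.
    """

    eigen_entries: pd.DataFrame
    final_weight: pd.Series

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.eigen_entries.index)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.eigen_entries.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.eigen_entries.copy()
        out["final_weight"] = self.final_weight
        out.index.name = "trait"
        return out


def _unit_column(values: np.ndarray, label: str) -> np.ndarray:
    norm = float(np.linalg.norm(values))
    if norm == 0:
        raise DegenerateDataError(f"column {label!r} is identically zero")
    return values / norm


def trait_weights(
    parameter_table: pd.DataFrame,
    directions: Mapping[str, str] | None = None,
    standardize: bool = False,
) -> WeightTable:
    """Combine per-parameter eigenvectors into final trait weights.

    Parameters
    ----------
    parameter_table
        Traits (rows) x genetic parameters (columns) of measured values.
    directions
        Optional map parameter -> ``"lower_better"``/``"higher_better"``;
        lower-better columns are reflected about their maximum before the
        eigenvector step.  Default: all higher-better.
    standardize
        If True, z-score each column (ddof=1) before normalization.  Off by
        default: the unit-norm eigenvector step already removes scale, and
        centering changes the entry pattern.
    """
    directions = dict(directions or {})
    cols = {}
    for param in parameter_table.columns:
        vals = parameter_table[param].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"parameter column {param!r} contains NaN")
        if directions.get(param, "higher_better") == "lower_better":
            vals = transform_lower_better(vals)
        if standardize:
            sd = vals.std(ddof=1)
            if sd == 0:
                raise DegenerateDataError(f"column {param!r} is constant")
            vals = (vals - vals.mean()) / sd
        cols[param] = _unit_column(vals, param)
    entries = pd.DataFrame(cols, index=parameter_table.index)
    return WeightTable(eigen_entries=entries, final_weight=entries.sum(axis=1))


@dataclass(frozen=True)
class ScoreTable:
    """Per-family eigenvector entries, final scores and selection flags."""

    eigen_entries: pd.DataFrame
    score: pd.Series
    selected: pd.Series | None = None

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self.eigen_entries.index)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score": self.score})
        if self.selected is not None:
            out["selected"] = self.selected
        out.index.name = "family"
        return out


def family_scores(
    trait_matrix: pd.DataFrame,
    weights: WeightTable | pd.Series,
    trait_meta: Sequence[TraitMeta] | Mapping[str, str] | None = None,
) -> ScoreTable:
    """Score families as the weight-combined trait eigenvectors.

    ``trait_matrix`` is families x traits of (condition-averaged) family
    means; its columns must match the weight traits exactly and in order.
    ``trait_meta`` supplies per-trait directions (lower-better traits are
    reflected before the eigenvector step).
    """
    w = weights.final_weight if isinstance(weights, WeightTable) else weights
    if list(trait_matrix.columns) != list(w.index):
        raise AlignmentError(
            "trait matrix columns do not align with weight traits: "
            f"{list(trait_matrix.columns)} vs {list(w.index)}"
        )
    if isinstance(trait_meta, Mapping):
        directions = dict(trait_meta)
    elif trait_meta is not None:
        directions = {m.name: m.direction for m in trait_meta}
    else:
        directions = {}

    cols = {}
    for trait in trait_matrix.columns:
        vals = trait_matrix[trait].to_numpy(dtype=float)
        if directions.get(trait, "higher_better") == "lower_better":
            vals = transform_lower_better(vals)
        cols[trait] = _unit_column(vals, trait)
    entries = pd.DataFrame(cols, index=trait_matrix.index)
    score = entries @ w
    return ScoreTable(eigen_entries=entries, score=score)


def select_top(
    scores: ScoreTable | pd.Series,
    fraction: float | None = None,
    count: int | None = None,
) -> pd.DataFrame:
    """Rank families by score (descending) and flag the top set.

    Exactly one of ``fraction``/``count`` must be given; with a fraction,
    ``count = ceil(fraction * n_families)``.  Ties keep input order
    (stable sort), so the earlier-listed family ranks higher.

    Returns a DataFrame with columns ``family, score, rank, selected``
    sorted by rank.
    """
    s = scores.score if isinstance(scores, ScoreTable) else scores
    n = len(s)
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1] (got {fraction})")
        count = math.ceil(fraction * n)
    if not 1 <= count <= n:
        raise ValueError(f"count must be in [1, {n}] (got {count})")

    order = np.argsort(-s.to_numpy(), kind="stable")
    out = pd.DataFrame(
        {
            "family": np.asarray(s.index)[order],
            "score": s.to_numpy()[order],
            "rank": np.arange(1, n + 1),
        }
    )
    out["selected"] = out["rank"] <= count
    return out
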