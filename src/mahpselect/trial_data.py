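"""Container, I/O and validation for balanced two-condition field trials.

A trial is a balanced randomized-complete-block experiment repeated under one
or two growing conditions (canonically ``"normal"`` and ``"stress"``): every
family (genotype entry) appears once per replicate block per condition, and
every measured trait is recorded for every plot.  The container keeps the
long-format observations together with the first-seen ordering of families,
replicates, conditions and traits, so that downstream eigenvector and weight
tables align positionally with the input.

Missing or duplicated cells are hard validation errors — the variance
component estimators assume an exactly balanced design and no imputation is
performed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import BalanceError, FormatError, ParseError

#: Canonical condition labels; a dataset holds one or both.
CONDITIONS = ("normal", "stress")

#: Required columns of the long interchange layout.
LONG_COLUMNS = ("family", "replicate", "condition", "trait", "value")

#: Identifier columns of the wide layout (remaining columns are traits).
WIDE_ID_COLUMNS = ("family", "replicate", "condition")


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata used by weighting and scoring.

    direction
        ``"higher_better"`` for traits improved by larger values,
        ``"lower_better"`` for traits (e.g. phenological earliness measures)
        where small values are desirable and the max-minus-value transform
        is applied before eigenvector extraction.
    role
        ``"dependent"`` marks a breeding-target trait (the correlation
        anchor for weighting); everything else is ``"independent"``.
    """

    name: str
    direction: str = "higher_better"
    role: str = "independent"
    unit: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise FormatError(f"unknown trait direction {self.direction!r}")
        if self.role not in ("dependent", "independent"):
            raise FormatError(f"unknown trait role {self.role!r}")


def _ordered_unique(values: Iterable[str]) -> tuple[str, ...]:
    return tuple(dict.fromkeys(values))


class TrialDataset:
    """Balanced family x replicate x condition x trait observations.

    Parameters
    ----------
    frame
        Long-format table with columns ``family, replicate, condition,
        trait, value``.  Identifier columns are coerced to ``str``, values
        to ``float``.  Ordering of identifiers is preserved as first seen.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"long table is missing column(s): {', '.join(missing)}")
        frame = frame.loc[:, list(LONG_COLUMNS)].copy()
        for col in ("family", "replicate", "condition", "trait"):
            frame[col] = frame[col].astype(str)
        values = pd.to_numeric(frame["value"], errors="coerce")
        bad = values.isna() & frame["value"].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {frame.loc[row, 'value']!r} at row {row}"
            )
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise ParseError(f"missing value at row {row}")
        frame["value"] = values.astype(float)

        self._frame = frame.reset_index(drop=True)
        self._families = _ordered_unique(frame["family"])
        self._replicates = _ordered_unique(frame["replicate"])
        self._conditions = _ordered_unique(frame["condition"])
        self._traits = _ordered_unique(frame["trait"])
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        unknown = [c for c in self._conditions if c not in CONDITIONS]
        if unknown:
            raise FormatError(
                f"unknown condition label(s) {unknown}; expected subset of {CONDITIONS}"
            )
        if not 1 <= len(self._conditions) <= 2:
            raise FormatError("dataset must hold exactly 1 or 2 conditions")

        keys = self._frame[["family", "replicate", "condition", "trait"]]
        dup = keys.duplicated()
        if dup.any():
            cells = keys[dup].apply(tuple, axis=1).tolist()[:10]
            raise BalanceError(f"duplicated cell(s): {cells}")

        expected = set(
            itertools.product(
                self._families, self._replicates, self._conditions, self._traits
            )
        )
        present = set(keys.apply(tuple, axis=1))
        missing = sorted(expected - present)
        if missing:
            shown = missing[:10]
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise BalanceError(f"missing cell(s): {shown}{more}")

    # -- basic accessors -----------------------------------------------

    @property
    def families(self) -> tuple[str, ...]:
        return self._families

    @property
    def replicates(self) -> tuple[str, ...]:
        return self._replicates

    @property
    def conditions(self) -> tuple[str, ...]:
        return self._conditions

    @property
    def traits(self) -> tuple[str, ...]:
        return self._traits

    @property
    def n_families(self) -> int:
        return len(self._families)

    @property
    def n_replicates(self) -> int:
        return len(self._replicates)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        if (
            self._families != other._families
            or self._replicates != other._replicates
            or self._conditions != other._conditions
            or self._traits != other._traits
        ):
            return False
        a = self._sorted_frame()
        b = other._sorted_frame()
        return a["value"].to_numpy().tolist() == b["value"].to_numpy().tolist()

    def _sorted_frame(self) -> pd.DataFrame:
        return self._frame.sort_values(
            ["family", "replicate", "condition", "trait"], kind="stable"
        ).reset_index(drop=True)

    # -- views ----------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        """Return a copy of the long-format observation table."""
        return self._frame.copy()

    def values(self, trait: str, condition: str) -> pd.DataFrame:
        """Families x replicates matrix of raw plot values for one trait."""
        self._check_condition(condition)
        if trait not in self._traits:
            raise KeyError(f"unknown trait {trait!r}")
        sub = self._frame[
            (self._frame["trait"] == trait) & (self._frame["condition"] == condition)
        ]
        mat = sub.pivot(index="family", columns="replicate", values="value")
        return mat.reindex(index=list(self._families), columns=list(self._replicates))

    def family_means(self, condition: str) -> pd.DataFrame:
        """Families x traits matrix of replicate means for one condition."""
        self._check_condition(condition)
        sub = self._frame[self._frame["condition"] == condition]
        mat = sub.pivot_table(
            index="family", columns="trait", values="value", aggfunc="mean"
        )
        return mat.reindex(index=list(self._families), columns=list(self._traits))

    def condition_average(self) -> pd.DataFrame:
        """Elementwise mean of the two per-condition family-mean matrices."""
        if len(self._conditions) != 2:
            raise BalanceError(
                "condition_average requires a two-condition dataset; "
                f"got {self._conditions}"
            )
        a, b = self._conditions
        return (self.family_means(a) + self.family_means(b)) / 2.0

    def _check_condition(self, condition: str) -> None:
        if condition not in self._conditions:
            raise KeyError(
                f"condition {condition!r} not in dataset (has {self._conditions})"
            )

    # -- I/O -------------------------------------------------------------

    def write(self, path) -> None:
        """Write the long-layout CSV (round-trips exactly through reads)."""
        # %.17g round-trips every float64 exactly
        self._frame.to_csv(path, index=False, float_format="%.17g")


def _wide_to_long(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WIDE_ID_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"wide table is missing column(s): {', '.join(missing)}")
    traits = [c for c in frame.columns if c not in WIDE_ID_COLUMNS]
    if not traits:
        raise FormatError("wide table has no trait columns")
    long = frame.melt(
        id_vars=list(WIDE_ID_COLUMNS),
        value_vars=traits,
        var_name="trait",
        value_name="value",
    )
    # melt stacks trait blocks; restore row-major first-seen order so trait
    # order matches column order but family order matches row order
    return long


def read_trial_table(
    path,
    layout: str = "long",
    condition_aliases: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read a trial CSV in ``long`` or ``wide`` layout.

    ``condition_aliases`` maps raw condition labels in the file to the
    canonical ``"normal"``/``"stress"`` pair (e.g. ``{"irrigated": "normal",
    "drought": "stress"}``).
    """
    if layout not in ("long", "wide"):
        raise FormatError(f"unknown layout {layout!r}; expected 'long' or 'wide'")
    frame = pd.read_csv(
        path, dtype={"family": str, "replicate": str}, float_precision="round_trip"
    )
    if layout == "wide":
        frame = _wide_to_long(frame)
    if condition_aliases:
        frame["condition"] = (
            frame["condition"].astype(str).map(lambda c: condition_aliases.get(c, c))
        )
    return TrialDataset(frame)
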