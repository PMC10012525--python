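"""RCBD ANOVA, variance components, heritability, genetic advance and
genetic correlations for balanced family trials.

The decomposition is the classical two-way randomized-complete-block
analysis without interaction: for ``g`` families and ``r`` replicate
blocks,

    SS(total) = SS(replication) + SS(families) + SS(error)

with degrees of freedom ``r-1``, ``g-1`` and ``(r-1)(g-1)``.  Because the
design is balanced the sums of squares have closed forms, which are used
directly (and cross-checked against a general linear-model fit in the test
suite).

Genetic parameters follow the family-mean convention:

    sigma2_g = (MSf - MSe) / r          genetic variance of family means
    sigma2_e = MSe / r                  error variance of a family mean
    sigma2_p = sigma2_g + sigma2_e      phenotypic variance of a family mean
    h2_raw   = sigma2_g / sigma2_p  ==  1 - MSe/MSf

``h2_raw`` may be negative when families vary less than error predicts; the
clamped ``h2 = max(h2_raw, 0)`` is used for reporting and genetic advance,
while the raw value is propagated to the heritability-stability ratio (see
:mod:`mahpselect.stability`), which needs its sign.

Genetic covariance between two traits uses the analogous mean cross
products of the analysis of covariance:

    cov_g = (MCPf - MCPe) / r
    r_g   = cov_g / sqrt(sigma2_g(X) * sigma2_g(Y))

``r_g`` can exceed 1 in magnitude (an estimation artifact); a capped copy
clipped to [-1, 1] is provided for reporting while the uncapped value feeds
the weighting step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, UndefinedStatisticError
from .trial_data import TrialDataset

#: Standardized selection differential for 5% truncation of a normal trait.
DEFAULT_SELECTION_INTENSITY = 2.063


@dataclass(frozen=True)
class AnovaTable:
    """Balanced RCBD decomposition for one trait in one condition."""

    trait: str
    condition: str
    n_families: int
    n_replicates: int
    grand_mean: float
    df_replication: int
    df_families: int
    df_error: int
    ss_replication: float
    ss_families: float
    ss_error: float
    ms_replication: float
    ms_families: float
    ms_error: float
    f_replication: float
    f_families: float
    p_replication: float
    p_families: float

    @property
    def df_total(self) -> int:
        return self.df_replication + self.df_families + self.df_error

    @property
    def ss_total(self) -> float:
        return self.ss_replication + self.ss_families + self.ss_error

    def significance(self, source: str = "families") -> str:
        """Footnote-style flag: 'b' at 1%, 'a' at 5%, '' otherwise."""
        p = self.p_families if source == "families" else self.p_replication
        if np.isnan(p):
            return ""
        if p < 0.01:
            return "b"
        if p < 0.05:
            return "a"
        return ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("replication", self.df_replication, self.ss_replication,
             self.ms_replication, self.f_replication, self.p_replication),
            ("families", self.df_families, self.ss_families,
             self.ms_families, self.f_families, self.p_families),
            ("error", self.df_error, self.ss_error, self.ms_error,
             np.nan, np.nan),
        ]
        out = pd.DataFrame(rows, columns=["source", "df", "SS", "MS", "F", "p"])
        out.insert(0, "condition", self.condition)
        out.insert(0, "trait", self.trait)
        return out


@dataclass(frozen=True)
class GeneticParams:
    """Variance components and derived genetic parameters for one trait."""

    trait: str
    condition: str
    n_replicates: int
    grand_mean: float
    sigma2_g: float
    sigma2_e: float
    sigma2_p: float
    h2_raw: float
    h2: float
    significant_05: bool
    significant_01: bool
    ega: float = field(default=float("nan"))
    ega_pct: float = field(default=float("nan"))


def rcbd_anova(ds: TrialDataset, trait: str, condition: str) -> AnovaTable:
    """Two-way balanced RCBD ANOVA (replication + families + error)."""
    mat = ds.values(trait, condition).to_numpy()
    g, r = mat.shape
    if g < 2 or r < 2:
        raise DegenerateDataError(
            f"need >= 2 families and >= 2 replicates (got g={g}, r={r})"
        )
    grand = mat.mean()
    fam_means = mat.mean(axis=1)
    rep_means = mat.mean(axis=0)
    ss_fam = r * float(((fam_means - grand) ** 2).sum())
    ss_rep = g * float(((rep_means - grand) ** 2).sum())
    ss_tot = float(((mat - grand) ** 2).sum())
    ss_err = max(ss_tot - ss_fam - ss_rep, 0.0)

    df_rep, df_fam = r - 1, g - 1
    df_err = (r - 1) * (g - 1)
    ms_rep, ms_fam, ms_err = ss_rep / df_rep, ss_fam / df_fam, ss_err / df_err

    def f_and_p(ms: float, df: int) -> tuple[float, float]:
        if ms_err > 0:
            f = ms / ms_err
            return f, float(stats.f.sf(f, df, df_err))
        if ms > 0:
            return math.inf, 0.0
        return math.nan, math.nan

    f_rep, p_rep = f_and_p(ms_rep, df_rep)
    f_fam, p_fam = f_and_p(ms_fam, df_fam)

    return AnovaTable(
        trait=trait, condition=condition, n_families=g, n_replicates=r,
        grand_mean=float(grand),
        df_replication=df_rep, df_families=df_fam, df_error=df_err,
        ss_replication=ss_rep, ss_families=ss_fam, ss_error=ss_err,
        ms_replication=ms_rep, ms_families=ms_fam, ms_error=ms_err,
        f_replication=f_rep, f_families=f_fam,
        p_replication=p_rep, p_families=p_fam,
    )


def variance_components(anova: AnovaTable) -> GeneticParams:
    """Family-mean variance components and broad-sense heritability."""
    r = anova.n_replicates
    msf, mse = anova.ms_families, anova.ms_error
    sigma2_g = (msf - mse) / r
    sigma2_e = mse / r
    sigma2_p = sigma2_g + sigma2_e  # == msf / r
    if msf == 0:
        warnings.warn(
            f"{anova.trait}/{anova.condition}: zero families mean square; "
            "heritability set to 0",
            stacklevel=2,
        )
        h2_raw = 0.0
    else:
        h2_raw = sigma2_g / sigma2_p
    h2 = min(max(h2_raw, 0.0), 1.0)
    return GeneticParams(
        trait=anova.trait, condition=anova.condition, n_replicates=r,
        grand_mean=anova.grand_mean,
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, sigma2_p=sigma2_p,
        h2_raw=h2_raw, h2=h2,
        significant_05=(not np.isnan(anova.p_families)) and anova.p_families < 0.05,
        significant_01=(not np.isnan(anova.p_families)) and anova.p_families < 0.01,
    )


def heritability_from_mean_squares(ms_families: float, ms_error: float) -> float:
    """Raw family-mean-basis h2 = 1 - MSe/MSf directly from mean squares.

    Convenience for working from published ANOVA tables; may be negative.
    """
    if ms_families == 0:
        raise DegenerateDataError("zero families mean square")
    return 1.0 - ms_error / ms_families


def expected_genetic_advance(
    params: GeneticParams, k: float = DEFAULT_SELECTION_INTENSITY
) -> tuple[float, float]:
    """Expected genetic advance ``k * h2 * sqrt(sigma2_p)`` and its value
    as a percentage of the grand mean.

    Uses the clamped heritability: non-heritable traits advance by 0.
    """
    if k <= 0:
        raise ValueError(f"selection intensity must be positive (got {k})")
    if params.grand_mean == 0:
        raise ZeroDivisionError("grand mean is zero; EGA% undefined")
    if params.h2 <= 0:
        return 0.0, 0.0
    ega = k * params.h2 * math.sqrt(max(params.sigma2_p, 0.0))
    return ega, 100.0 * ega / params.grand_mean


def genetic_params(
    ds: TrialDataset,
    trait: str,
    condition: str,
    k: float = DEFAULT_SELECTION_INTENSITY,
) -> tuple[AnovaTable, GeneticParams]:
    """ANOVA plus fully populated genetic parameters for one trait."""
    anova = rcbd_anova(ds, trait, condition)
    params = variance_components(anova)
    ega, ega_pct = expected_genetic_advance(params, k)
    return anova, replace(params, ega=ega, ega_pct=ega_pct)


@dataclass(frozen=True)
class GeneticCovariance:
    """Genetic covariance and correlation between two traits."""

    trait_x: str
    trait_y: str
    condition: str
    cov_g: float
    r_g: float

    @property
    def r_g_capped(self) -> float:
        return float(np.clip(self.r_g, -1.0, 1.0))


def genetic_correlation(
    ds: TrialDataset, trait_x: str, trait_y: str, condition: str
) -> GeneticCovariance:
    """Genetic covariance/correlation from RCBD mean cross products.

    ``cov_g = (MCPf - MCPe)/r``; ``r_g`` divides by the geometric mean of
    the raw genetic variances.  The raw variances may be negative; the
    denominator uses the magnitude of their product (the sign of r_g is
    then carried by the covariance alone).  Self-correlation is exactly 1.
    """
    sg_x = variance_components(rcbd_anova(ds, trait_x, condition)).sigma2_g
    if sg_x == 0:
        raise UndefinedStatisticError(
            f"zero genetic variance for {trait_x!r}; r_g undefined"
        )
    if trait_x == trait_y:
        return GeneticCovariance(trait_x, trait_y, condition, sg_x, 1.0)
    sg_y = variance_components(rcbd_anova(ds, trait_y, condition)).sigma2_g
    if sg_y == 0:
        raise UndefinedStatisticError(
            f"zero genetic variance for {trait_y!r}; r_g undefined"
        )

    x = ds.values(trait_x, condition).to_numpy()
    y = ds.values(trait_y, condition).to_numpy()
    g, r = x.shape
    gx, gy = x.mean(), y.mean()
    fx, fy = x.mean(axis=1), y.mean(axis=1)
    rx, ry = x.mean(axis=0), y.mean(axis=0)
    cp_fam = r * float(((fx - gx) * (fy - gy)).sum())
    resid_x = x - fx[:, None] - rx[None, :] + gx
    resid_y = y - fy[:, None] - ry[None, :] + gy
    cp_err = float((resid_x * resid_y).sum())
    mcp_f = cp_fam / (g - 1)
    mcp_e = cp_err / ((g - 1) * (r - 1))
    cov_g = (mcp_f - mcp_e) / r
    r_g = cov_g / math.sqrt(abs(sg_x * sg_y))
    return GeneticCovariance(trait_x, trait_y, condition, cov_g, r_g)


@dataclass(frozen=True)
class GeneticCorrelationMatrix:
    """All-pairs genetic correlations for one condition.

    Entries are NaN where either trait has zero genetic variance.
    """

    condition: str
    uncapped: pd.DataFrame
    cov_g: pd.DataFrame

    @property
    def capped(self) -> pd.DataFrame:
        return self.uncapped.clip(-1.0, 1.0)


def genetic_correlation_matrix(
    ds: TrialDataset, condition: str
) -> GeneticCorrelationMatrix:
    traits = list(ds.traits)
    n = len(traits)
    rg = np.full((n, n), np.nan)
    cov = np.full((n, n), np.nan)
    for i, tx in enumerate(traits):
        for j, ty in enumerate(traits[i:], start=i):
            try:
                gc = genetic_correlation(ds, tx, ty, condition)
            except UndefinedStatisticError:
                continue
            rg[i, j] = rg[j, i] = gc.r_g
            cov[i, j] = cov[j, i] = gc.cov_g
    return GeneticCorrelationMatrix(
        condition=condition,
        uncapped=pd.DataFrame(rg, index=traits, columns=traits),
        cov_g=pd.DataFrame(cov, index=traits, columns=traits),
    )
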