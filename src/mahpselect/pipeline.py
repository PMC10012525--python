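"""End-to-end orchestration: trait filtering, genetic parameters,
stability, weighting, scoring and selection for a two-condition trial.

Stage order (fully deterministic for fixed input and configuration):

1.  Per-condition RCBD ANOVA and variance components for every trait.
2.  Trait filter — a trait is dropped iff its family effect is
    non-significant in BOTH conditions, or its clamped heritability is 0
    in both; every exclusion is logged with its reason.
3.  Genetic correlations of each retained trait with the dependent
    (breeding-target) traits, per condition; the uncapped values feed
    weighting, the capped values are reported.
4.  Stability statistics (SI across the condition pair; SIBH from the
    unclamped heritabilities).  A trait whose SIBH is undefined stays in
    the analysis but contributes 0 to the SIBH parameter column (logged).
5.  Trait weighting from the parameter table (stability indices,
    correlations, expected genetic advance per condition).
6.  Family scoring on condition-averaged family means and top-set
    selection.

Outputs are tidy CSV tables plus a human-readable Markdown report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .exceptions import ConfigError, DegenerateDataError, UndefinedStatisticError
from .genetics import (DEFAULT_SELECTION_INTENSITY, AnovaTable, GeneticParams,
                       genetic_correlation, genetic_params)
from .mahp import ScoreTable, WeightTable, family_scores, select_top, trait_weights
from .stability import StabilityParams, sibh, stability_index
from .trial_data import TrialDataset

logger = logging.getLogger("mahpselect.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full selection pipeline.

    ``reproduction_mode`` keeps the stability-index parameter column
    untransformed (the convention the bundled case-study weight table
    follows); the default treats SI as lower-better and reflects it about
    its maximum before the eigenvector step, as a fresh analysis should.
    """

    dependent_traits: tuple[str, ...] = ("Yld", "TSS")
    trait_directions: Mapping[str, str] = field(default_factory=dict)
    parameter_directions: Mapping[str, str] | None = None
    selection_intensity: float = DEFAULT_SELECTION_INTENSITY
    selection_fraction: float | None = 0.1
    selection_count: int | None = None
    significance_threshold: float = 0.05
    reproduction_mode: bool = False
    standardize: bool = False
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.significance_threshold < 1:
            raise ConfigError("significance threshold must be in (0, 1)")
        if self.selection_fraction is not None and self.selection_count is not None:
            raise ConfigError("give selection_fraction or selection_count, not both")
        if self.selection_fraction is None and self.selection_count is None:
            raise ConfigError("one of selection_fraction/selection_count is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "dependent_traits" in raw:
            raw["dependent_traits"] = tuple(raw["dependent_traits"])
        return cls(**raw)


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline computed, plus the audit trail."""

    anova_tables: dict
    params: dict
    correlations: pd.DataFrame
    correlations_capped: pd.DataFrame
    stability: list[StabilityParams]
    retained_traits: tuple[str, ...]
    exclusions: tuple[tuple[str, str], ...]
    parameter_table: pd.DataFrame
    weight_table: WeightTable
    score_table: ScoreTable
    selection: pd.DataFrame
    report: str


def filter_traits(
    anova_tables: Mapping[tuple[str, str], AnovaTable],
    params: Mapping[tuple[str, str], GeneticParams],
    threshold: float = 0.05,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop traits with no usable genetic signal in either condition.

    A trait is excluded iff its family effect is non-significant at
    ``threshold`` in both conditions OR its clamped heritability is zero
    in both.  Returns ``(retained, exclusions)`` where each exclusion is
    ``(trait, reason)``; the two lists partition the input traits.
    """
    traits = list(dict.fromkeys(t for (t, _c) in anova_tables))
    conditions = list(dict.fromkeys(c for (_t, c) in anova_tables))
    retained, excluded = [], []
    for trait in traits:
        ps = [anova_tables[(trait, c)].p_families for c in conditions]
        h2s = [params[(trait, c)].h2 for c in conditions]
        if all(p >= threshold for p in ps):
            excluded.append(
                (trait, "family effect non-significant in all conditions "
                        f"(p = {', '.join(f'{p:.3g}' for p in ps)})")
            )
        elif all(h == 0 for h in h2s):
            excluded.append((trait, "clamped heritability 0 in all conditions"))
        else:
            retained.append(trait)
    if not retained:
        raise DegenerateDataError("trait filter removed every trait")
    for trait, reason in excluded:
        logger.info("filter_traits: excluded %s (%s)", trait, reason)
    return retained, excluded


def _parameter_columns(dependents: tuple[str, ...]) -> list[str]:
    cols = ["SI", "SIBH"]
    cols += [f"r_g_{d}-N" for d in dependents]
    cols += [f"r_g_{d}-S" for d in dependents]
    cols += ["EGA-N", "EGA-S"]
    return cols


def run_pipeline(ds: TrialDataset, config: PipelineConfig) -> PipelineResult:
    """Run the full selection pipeline on a validated two-condition trial."""
    if len(ds.conditions) != 2:
        raise DegenerateDataError(
            f"pipeline requires two conditions, dataset has {ds.conditions}"
        )
    normal, stress = "normal", "stress"
    missing_dep = [t for t in config.dependent_traits if t not in ds.traits]
    if missing_dep:
        raise ConfigError(f"dependent trait(s) not in dataset: {missing_dep}")

    # 1. genetics per trait per condition
    anovas: dict[tuple[str, str], AnovaTable] = {}
    params: dict[tuple[str, str], GeneticParams] = {}
    for trait in ds.traits:
        for cond in ds.conditions:
            a, p = genetic_params(ds, trait, cond, k=config.selection_intensity)
            anovas[(trait, cond)] = a
            params[(trait, cond)] = p
    logger.info("anova: %d traits x %d conditions", len(ds.traits), len(ds.conditions))

    # 2. filter
    retained, exclusions = filter_traits(
        anovas, params, config.significance_threshold
    )

    # 3. correlations with dependent traits
    rg_rows = []
    for trait in retained:
        for dep in config.dependent_traits:
            for cond, tag in ((normal, "N"), (stress, "S")):
                try:
                    gc = genetic_correlation(ds, trait, dep, cond)
                    rg, rg_cap = gc.r_g, gc.r_g_capped
                except UndefinedStatisticError as err:
                    logger.info("r_g(%s, %s, %s) undefined: %s; using 0",
                                trait, dep, cond, err)
                    rg, rg_cap = 0.0, 0.0
                rg_rows.append((trait, dep, cond, f"r_g_{dep}-{tag}", rg, rg_cap))
    rg_long = pd.DataFrame(
        rg_rows, columns=["trait", "dependent", "condition", "parameter",
                          "r_g", "r_g_capped"],
    )
    rg_wide = rg_long.pivot(index="trait", columns="parameter", values="r_g")
    rg_wide = rg_wide.reindex(index=retained)
    rg_wide_cap = rg_long.pivot(index="trait", columns="parameter",
                                values="r_g_capped").reindex(index=retained)

    # 4. stability
    mn, ms_ = ds.family_means(normal), ds.family_means(stress)
    stability: list[StabilityParams] = []
    for trait in retained:
        si, slope = stability_index(mn[trait].to_numpy(), ms_[trait].to_numpy())
        try:
            s, raw = sibh(params[(trait, normal)].h2_raw,
                          params[(trait, stress)].h2_raw)
        except UndefinedStatisticError:
            logger.info("SIBH undefined for %s; contributes 0", trait)
            s, raw = 0.0, 0.0
        stability.append(StabilityParams(trait, si, slope, s, raw))

    # 5. parameter table and trait weights
    cols = _parameter_columns(config.dependent_traits)
    ptab = pd.DataFrame(index=pd.Index(retained, name="trait"), columns=cols,
                        dtype=float)
    for sp in stability:
        ptab.loc[sp.trait, "SI"] = sp.si
        ptab.loc[sp.trait, "SIBH"] = sp.sibh
    for col in rg_wide.columns:
        ptab.loc[:, col] = rg_wide[col]
    for trait in retained:
        ptab.loc[trait, "EGA-N"] = params[(trait, normal)].ega_pct
        ptab.loc[trait, "EGA-S"] = params[(trait, stress)].ega_pct

    if config.parameter_directions is not None:
        pdirs = dict(config.parameter_directions)
    elif config.reproduction_mode:
        pdirs = {}  # SI column left untransformed, as in the case study
    else:
        pdirs = {"SI": "lower_better"}
    weights = trait_weights(ptab, directions=pdirs, standardize=config.standardize)

    # 6. scoring and selection
    trait_matrix = ds.condition_average().loc[:, retained]
    scores = family_scores(trait_matrix, weights, dict(config.trait_directions))
    selection = select_top(scores, fraction=config.selection_fraction,
                           count=config.selection_count)
    n_sel = int(selection["selected"].sum())
    scores = replace(
        scores,
        selected=selection.set_index("family")["selected"].reindex(
            scores.score.index
        ),
    )

    report = _render_report(ds, config, retained, exclusions, weights,
                            selection, n_sel)
    result = PipelineResult(
        anova_tables=anovas, params=params,
        correlations=rg_wide, correlations_capped=rg_wide_cap,
        stability=stability,
        retained_traits=tuple(retained), exclusions=tuple(exclusions),
        parameter_table=ptab, weight_table=weights,
        score_table=scores, selection=selection, report=report,
    )
    if config.outdir:
        write_outputs(result, config.outdir)
    return result


def _render_report(ds, config, retained, exclusions, weights, selection,
                   n_sel) -> str:
    top = selection[selection["selected"]]
    lines = [
        "# Selection pipeline report",
        "",
        f"- Families: {ds.n_families}; replicates: {ds.n_replicates}; "
        f"conditions: {', '.join(ds.conditions)}",
        f"- Traits measured: {len(ds.traits)}; retained after filter: "
        f"{len(retained)}; excluded: {len(exclusions)}",
        f"- Dependent traits: {', '.join(config.dependent_traits)}",
        f"- Selection: {n_sel} of {ds.n_families} families",
        "",
        "## Excluded traits",
        "",
    ]
    if exclusions:
        lines += [f"- {t}: {reason}" for t, reason in exclusions]
    else:
        lines.append("- none")
    ranked = weights.final_weight.sort_values(ascending=False)
    lines += [
        "",
        "## Top traits by final weight",
        "",
    ]
    lines += [f"- {t}: {w:.3f}" for t, w in ranked.head(5).items()]
    lines += [
        "",
        "## Selected families",
        "",
    ]
    lines += [
        f"- rank {int(r['rank'])}: family {r['family']} (score {r['score']:.3f})"
        for _, r in top.iterrows()
    ]
    return "\n".join(lines) + "\n"


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write all stage outputs as CSV plus the Markdown report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    anova = pd.concat([a.to_frame() for a in result.anova_tables.values()],
                      ignore_index=True)
    anova["sig"] = [
        result.anova_tables[(t, c)].significance()
        for t, c in zip(anova["trait"], anova["condition"])
    ]
    anova.to_csv(out / "anova.csv", index=False)

    pd.DataFrame([vars(p) for p in result.params.values()]).to_csv(
        out / "params.csv", index=False
    )

    rg = result.correlations.copy()
    rg.columns = [f"{c}_uncapped" for c in rg.columns]
    for c in result.correlations_capped.columns:
        rg[f"{c}_capped"] = result.correlations_capped[c]
    rg.to_csv(out / "rg.csv")

    pd.DataFrame([vars(s) for s in result.stability]).to_csv(
        out / "stability.csv", index=False
    )
    result.weight_table.to_frame().to_csv(out / "weights.csv")
    result.selection.to_csv(out / "scores.csv", index=False)
    (out / "report.md").write_text(result.report)
    logger.info("wrote outputs to %s", out)
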