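"""Scenario evaluation: one full pass of the estimation pipeline.

This is the unit of work that the replication module re-runs on modified
weights: fit the measurement-error model (per fortification variant),
simulate the pseudo-population, apply additive interventions, and
collect every requested statistic for every scenario and subgroup.
"""

from __future__ import annotations

import pandas as pd

from .adequacy import (
    RequirementDistribution,
    prevalence_cut_point,
    prevalence_full_probability,
)
from .config import AnalysisConfig, Scenario
from .intervention import (
    FixedAdditionSpec,
    SupplementProgramSpec,
    add_fixed_amounts,
    add_supplement_program,
    apply_fortification,
    split_interventions,
)
from .recall_model import RecallDataset, TransformSpec
from .usual_intake import distribution_summary, estimate_usual_intake

__all__ = ["run_scenarios", "flatten_statistics"]


def _transform_from_config(config: AnalysisConfig):
    if config.transform_lambda is None:
        return None
    return TransformSpec(lam=config.transform_lambda, offset=config.offset or 0.0)


def _scenario_list(config: AnalysisConfig) -> list[Scenario]:
    scenarios = [Scenario(name="food", interventions=[])]
    scenarios += [s for s in config.scenarios if s.name != "food"]
    return scenarios


def run_scenarios(dataset: RecallDataset, config: AnalysisConfig,
                  seed: int | None = None) -> pd.DataFrame:
    """Evaluate every scenario; returns rows indexed by (scenario, subgroup).

    The baseline scenario ``food`` (no interventions) is always first.
    Model fits are shared between scenarios with the same fortification
    stack, since additive interventions do not touch the recall records.
    """
    seed = config.seed if seed is None else seed
    transform = _transform_from_config(config)
    fit_cache: dict = {}
    blocks = []
    for scenario in _scenario_list(config):
        pre, post = split_interventions(scenario.interventions)
        key = tuple(pre)
        if key not in fit_cache:
            ds = dataset
            for spec in pre:
                ds = apply_fortification(ds, spec)
            _, pseudo, model = estimate_usual_intake(
                ds, covariates=config.covariates, transform=transform,
                lambda_grid=config.lambda_grid,
                zero_share_threshold=config.zero_share_threshold,
                one_day_ratio=config.one_day_ratio,
                m=config.m, n_nodes=config.n_nodes, seed=seed,
                return_parts=True)
            fit_cache[key] = pseudo
        pseudo = fit_cache[key]
        for spec in post:
            if isinstance(spec, SupplementProgramSpec):
                pseudo = add_supplement_program(pseudo, spec, seed=seed)
            elif isinstance(spec, FixedAdditionSpec):
                pseudo = add_fixed_amounts(pseudo, spec)
            else:
                raise TypeError(f"unsupported intervention {spec!r}")

        stats = distribution_summary(
            pseudo, percentiles=config.percentiles,
            cutoffs_below=config.cutoffs_below, cutoffs_above=config.cutoffs_above,
            subgroup_by=config.subgroup_by)
        if config.reference_table is not None:
            adeq = prevalence_cut_point(
                pseudo, config.reference_table, sex_col=config.sex_col,
                age_col=config.age_col, status_col=config.status_col,
                subgroup_by=config.subgroup_by)
            stats = stats.join(adeq[["pct_inadequate", "pct_excessive"]])
        if config.requirements is not None:
            fp = prevalence_full_probability(
                pseudo, config.requirements,
                group_by=config.requirement_group_by,
                subgroup_by=config.subgroup_by)
            stats = stats.join(fp[["pct_inadequate"]].rename(
                columns={"pct_inadequate": "pct_inadequate_fullprob"}))
        stats.insert(0, "scenario", scenario.name)
        blocks.append(stats.reset_index())
    out = pd.concat(blocks, ignore_index=True)
    return out.set_index(["scenario", "subgroup"])


def flatten_statistics(table: pd.DataFrame) -> dict[str, float]:
    """Flatten a scenario table to ``{"scenario|subgroup|stat": value}``.

    ``n`` (a design count, not an estimate) is excluded; this is the
    vector of statistics the replication machinery attaches SEs to.
    """
    flat: dict[str, float] = {}
    for (scenario, subgroup), row in table.iterrows():
        for stat, value in row.items():
            if stat in ("scenario", "n"):
                continue
            flat[f"{scenario}|{subgroup}|{stat}"] = float(value)
    return flat
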