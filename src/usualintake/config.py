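"""Analysis configuration: one structured object driving the whole pipeline.

A run is described by an :class:`AnalysisConfig` — nutrient/model options,
scenario list, adequacy references, and the replication design — loadable
from a YAML file so command-line runs are reproducible from a single
artifact plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .adequacy import DEFAULT_ABSORPTION, ReferenceTable, RequirementDistribution
from .errors import DataError
from .intervention import parse_intervention

__all__ = ["ReplicateDesign", "Scenario", "AnalysisConfig", "load_requirements_csv"]


@dataclass
class ReplicateDesign:
    """How replicate weights are produced for uncertainty estimation.

    ``method='brr'`` needs a two-PSU-per-stratum design (or pre-supplied
    ``repw_*`` columns); ``fay`` is the Fay down-weighting coefficient in
    [0, 1), default 0.3.  ``method='bootstrap'`` resamples persons with
    replacement within strata, default 200 replicates.
    """

    method: str = "brr"
    n_replicates: int | None = None
    fay: float = 0.3
    max_failure_rate: float = 0.10

    def __post_init__(self):
        if self.method not in ("brr", "bootstrap"):
            raise DataError(f"unknown replication method {self.method!r}")
        if not (0.0 <= self.fay < 1.0):
            raise DataError(f"Fay coefficient must be in [0, 1), got {self.fay}")
        if self.n_replicates is not None and self.n_replicates < 1:
            raise DataError("n_replicates must be >= 1")


@dataclass
class Scenario:
    """A named intervention stack evaluated as one output block.

    ``interventions`` may mix fortification (applied to recall records
    before fitting) and additive specs (applied to the simulated usual
    intakes); the stage split is structural, not positional.
    """

    name: str
    interventions: list = field(default_factory=list)


@dataclass
class AnalysisConfig:
    """Everything the pipeline needs besides the recall data and the seed."""

    covariates: list[str] = field(default_factory=list)
    subgroup_by: str | None = None
    # transform: fixed lambda wins over grid selection; offset None = policy
    transform_lambda: float | None = None
    lambda_grid: list | None = None
    offset: float | None = None
    zero_share_threshold: float = 0.05
    one_day_ratio: float | None = None
    # simulation
    m: int = 100
    n_nodes: int = 9
    seed: int = 0
    # summaries
    percentiles: tuple = (25, 50, 75)
    cutoffs_below: tuple = ()
    cutoffs_above: tuple = ()
    # adequacy
    reference_table: ReferenceTable | None = None
    sex_col: str = "sex"
    age_col: str = "age"
    status_col: str = "status"
    requirements: dict | RequirementDistribution | None = None
    requirement_group_by: str | None = None
    absorption: float = DEFAULT_ABSORPTION
    # scenarios (baseline "food" is always evaluated first)
    scenarios: list = field(default_factory=list)
    # uncertainty
    replication: ReplicateDesign | None = None

    def __post_init__(self):
        self.scenarios = [
            s if isinstance(s, Scenario)
            else Scenario(name=s["name"],
                          interventions=[parse_intervention(b) if isinstance(b, dict) else b
                                         for b in s.get("interventions", [])])
            for s in self.scenarios
        ]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "reference_table" in raw and isinstance(raw["reference_table"], str):
            raw["reference_table"] = ReferenceTable.from_csv(raw["reference_table"])
        if "requirements" in raw and isinstance(raw["requirements"], str):
            raw["requirements"] = load_requirements_csv(
                raw["requirements"], absorption=raw.get("absorption", DEFAULT_ABSORPTION))
        if "replication" in raw and isinstance(raw["replication"], dict):
            raw["replication"] = ReplicateDesign(**raw["replication"])
        for key in ("percentiles", "cutoffs_below", "cutoffs_above"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_requirements_csv(path, absorption: float = DEFAULT_ABSORPTION,
                          interpolation: str = "linear") -> dict:
    """Read tabulated requirement percentiles: columns group, p, q_absorbed.

    Returns a mapping group label -> :class:`RequirementDistribution`.
    """
    df = pd.read_csv(path)
    for col in ("group", "p", "q_absorbed"):
        if col not in df.columns:
            raise DataError(f"requirement CSV is missing column {col!r}",
                            hint="expected header: group,p,q_absorbed")
    out = {}
    for grp, g in df.groupby("group", sort=True):
        g = g.sort_values("p")
        out[grp] = RequirementDistribution(
            probs=g["p"].to_numpy(), quantiles=g["q_absorbed"].to_numpy(),
            absorption=absorption, interpolation=interpolation, group=str(grp))
    return out
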