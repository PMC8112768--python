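"""Fortification, supplementation-program, and fixed-addition scenarios.

Two structurally different ways of adding nutrients are enforced:

* **Add-then-shrink** (fortification): a fortified food changes what a
  24-h recall would measure, so the addition is applied to the *recall
  records* before the measurement-error model is fitted
  (``intake' = intake + vehicle_grams x level``).
* **Shrink-then-add** (supplement programs, breast milk, reported
  supplements): these sources have a longer temporal scope than a recall
  day, so their contribution is added to the *simulated usual intakes*
  after the model has removed day-to-day variation.

Applying a long-scope source to recall records (or vice versa) would
mis-attribute its variance, which is why the order is structural and not
configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .recall_model import RecallDataset, VEHICLE_PREFIX
from .usual_intake import PseudoPopulation

__all__ = [
    "FortificationSpec",
    "SupplementProgramSpec",
    "FixedAdditionSpec",
    "parse_intervention",
    "apply_fortification",
    "add_supplement_program",
    "add_fixed_amounts",
    "split_interventions",
]


@dataclass(frozen=True)
class FortificationSpec:
    """Fortify a vehicle food at ``level`` nutrient units per gram."""

    vehicle: str
    level: float  # nutrient units per gram of vehicle
    label: str = "fortification"
    kind: str = field(default="fortification", init=False)

    def __post_init__(self):
        if self.level < 0:
            raise DomainError(f"fortification level must be >= 0, got {self.level}")


@dataclass(frozen=True)
class SupplementProgramSpec:
    """Hypothetical program delivering ``dose`` units/day to a random
    ``coverage`` share of the eligible population.

    ``eligibility`` is a predicate over the pseudo-population frame
    (column name of a boolean flag, or a callable returning a mask);
    ``None`` means everyone is eligible.  Assignment is an independent
    seeded Bernoulli per pseudo-person, uncorrelated with food intake.
    """

    dose: float
    coverage: float
    eligibility: "str | Callable | None" = None
    label: str = "supplement_program"
    kind: str = field(default="supplement_program", init=False)

    def __post_init__(self):
        if self.dose < 0:
            raise DomainError(f"dose must be >= 0, got {self.dose}")
        if not (0.0 <= self.coverage <= 1.0):
            raise DomainError(f"coverage must be in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class FixedAdditionSpec:
    """Deterministic per-group or per-person additions (breast milk,
    reported supplement amounts).

    ``amounts`` maps values of ``key_column`` (e.g. ``stratum`` for
    group-level estimates, ``source_person_id`` for individual data) to
    nutrient units/day.  ``eligibility`` restricts who receives the
    addition (e.g. a ``breastfed`` flag column).
    """

    amounts: Mapping
    key_column: str = "stratum"
    eligibility: "str | Callable | None" = None
    label: str = "fixed_addition"
    kind: str = field(default="fixed_addition", init=False)

    def __post_init__(self):
        if any(v < 0 for v in self.amounts.values()):
            raise DomainError("fixed-addition amounts must be >= 0")


def parse_intervention(block: dict):
    """Build a spec from a config mapping ``{kind: ..., <parameters>}``."""
    block = dict(block)
    kind = block.pop("kind", None)
    if kind == "fortification":
        return FortificationSpec(**block)
    if kind == "supplement_program":
        return SupplementProgramSpec(**block)
    if kind == "fixed_addition":
        return FixedAdditionSpec(**block)
    raise DataError(
        f"unknown intervention kind {kind!r}",
        hint="expected one of: fortification, supplement_program, fixed_addition",
    )


def split_interventions(specs):
    """Partition a scenario list into pre-fit and post-simulation stages.

    Fortification is always applied to recall records before model
    fitting; additive interventions always act on the simulated usual
    intakes — regardless of their order in the list.
    """
    pre = [s for s in specs if isinstance(s, FortificationSpec)]
    post = [s for s in specs if not isinstance(s, FortificationSpec)]
    return pre, post


def _eligible_mask(frame: pd.DataFrame, eligibility) -> np.ndarray:
    if eligibility is None:
        return np.ones(len(frame), dtype=bool)
    if callable(eligibility):
        return np.asarray(eligibility(frame), dtype=bool)
    if eligibility not in frame.columns:
        raise DataError(f"eligibility column {eligibility!r} not found")
    return frame[eligibility].to_numpy(dtype=bool)


def apply_fortification(dataset: RecallDataset, spec: FortificationSpec) -> RecallDataset:
    """Return a new dataset with ``intake += vehicle_grams x level``.

    The input dataset is untouched; rows with zero vehicle consumption
    are unchanged, so the scenario affects consumers only.
    """
    col = spec.vehicle if spec.vehicle.startswith(VEHICLE_PREFIX) else VEHICLE_PREFIX + spec.vehicle
    if col not in dataset.recalls.columns:
        raise DataError(
            f"vehicle column {col!r} not found in the recall data",
            hint=f"available vehicles: {dataset.vehicle_columns or 'none'}",
        )
    recalls = dataset.recalls.copy()
    grams = recalls[col].to_numpy(dtype=float)
    if np.any(grams < 0):
        raise DataError(f"negative vehicle amounts in {col!r}")
    recalls["intake"] = recalls["intake"].to_numpy(dtype=float) + grams * spec.level
    return RecallDataset(recalls=recalls, persons=dataset.persons.copy())


def _spec_rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def add_supplement_program(pseudo: PseudoPopulation, spec: SupplementProgramSpec,
                           seed: int = 0) -> PseudoPopulation:
    """Seeded Bernoulli assignment of the program dose to eligible pseudo-persons.

    The RNG stream is derived from the root seed and the spec's label, so
    adding a second scenario to a run never perturbs the draws of the
    first.  Mean contribution among the eligible converges to
    dose x coverage.
    """
    eligible = _eligible_mask(pseudo.frame, spec.eligibility)
    rng = _spec_rng(seed, spec.label)
    takes = rng.random(len(pseudo.frame)) < spec.coverage
    extra = np.where(eligible & takes, spec.dose, 0.0)
    return pseudo.with_contribution(extra)


def add_fixed_amounts(pseudo: PseudoPopulation, spec: FixedAdditionSpec) -> PseudoPopulation:
    """Deterministically add mapped amounts to eligible pseudo-persons."""
    frame = pseudo.frame
    if spec.key_column not in frame.columns:
        raise DataError(f"key column {spec.key_column!r} not in the pseudo-population")
    eligible = _eligible_mask(frame, spec.eligibility)
    keys = frame[spec.key_column].to_numpy()
    extra = np.zeros(len(frame))
    unmapped = sorted({k for k in keys[eligible] if k not in spec.amounts})
    if unmapped:
        raise DataError(
            f"eligible pseudo-persons with unmapped {spec.key_column!r} value(s): "
            f"{unmapped[:10]}",
            hint="add the missing keys to the fixed-addition amounts map",
        )
    for k, v in spec.amounts.items():
        extra[eligible & (keys == k)] = v
    return pseudo.with_contribution(extra)
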