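"""Prevalence of inadequate and excessive intake.

Two estimators are provided:

* **EAR cut-point** — the weighted share of usual intakes below each
  person's age-/sex-/status-specific Estimated Average Requirement (and
  above the Tolerable Upper Intake Level for excess).  Valid when the
  requirement distribution is roughly symmetric and independent of
  intake.
* **Full probability** — the population-weighted average of each
  person's probability of inadequacy, ``P(requirement > absorbed
  intake)``, read off a tabulated requirement-percentile distribution.
  Required when requirements are skewed, the canonical case being iron
  in menstruating women; absorbed intake is ``absorption * intake`` with
  a default absorption fraction of 0.18 (the mixed-diet assumption used
  to set recommended iron intakes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, ReferenceLookupError
from .usual_intake import PseudoPopulation

__all__ = [
    "ReferenceTable",
    "RequirementDistribution",
    "prevalence_cut_point",
    "risk_of_inadequacy",
    "prevalence_full_probability",
    "DEFAULT_ABSORPTION",
]

DEFAULT_ABSORPTION = 0.18


@dataclass
class ReferenceTable:
    """EAR/UL reference values by sex, age interval, and physiological status.

    ``frame`` columns: sex, age_min, age_max, status, ear, ul (ul may be
    missing).  Age matching uses half-open intervals
    ``age_min < age <= age_max`` so a boundary age belongs to the younger
    group (age 50 matches a "<=50 y" row whose interval is (18, 50], and
    55 matches the ">50 y" row (50, 120]).
    """

    frame: pd.DataFrame

    REQUIRED = ("sex", "age_min", "age_max", "status", "ear")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise DataError(f"reference table is missing columns {missing}")
        if "ul" not in self.frame.columns:
            self.frame = self.frame.assign(ul=np.nan)
        both = self.frame.dropna(subset=["ul"])
        if (both["ear"] >= both["ul"]).any():
            raise DataError("reference table has rows with EAR >= UL")
        for (sex, status), grp in self.frame.groupby(["sex", "status"], dropna=False):
            g = grp.sort_values("age_min")
            if (g["age_max"].to_numpy()[:-1] > g["age_min"].to_numpy()[1:]).any():
                raise DataError(f"overlapping age intervals for sex={sex!r}, status={status!r}")

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))

    def lookup(self, sex, age, status) -> pd.Series:
        f = self.frame
        hit = f[(f["sex"] == sex) & (f["status"] == status)
                & (f["age_min"] < age) & (age <= f["age_max"])]
        if len(hit) != 1:
            raise ReferenceLookupError(
                f"no unique reference row for sex={sex!r}, age={age}, status={status!r}",
                hint="add a covering (sex, age interval, status) row to the reference CSV",
            )
        return hit.iloc[0]

    def assign(self, frame: pd.DataFrame, sex_col="sex", age_col="age",
               status_col="status") -> pd.DataFrame:
        """Vectorised EAR/UL per row of ``frame``; errors list unmatched combos."""
        ear = np.full(len(frame), np.nan)
        ul = np.full(len(frame), np.nan)
        status = frame[status_col] if status_col in frame.columns else pd.Series(
            ["none"] * len(frame), index=frame.index)
        unmatched = set()
        key = pd.DataFrame({"sex": frame[sex_col].to_numpy(),
                            "age": frame[age_col].to_numpy(dtype=float),
                            "status": status.to_numpy()})
        for (sex, st), grp in key.groupby(["sex", "status"], sort=False):
            rows = self.frame[(self.frame["sex"] == sex) & (self.frame["status"] == st)]
            ages = grp["age"].to_numpy()
            e = np.full(ages.size, np.nan)
            u = np.full(ages.size, np.nan)
            for _, r in rows.iterrows():
                m = (r["age_min"] < ages) & (ages <= r["age_max"])
                e[m] = r["ear"]
                u[m] = r["ul"]
            miss = np.isnan(e)
            if miss.any():
                unmatched.update((sex, float(a), st) for a in np.unique(ages[miss]))
            ear[grp.index.to_numpy()] = e
            ul[grp.index.to_numpy()] = u
        if unmatched:
            raise ReferenceLookupError(
                f"no reference row for (sex, age, status) combinations: "
                f"{sorted(unmatched)[:10]}",
                hint="extend the reference CSV so every person is covered",
            )
        out = frame.copy()
        out["_ear"] = ear
        out["_ul"] = ul
        return out


def prevalence_cut_point(pseudo: PseudoPopulation, refs: ReferenceTable,
                         sex_col="sex", age_col="age", status_col="status",
                         subgroup_by: str | None = None) -> pd.DataFrame:
    """EAR cut-point prevalence of inadequate and excessive usual intake.

    Per subgroup: the weighted share (%) of pseudo-persons with total
    intake strictly below their individual EAR, and strictly above their
    individual UL (0 when no UL is defined for anyone in the group).
    """
    if len(pseudo) == 0:
        raise DataError("empty pseudo-population")
    frame = refs.assign(pseudo.frame, sex_col=sex_col, age_col=age_col,
                        status_col=status_col)
    groups = [("overall", frame)]
    if subgroup_by is not None:
        groups += [(str(k), g) for k, g in frame.groupby(subgroup_by, sort=True, observed=True)]
    rows = []
    for label, g in groups:
        w = g["weight_share"].to_numpy(dtype=float)
        t = g["total_intake"].to_numpy(dtype=float)
        inad = 100.0 * float(w[t < g["_ear"].to_numpy()].sum() / w.sum())
        ul = g["_ul"].to_numpy(dtype=float)
        exc_mask = ~np.isnan(ul) & (t > ul)
        exc = 100.0 * float(w[exc_mask].sum() / w.sum())
        rows.append({"subgroup": label, "n": int(g["source_person_id"].nunique()),
                     "pct_inadequate": inad, "pct_excessive": exc})
    return pd.DataFrame(rows).set_index("subgroup")


@dataclass
class RequirementDistribution:
    """Tabulated CDF of the *absorbed* daily requirement for one group.

    ``probs`` (strictly increasing, in (0,1)) and ``quantiles`` (strictly
    increasing, same length, in intake units absorbed/day) tabulate
    requirement percentiles; ``absorption`` converts ingested intake to
    absorbed intake before comparison.  Interpolation between tabulated
    points is piecewise-linear in the requirement by default
    (``interpolation='linear'``) or linear in its logarithm
    (``'log'``); the CDF is 0 below and 1 above the table.
    """

    probs: np.ndarray
    quantiles: np.ndarray
    absorption: float = DEFAULT_ABSORPTION
    interpolation: str = "linear"
    group: str | None = None

    def __post_init__(self):
        self.probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        self.quantiles = np.atleast_1d(np.asarray(self.quantiles, dtype=float))
        if self.probs.shape != self.quantiles.shape:
            raise DataError("probs and quantiles must have the same length")
        if np.any((self.probs <= 0) | (self.probs >= 1)):
            raise DataError("tabulated probabilities must lie strictly in (0, 1)")
        if np.any(np.diff(self.probs) <= 0):
            raise DataError("tabulated probabilities must be strictly increasing")
        if np.any(np.diff(self.quantiles) <= 0):
            raise DataError("tabulated requirements must be strictly increasing")
        if not (0.0 < self.absorption <= 1.0):
            raise DomainError(f"absorption fraction must be in (0, 1], got {self.absorption}")
        if self.interpolation not in ("linear", "log"):
            raise DomainError(f"unknown interpolation {self.interpolation!r}")

    @classmethod
    def point_mass(cls, requirement: float, absorption: float = 1.0,
                   group: str | None = None) -> "RequirementDistribution":
        """Degenerate requirement at a single value; reduces the full
        probability method to the EAR cut-point method."""
        return cls(probs=[0.5], quantiles=[requirement], absorption=absorption, group=group)

    def cdf(self, absorbed):
        absorbed = np.asarray(absorbed, dtype=float)
        if self.quantiles.size == 1:
            # point mass at q: requirement <= absorbed iff q <= absorbed
            return (absorbed >= self.quantiles[0]).astype(float)
        if self.interpolation == "log":
            if np.any(self.quantiles <= 0):
                raise DataError("log interpolation needs strictly positive requirements")
            x = np.log(np.maximum(absorbed, np.finfo(float).tiny))
            q = np.log(self.quantiles)
        else:
            x, q = absorbed, self.quantiles
        f = np.interp(x, q, self.probs)
        f = np.where(x < q[0], 0.0, f)
        f = np.where(x > q[-1], 1.0, f)
        return f


def risk_of_inadequacy(y, dist: RequirementDistribution):
    """Probability that the requirement exceeds the absorbed usual intake.

    ``risk = 1 - F_req(absorption * y)``; non-increasing in y and in the
    absorption fraction, 1 below the tabulated range and 0 above it.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise DomainError("usual intake must be non-negative")
    risk = 1.0 - dist.cdf(dist.absorption * y)
    return np.clip(risk, 0.0, 1.0)


def prevalence_full_probability(pseudo: PseudoPopulation,
                                dists: "RequirementDistribution | dict",
                                group_by: str | None = None,
                                subgroup_by: str | None = None) -> pd.DataFrame:
    """Full-probability prevalence of inadequacy per subgroup.

    ``dists`` is either a single :class:`RequirementDistribution` applied
    to everyone or a mapping from the levels of the ``group_by`` column
    (e.g. a sex-age group label) to group-specific distributions.  The
    prevalence is the weighted mean of the individual risks x 100.
    """
    if len(pseudo) == 0:
        raise DataError("empty pseudo-population")
    frame = pseudo.frame
    risk = np.empty(len(frame))
    if isinstance(dists, RequirementDistribution):
        risk[:] = risk_of_inadequacy(frame["total_intake"].to_numpy(dtype=float), dists)
    else:
        if group_by is None:
            raise DataError("a mapping of requirement distributions needs group_by")
        pos = {}
        for i, k in enumerate(frame[group_by].to_numpy()):
            pos.setdefault(k, []).append(i)
        missing = [k for k in pos if k not in dists]
        if missing:
            raise ReferenceLookupError(
                f"no requirement distribution for group(s) {missing}",
                hint=f"provide a distribution for every level of {group_by!r}",
            )
        t = frame["total_intake"].to_numpy(dtype=float)
        for k, idx in pos.items():
            idx = np.asarray(idx)
            risk[idx] = risk_of_inadequacy(t[idx], dists[k])
    work = frame[["source_person_id", "weight_share"]].copy()
    work["_risk"] = risk
    if subgroup_by is not None:
        work[subgroup_by] = frame[subgroup_by].to_numpy()
    groups = [("overall", work)]
    if subgroup_by is not None:
        groups += [(str(k), g) for k, g in work.groupby(subgroup_by, sort=True, observed=True)]
    rows = []
    for label, g in groups:
        w = g["weight_share"].to_numpy(dtype=float)
        rows.append({"subgroup": label, "n": int(g["source_person_id"].nunique()),
                     "pct_inadequate": 100.0 * float(w @ g["_risk"].to_numpy() / w.sum())})
    return pd.DataFrame(rows).set_index("subgroup")
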