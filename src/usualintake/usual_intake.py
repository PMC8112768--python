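"""Simulated usual-intake distributions and their summaries.

The fitted mixed model gives, for person *i*, a transformed-scale usual
level ``b_i = x_i' beta + u_i``.  The person's usual intake on the
original scale is the *expectation over days*

    T_i = E[ g^{-1}(b_i + eps) ],   eps ~ N(0, sigma_e^2),

evaluated by Gauss-Hermite quadrature.  Imputing only the between-person
deviation ``u_i`` (m times per sampled person, the "pseudo-persons") and
integrating out ``eps`` is exactly what corrects the distribution for
within-person variation: the day-to-day noise is averaged away inside
each ``T_i`` rather than inflating the spread across persons.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, GuidanceError, NotConvergedError
from .recall_model import (
    FittedAmountModel,
    RecallDataset,
    TransformSpec,
    choose_offset,
    fit_mixed_model,
    fit_one_day,
    fit_transform,
)

__all__ = [
    "PseudoPopulation",
    "backtransform_mean",
    "simulate_pseudo_population",
    "weighted_quantile",
    "distribution_summary",
    "estimate_usual_intake",
]

#: Columns every pseudo-population frame carries, in output order.
PSEUDO_COLUMNS = ("source_person_id", "weight_share", "usual_food_intake",
                  "supplement_contribution", "total_intake")


def backtransform_mean(b, transform: TransformSpec, sigma2_within: float,
                       n_nodes: int = 9):
    """Gauss-Hermite approximation of ``E[g^{-1}(b + eps)]``, eps ~ N(0, s2).

    Exact for lam=1 (linear inverse) at any node count and for lam=0.5
    (quadratic inverse) at >= 2 nodes; for the log transform 9 nodes give
    the lognormal mean ``exp(b + s2/2)`` to well within 0.1% for
    sigma_e <= 0.7.  Quadrature points falling below the transform's
    range boundary (possible for lam > 0) contribute an intake of 0.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise DomainError("conditional mean b must be finite")
    if n_nodes < 2:
        raise DomainError(f"n_nodes must be >= 2, got {n_nodes}")
    if sigma2_within < 0:
        raise DomainError("sigma2_within must be >= 0")
    if sigma2_within == 0:
        return transform.inverse(b)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    sigma = np.sqrt(sigma2_within)
    out = np.zeros_like(b, dtype=float)
    for x, wt in zip(nodes, weights):
        out += wt * transform.inverse(b + np.sqrt(2.0) * sigma * x)
    return out / np.sqrt(np.pi)


@dataclass
class PseudoPopulation:
    """m simulated usual-intake records per sampled person.

    ``frame`` columns: ``source_person_id``, ``weight_share`` (the source
    person's survey weight divided by m), carried covariates, and the
    intake accounting triple ``usual_food_intake``,
    ``supplement_contribution``, ``total_intake`` with
    ``total = food + supplement`` holding exactly per record.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in PSEUDO_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DataError(f"pseudo-population frame is missing columns {missing}")
        if len(self.frame) and (self.frame["weight_share"] <= 0).any():
            raise DataError("weight_share must be strictly positive")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in PSEUDO_COLUMNS]

    def with_contribution(self, extra: np.ndarray) -> "PseudoPopulation":
        """New population with ``extra`` added to the supplement contribution."""
        extra = np.asarray(extra, dtype=float)
        if np.any(extra < 0):
            raise DomainError("contributions must be non-negative")
        frame = self.frame.copy()
        frame["supplement_contribution"] = frame["supplement_contribution"].to_numpy() + extra
        frame["total_intake"] = (frame["usual_food_intake"].to_numpy()
                                 + frame["supplement_contribution"].to_numpy())
        return PseudoPopulation(frame)

    def to_csv(self, path) -> None:
        cov = self.covariate_columns
        order = ["source_person_id", "weight_share", *cov,
                 "usual_food_intake", "supplement_contribution", "total_intake"]
        self.frame[order].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PseudoPopulation":
        return cls(pd.read_csv(path))


def _person_rng(root_seed: int, person_id) -> np.random.Generator:
    """Deterministic per-person stream: dropping persons never shifts others."""
    digest = hashlib.sha256(str(person_id).encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, key]))


def simulate_pseudo_population(model: FittedAmountModel, dataset: RecallDataset,
                               m: int = 100, seed: int = 0, n_nodes: int = 9,
                               allow_unconverged: bool = False) -> PseudoPopulation:
    """Impute between-person deviations and back-transform to usual intakes.

    For each source person, m independent draws ``u ~ N(0, sigma_u^2)``
    are added to the person's covariate prediction and the transformed
    value is mapped back with :func:`backtransform_mean`.  Every person
    uses an RNG stream derived from the root seed and a hash of their id,
    so runs are reproducible and subsetting persons leaves the remaining
    draws unchanged.
    """
    if m < 1:
        raise DomainError(f"m must be >= 1, got {m}")
    if not model.converged and not allow_unconverged:
        raise NotConvergedError(
            "model fit did not converge; refusing to simulate",
            hint="inspect the fit or pass allow_unconverged=True to use the "
            "moment-estimator fallback values",
        )
    xb = model.person_linear_predictor(dataset)
    persons = dataset.persons
    sigma_u = np.sqrt(model.sigma2_between)
    P = len(persons)
    b = np.empty(P * m)
    for p, pid in enumerate(persons.index):
        u = _person_rng(seed, pid).normal(0.0, sigma_u, size=m) if sigma_u > 0 else np.zeros(m)
        b[p * m:(p + 1) * m] = xb.iloc[p] + u
    T = np.maximum(
        backtransform_mean(b, model.transform, model.sigma2_within, n_nodes=n_nodes), 0.0)

    drop = ["weight", *dataset.replicate_weight_columns]
    frame = persons.drop(columns=drop).loc[persons.index.repeat(m)].reset_index()
    frame = frame.rename(columns={frame.columns[0]: "source_person_id"})
    frame.insert(1, "weight_share", np.repeat(persons["weight"].to_numpy(dtype=float) / m, m))
    frame["usual_food_intake"] = T
    frame["supplement_contribution"] = 0.0
    frame["total_intake"] = T
    return PseudoPopulation(frame)


def weighted_quantile(values, weights, q):
    """Weighted quantiles: inverse weighted empirical CDF, linear interpolation.

    Each sorted value v_(k) sits at CDF position
    ``(cum_k - w_(k)/2) / W``; quantiles interpolate linearly between
    adjacent positions and are constant beyond the extremes.  With equal
    weights this reduces to the common midpoint-interpolation convention
    (e.g. {1,2,3,4} at q=0.5 gives 2.5).  Invariant to uniform weight
    rescaling and monotone in q.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise DataError("cannot take quantiles of an empty set")
    if np.any(w < 0) or w.sum() <= 0:
        raise DataError("weights must be non-negative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    pos = (cum - 0.5 * w) / cum[-1]
    return np.interp(np.asarray(q, dtype=float), pos, v)


def _weighted_share(values, weights, predicate) -> float:
    mask = predicate(np.asarray(values, dtype=float))
    w = np.asarray(weights, dtype=float)
    return 100.0 * float(w[mask].sum() / w.sum())


def distribution_summary(pseudo: PseudoPopulation, percentiles=(25, 50, 75),
                         cutoffs_below=(), cutoffs_above=(),
                         subgroup_by: str | None = None) -> pd.DataFrame:
    """Weighted summary of the usual-intake distribution per subgroup.

    Returns one row per subgroup (plus ``overall``) with the number of
    source persons, weighted mean of total intake, mean supplement
    contribution, requested percentiles ``p<q>``, and weighted shares (%)
    below/above the requested cutoffs (``pct_below_<c>``/``pct_above_<c>``).
    """
    if len(pseudo) == 0:
        raise DataError("empty pseudo-population")
    frame = pseudo.frame
    groups: list[tuple[str, pd.DataFrame]] = [("overall", frame)]
    if subgroup_by is not None:
        if subgroup_by not in frame.columns:
            raise DataError(f"subgroup column {subgroup_by!r} not in the pseudo-population")
        for lev, sub in frame.groupby(subgroup_by, sort=True, observed=True):
            if len(sub) == 0:
                warnings.warn(f"subgroup {lev!r} is empty; reported as missing")
                continue
            groups.append((str(lev), sub))
    rows = []
    for label, sub in groups:
        t = sub["total_intake"].to_numpy(dtype=float)
        w = sub["weight_share"].to_numpy(dtype=float)
        row = {
            "subgroup": label,
            "n": int(sub["source_person_id"].nunique()),
            "mean": float(w @ t / w.sum()),
            "mean_supplement": float(w @ sub["supplement_contribution"].to_numpy() / w.sum()),
        }
        qs = weighted_quantile(t, w, np.asarray(percentiles, dtype=float) / 100.0)
        for p, val in zip(percentiles, np.atleast_1d(qs)):
            row[f"p{p:g}"] = float(val)
        for c in cutoffs_below:
            row[f"pct_below_{c:g}"] = _weighted_share(t, w, lambda x: x < c)
        for c in cutoffs_above:
            row[f"pct_above_{c:g}"] = _weighted_share(t, w, lambda x: x > c)
        rows.append(row)
    return pd.DataFrame(rows).set_index("subgroup")


def estimate_usual_intake(dataset: RecallDataset, covariates=(),
                          transform: TransformSpec | None = None,
                          lambda_grid=None, zero_share_threshold: float = 0.05,
                          one_day_ratio: float | None = None,
                          m: int = 100, n_nodes: int = 9, seed: int = 0,
                          percentiles=(25, 50, 75), cutoffs_below=(), cutoffs_above=(),
                          subgroup_by: str | None = None,
                          save_pseudo_path=None, return_parts: bool = False):
    """One-call pipeline: transform -> mixed model -> simulate -> summarize.

    Chooses the Box-Cox exponent from the data unless ``transform`` is
    given, fits the repeated-recall mixed model (or, when every person
    has a single recall, the one-day model using ``one_day_ratio``),
    simulates ``m`` pseudo-persons per sampled person, and summarizes.

    With ``return_parts=True`` returns
    ``(summary, pseudo_population, fitted_model)`` so advanced analyses
    (supplements, fixed additions, adequacy) can reuse the simulated
    population; ``save_pseudo_path`` writes it as CSV.
    """
    intakes = dataset.recalls["intake"].to_numpy(dtype=float)
    if transform is None:
        offset = choose_offset(intakes, zero_share_threshold)
        transform = fit_transform(intakes, grid=lambda_grid, offset=offset)
    single_day = int((dataset.recalls_per_person() >= 2).sum()) == 0
    if single_day:
        if one_day_ratio is None:
            raise GuidanceError(
                "every person has a single recall and no external variance "
                "ratio was provided",
                hint="pass one_day_ratio (an external within:between variance "
                "ratio from a comparable survey) to run in one-day mode, and "
                "report sensitivity analyses over a range of ratios",
            )
        model = fit_one_day(dataset, one_day_ratio, covariates, transform)
    elif one_day_ratio is not None:
        model = fit_one_day(dataset, one_day_ratio, covariates, transform)
    else:
        model = fit_mixed_model(dataset, covariates, transform)
    pseudo = simulate_pseudo_population(model, dataset, m=m, seed=seed, n_nodes=n_nodes)
    if save_pseudo_path is not None:
        pseudo.to_csv(save_pseudo_path)
    summary = distribution_summary(pseudo, percentiles=percentiles,
                                   cutoffs_below=cutoffs_below,
                                   cutoffs_above=cutoffs_above,
                                   subgroup_by=subgroup_by)
    if return_parts:
        return summary, pseudo, model
    return summary
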