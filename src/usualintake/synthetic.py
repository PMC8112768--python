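"""Synthetic recall surveys with known truth.

Generates data exactly under the estimation model — transformed daily
intake equal to a linear predictor plus a person-level and a day-level
Gaussian deviation — so the whole pipeline can be validated against
closed-form population truths (available for the identity and log
transforms).  Also simulates the survey apparatus around the intakes:
a stratified two-PSU design with dispersed weights, a zero-inflated
gamma fortification-vehicle food, and discrete-dose supplement usage.

What this generator does *not* emulate: reporting error beyond symmetric
day-to-day noise (no systematic under-reporting), intake-requirement
correlation, non-Gaussian person effects, or seasonal structure.
Pipeline checks against this generator therefore validate the estimation
machinery, not the behaviour of real surveys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DomainError
from .recall_model import RecallDataset, TransformSpec

__all__ = ["SyntheticSpec", "TruthRecord", "generate_population", "closed_form_truth"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generating parameters for a synthetic recall survey.

    The transformed-scale model is ``g(intake) = beta0 [+ beta_sex * male]
    + u_i + eps_ij`` with ``u ~ N(0, sigma2_between)``,
    ``eps ~ N(0, sigma2_within)`` and ``g`` the shifted Box-Cox transform
    with exponent ``lam``.  Survey weights are inverse inclusion
    probabilities with log-uniform dispersion ``weight_dispersion`` (0
    gives equal weights).  ``n_strata`` strata each contain two PSUs.
    """

    n_persons: int = 2000
    n_recalls: int = 2
    lam: float = 1.0
    offset: float = 0.0
    beta0: float = 10.0
    beta_sex: float = 0.0
    sigma2_between: float = 1.0
    sigma2_within: float = 2.0
    n_strata: int = 1
    weight_dispersion: float = 0.0
    age_range: tuple = (19.0, 70.0)
    male_share: float = 0.5
    # zero-inflated gamma vehicle food (grams/day)
    vehicle_name: str | None = None
    vehicle_consumer_share: float = 0.7
    vehicle_mean_grams: float = 10.0
    vehicle_shape: float = 2.0
    vehicle_constant_within_person: bool = False
    # discrete-dose supplement usage (person-level usual amounts)
    supplement_dosages: tuple = ()
    supplement_use_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise DomainError("variance components must be >= 0")
        if not (0.0 <= self.supplement_use_probability <= 1.0):
            raise DomainError("supplement_use_probability must be in [0, 1]")
        if not (0.0 <= self.vehicle_consumer_share <= 1.0):
            raise DomainError("vehicle_consumer_share must be in [0, 1]")

    @property
    def transform(self) -> TransformSpec:
        return TransformSpec(lam=self.lam, offset=self.offset)


@dataclass
class TruthRecord:
    """Generating parameters plus closed-form population truths.

    ``mean``/``percentiles``/``prevalence_below`` describe the usual-intake
    distribution implied by the generating model (populated for
    lam in {0, 1}); ``person_usual`` holds each generated person's true
    usual intake for empirical cross-checks.
    """

    spec: SyntheticSpec
    mean: float | None = None
    percentiles: dict = field(default_factory=dict)
    prevalence_below: dict = field(default_factory=dict)
    person_usual: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "mean": self.mean,
            "percentiles": self.percentiles,
            "prevalence_below": self.prevalence_below,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _usual_intake_given_u(spec: SyntheticSpec, linpred: np.ndarray) -> np.ndarray:
    """True usual intake E[g^-1(b + eps)] for transformed usual level b.

    Closed form for lam=1 (identity shift) and lam=0 (lognormal); other
    exponents fall back to dense Gauss-Hermite quadrature (80 nodes) —
    still 'truth' for test purposes, just not analytic.
    """
    if spec.lam == 1.0:
        return np.maximum(linpred + 1.0 - spec.offset, 0.0)
    if spec.lam == 0.0:
        return np.exp(linpred + spec.sigma2_within / 2.0) - spec.offset
    nodes, wts = np.polynomial.hermite.hermgauss(80)
    sig = np.sqrt(spec.sigma2_within)
    tr = spec.transform
    out = np.zeros_like(linpred)
    for x, w in zip(nodes, wts):
        out += w * tr.inverse(linpred + np.sqrt(2.0) * sig * x)
    return out / np.sqrt(np.pi)


def generate_population(spec: SyntheticSpec) -> tuple[RecallDataset, TruthRecord]:
    """Simulate a recall survey under the model; bit-reproducible by seed."""
    if spec.n_persons < 1 or spec.n_recalls < 1:
        raise DataError("need at least one person and one recall per person")
    rng = np.random.default_rng(spec.seed)
    P, K = spec.n_persons, spec.n_recalls

    age = rng.uniform(*spec.age_range, size=P)
    sex = np.where(rng.random(P) < spec.male_share, "M", "F")
    stratum = rng.integers(0, spec.n_strata, size=P)
    psu = rng.integers(1, 3, size=P)
    if spec.weight_dispersion > 0:
        incl = np.exp(rng.uniform(-spec.weight_dispersion, spec.weight_dispersion, size=P))
        weight = 1.0 / incl
    else:
        weight = np.ones(P)

    linpred = spec.beta0 + spec.beta_sex * (sex == "M")
    u = rng.normal(0.0, np.sqrt(spec.sigma2_between), size=P)
    eps = rng.normal(0.0, np.sqrt(spec.sigma2_within), size=(P, K))
    # recalls are non-negative amounts; the clip only binds in extreme tails
    intake = np.maximum(spec.transform.inverse((linpred + u)[:, None] + eps), 0.0)

    person_ids = np.array([f"p{i:05d}" for i in range(P)])
    persons = pd.DataFrame({
        "weight": weight, "stratum": stratum, "psu": psu,
        "age": age, "sex": sex,
    }, index=pd.Index(person_ids, name="person_id"))

    recalls = pd.DataFrame({
        "person_id": np.repeat(person_ids, K),
        "recall_index": np.tile(np.arange(1, K + 1), P),
        "intake": intake.reshape(-1),
    })
    if spec.vehicle_name is not None:
        consumer = rng.random(P) < spec.vehicle_consumer_share
        scale = spec.vehicle_mean_grams / spec.vehicle_shape
        if spec.vehicle_constant_within_person:
            grams = np.repeat(np.where(
                consumer, rng.gamma(spec.vehicle_shape, scale, size=P), 0.0), K)
        else:
            grams = (np.repeat(consumer, K)
                     * rng.gamma(spec.vehicle_shape, scale, size=P * K))
        recalls[f"vehicle_{spec.vehicle_name}"] = grams
    if spec.supplement_dosages:
        uses = rng.random(P) < spec.supplement_use_probability
        dose = rng.choice(np.asarray(spec.supplement_dosages, dtype=float), size=P)
        persons["supplement_amount"] = np.where(uses, dose, 0.0)

    closed_form = spec.lam in (0.0, 1.0) and spec.beta_sex == 0.0
    truth = closed_form_truth(spec) if closed_form else TruthRecord(spec=spec)
    truth.person_usual = _usual_intake_given_u(spec, linpred + u)
    return RecallDataset(recalls=recalls, persons=persons), truth


def closed_form_truth(spec: SyntheticSpec, cutoffs=(),
                      percentiles=(25, 50, 75)) -> TruthRecord:
    """Analytic usual-intake distribution for intercept-only generating models.

    lam=1 (offset 0): usual intake is ``N(beta0 + 1, sigma2_between)``, so
    the share below c is ``Phi((c - beta0 - 1)/sigma_u)``.  lam=0: usual
    intake is ``exp(beta0 + sigma2_within/2 + u)`` — lognormal with log-scale
    mean ``beta0 + sigma2_within/2`` and SD ``sigma_u`` — so the mean is
    ``exp(beta0 + sigma2_between/2 + sigma2_within/2)`` and the share below c
    is ``Phi((ln c - beta0 - sigma2_within/2)/sigma_u)``.
    """
    if spec.lam not in (0.0, 1.0):
        raise DomainError(
            f"closed-form truth is only available for lam in {{0, 1}}, got {spec.lam}",
            hint="use a Monte-Carlo estimate from TruthRecord.person_usual instead",
        )
    if spec.beta_sex != 0.0:
        raise DomainError("closed-form truth assumes an intercept-only model")
    su = np.sqrt(spec.sigma2_between)
    truth = TruthRecord(spec=spec)
    if spec.lam == 1.0:
        mu = spec.beta0 + 1.0 - spec.offset
        truth.mean = mu
        for p in percentiles:
            truth.percentiles[p] = float(mu + stats.norm.ppf(p / 100.0) * su)
        for c in cutoffs:
            z = np.inf if su == 0 and c > mu else (-np.inf if su == 0 else (c - mu) / su)
            truth.prevalence_below[c] = float(100.0 * stats.norm.cdf(z)) if su > 0 \
                else (100.0 if c > mu else 0.0)
    else:
        logmu = spec.beta0 + spec.sigma2_within / 2.0
        truth.mean = float(np.exp(logmu + spec.sigma2_between / 2.0) - spec.offset)
        for p in percentiles:
            truth.percentiles[p] = float(
                np.exp(logmu + stats.norm.ppf(p / 100.0) * su) - spec.offset)
        for c in cutoffs:
            shifted = c + spec.offset
            if su > 0:
                truth.prevalence_below[c] = float(
                    100.0 * stats.norm.cdf((np.log(shifted) - logmu) / su))
            else:
                truth.prevalence_below[c] = 100.0 if shifted > np.exp(logmu) else 0.0
    return truth
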