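"""Recall data model, normality transform, and person-level mixed model.

A 24-h recall measures a single day of intake, which scatters widely
around the person's long-run average ("usual") intake.  On a suitably
transformed scale the daily amount is modeled as

    g(r_ij; lambda) = x_i' beta + u_i + eps_ij,

where ``g`` is a shifted Box-Cox transform, ``u_i ~ N(0, sigma_u^2)`` is a
person-level (between-person) deviation and ``eps_ij ~ N(0, sigma_e^2)``
is the day-to-day (within-person) deviation.  The fitted variance
components drive the downstream simulation of the usual-intake
distribution; only the between-person deviation is retained there, which
is what removes day-to-day noise from the estimated distribution.

Two fitting modes are provided:

* :func:`fit_mixed_model` — weighted REML when at least a subsample of
  persons has repeated recalls (the ordinary case);
* :func:`fit_one_day` — a single recall per person plus an *external*
  within:between variance ratio, trading an untestable assumption for
  the ability to analyze one-day surveys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DataError,
    DomainError,
    GuidanceError,
    NearlyDailyViolationError,
    NoVarianceError,
    RankError,
)

__all__ = [
    "TransformSpec",
    "RecallDataset",
    "DesignSpec",
    "FittedAmountModel",
    "choose_offset",
    "fit_transform",
    "fit_mixed_model",
    "fit_one_day",
    "default_lambda_grid",
]

#: Recall-level covariate columns recognised in long-format input; everything
#: else apart from the structural columns is treated as a person-level value.
RECALL_LEVEL_COVARIATES = ("weekend_flag", "recall_sequence")

_STRUCTURAL = ("person_id", "recall_index", "intake")
_DESIGN_COLS = ("weight", "stratum", "psu")

VEHICLE_PREFIX = "vehicle_"
REPW_PREFIX = "repw_"


# ---------------------------------------------------------------------------
# Transform
# ---------------------------------------------------------------------------

def default_lambda_grid() -> np.ndarray:
    """Candidate Box-Cox exponents 0.01, 0.02, ..., 1.00."""
    return np.round(np.arange(1, 101) / 100.0, 2)


@dataclass(frozen=True)
class TransformSpec:
    """Shifted Box-Cox transform ``g(r) = ((r+offset)^lam - 1)/lam`` (log at lam=0).

    ``lam`` in (0, 1] or exactly 0 for the log; ``offset >= 0`` shifts the
    data off zero before transforming.  ``g`` is strictly increasing on
    ``r > -offset``.
    """

    lam: float
    offset: float = 0.0

    def __post_init__(self):
        if not (self.lam == 0.0 or 0.0 < self.lam <= 1.0):
            raise DomainError(f"lambda must be 0 or in (0, 1], got {self.lam}")
        if self.offset < 0:
            raise DomainError(f"offset must be >= 0, got {self.offset}")

    def apply(self, r):
        """Transform original-scale amounts to the modeling scale."""
        r = np.asarray(r, dtype=float)
        shifted = r + self.offset
        if np.any(shifted <= 0):
            bad = np.flatnonzero(shifted <= 0)
            raise DomainError(
                f"{bad.size} non-positive value(s) after offset {self.offset} "
                f"(first positions: {bad[:10].tolist()})",
                hint="increase the offset or drop zero-intake rows",
            )
        if self.lam == 0.0:
            return np.log(shifted)
        return (np.power(shifted, self.lam) - 1.0) / self.lam

    def inverse(self, t, clamp: bool = True):
        """Back-transform to the original scale.

        When ``1/lam`` is an integer the inverse is a polynomial and is
        evaluated globally — this keeps Gauss-Hermite integration of the
        inverse exact (identity at lam=1, quadratic at lam=0.5).  For
        other exponents, points below ``-1/lam`` have no real preimage:
        they are mapped to an intake of 0 when ``clamp`` is true
        (intakes are non-negative), otherwise they raise.
        """
        t = np.asarray(t, dtype=float)
        if self.lam == 0.0:
            return np.exp(t) - self.offset
        base = self.lam * t + 1.0
        inv_exp = 1.0 / self.lam
        if abs(inv_exp - round(inv_exp)) < 1e-12:
            return np.power(base, int(round(inv_exp))) - self.offset
        below = base < 0
        if np.any(below):
            if not clamp:
                raise DomainError("value below the transform's range boundary")
            base = np.where(below, 0.0, base)
        return np.power(base, inv_exp) - self.offset

    @property
    def lower_bound(self) -> float:
        """Infimum of the transform's range (-inf for the log)."""
        return -np.inf if self.lam == 0.0 else -1.0 / self.lam


def choose_offset(intakes, zero_share_threshold: float = 0.05) -> float:
    """Offset policy for zero intakes of a nearly-daily component.

    Zero person-days are tolerated up to ``zero_share_threshold`` (default
    5%), in which case the offset is half the smallest positive intake.
    A larger zero share means the component is episodically consumed and
    outside this tool's scope.
    """
    x = np.asarray(intakes, dtype=float)
    if np.any(x < 0):
        raise DomainError("negative intakes are not allowed")
    zero_share = np.mean(x == 0)
    if zero_share == 0:
        return 0.0
    if zero_share > zero_share_threshold:
        raise NearlyDailyViolationError(
            f"{zero_share:.1%} of person-days report zero intake "
            f"(threshold {zero_share_threshold:.0%}); this looks like an "
            "episodically consumed component, which the amount-only model "
            "cannot analyze",
            hint="episodic components need a two-part model; this tool only "
            "handles components consumed nearly every day",
        )
    return 0.5 * float(np.min(x[x > 0]))


def fit_transform(intakes, grid=None, offset: float = 0.0) -> TransformSpec:
    """Select the Box-Cox exponent maximizing the profile log-likelihood.

    The criterion is the standard Box-Cox profile likelihood of the
    transformed values including the Jacobian term
    ``(lam - 1) * sum(log(r + offset))``; the search is an exhaustive grid
    evaluation, so the result is deterministic for fixed input and grid.
    """
    x = np.asarray(intakes, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("intakes must be finite")
    shifted = x + offset
    if np.any(shifted <= 0):
        bad = np.flatnonzero(shifted <= 0)
        raise DomainError(
            f"non-positive values at positions {bad[:10].tolist()} with offset {offset}",
            hint="use choose_offset() or pass a positive offset",
        )
    if shifted.size < 10:
        raise DataError(f"need at least 10 positive values to select lambda, got {shifted.size}")
    if np.ptp(shifted) == 0:
        raise NoVarianceError("all intakes are equal; the transform is undefined")
    grid = default_lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    ll = np.array([stats.boxcox_llf(lam, shifted) for lam in grid])
    lam = float(grid[int(np.argmax(ll))])
    return TransformSpec(lam=lam, offset=offset)


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class RecallDataset:
    """Person-recall table split into recall-level and person-level frames.

    ``recalls`` has one row per person-recall with columns ``person_id``,
    ``recall_index``, ``intake``, any ``vehicle_<name>`` columns, and
    recall-level covariates (``weekend_flag``).  ``persons`` is indexed by
    ``person_id`` and carries the survey ``weight`` (strictly positive),
    optional ``stratum``/``psu`` design identifiers, person-level
    covariates, and optional pre-computed replicate weight columns
    ``repw_1..repw_R``.
    """

    recalls: pd.DataFrame
    persons: pd.DataFrame

    def __post_init__(self):
        for col in ("person_id", "recall_index", "intake"):
            if col not in self.recalls.columns:
                raise DataError(f"recalls frame is missing required column {col!r}")
        if "weight" not in self.persons.columns:
            raise DataError("persons frame is missing required column 'weight'")
        missing = set(self.recalls["person_id"]) - set(self.persons.index)
        if missing:
            raise DataError(f"recall rows reference unknown persons: {sorted(missing)[:5]}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "RecallDataset":
        """Build from one long table with one row per person-recall.

        Columns other than the structural ones, vehicles, and the known
        recall-level covariates are taken as person-level and read off each
        person's first row.
        """
        df = df.copy()
        for col in _STRUCTURAL:
            if col not in df.columns:
                raise DataError(
                    f"input is missing required column {col!r}",
                    hint=f"expected header: person_id,recall_index,intake[,weight,...]; got {list(df.columns)}",
                )
        recall_cols = [c for c in df.columns
                       if c in _STRUCTURAL or c.startswith(VEHICLE_PREFIX)
                       or c in RECALL_LEVEL_COVARIATES]
        person_cols = [c for c in df.columns if c not in recall_cols]
        recalls = df[recall_cols].reset_index(drop=True)
        persons = df.groupby("person_id", sort=True)[person_cols].first()
        if "weight" not in persons.columns:
            raise DataError(
                "input is missing required column 'weight'",
                hint="every person needs a strictly positive survey weight "
                "(use 1.0 for an unweighted sample)",
            )
        return cls(recalls=recalls, persons=persons)

    @classmethod
    def from_csv(cls, path) -> "RecallDataset":
        return cls.from_long(pd.read_csv(path))

    def to_long(self) -> pd.DataFrame:
        return self.recalls.merge(self.persons, left_on="person_id", right_index=True, how="left")

    def to_csv(self, path) -> None:
        self.to_long().to_csv(path, index=False)

    # -- accessors ---------------------------------------------------------

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_recalls(self) -> int:
        return len(self.recalls)

    @property
    def vehicle_columns(self) -> list[str]:
        return [c for c in self.recalls.columns if c.startswith(VEHICLE_PREFIX)]

    @property
    def replicate_weight_columns(self) -> list[str]:
        cols = [c for c in self.persons.columns if c.startswith(REPW_PREFIX)]
        return sorted(cols, key=lambda c: int(c[len(REPW_PREFIX):]))

    def recalls_per_person(self) -> pd.Series:
        return self.recalls.groupby("person_id").size().reindex(self.persons.index, fill_value=0)

    def with_weights(self, weights: pd.Series) -> "RecallDataset":
        """Copy with the person weights replaced (used by replication)."""
        persons = self.persons.copy()
        persons["weight"] = weights.reindex(persons.index)
        if persons["weight"].isna().any():
            raise DataError("replacement weights do not cover every person")
        return RecallDataset(recalls=self.recalls.copy(), persons=persons)

    def subset_recalls(self, mask) -> "RecallDataset":
        recalls = self.recalls.loc[mask].reset_index(drop=True)
        keep = recalls["person_id"].unique()
        return RecallDataset(recalls=recalls, persons=self.persons.loc[keep])


# ---------------------------------------------------------------------------
# Covariate design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Frozen covariate encoding so replicate refits use identical columns.

    Categorical covariates are one-hot encoded with the first (sorted)
    level as reference; numeric covariates enter as-is.  The intercept is
    always the first column.
    """

    covariates: list[str] = field(default_factory=list)
    levels: dict[str, list] = field(default_factory=dict)  # categorical name -> ordered levels

    @classmethod
    def infer(cls, frame: pd.DataFrame, covariates: list[str]) -> "DesignSpec":
        levels: dict[str, list] = {}
        for name in covariates:
            if name not in frame.columns:
                raise DataError(f"covariate {name!r} not found in the data")
            col = frame[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
                levels[name] = sorted(pd.unique(col.dropna()).tolist())
        return cls(covariates=list(covariates), levels=levels)

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"]
        for name in self.covariates:
            if name in self.levels:
                names.extend(f"{name}[{lev}]" for lev in self.levels[name][1:])
            else:
                names.append(name)
        return names

    def build(self, frame: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(frame))]
        for name in self.covariates:
            col = frame[name]
            if name in self.levels:
                for lev in self.levels[name][1:]:
                    cols.append((col == lev).to_numpy(dtype=float))
            else:
                cols.append(col.to_numpy(dtype=float))
        return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                collinear.append(names[j])
        raise RankError(
            f"covariate design is singular (rank {rank} < {X.shape[1]})",
            collinear=collinear,
            hint=f"columns involved in collinearity: {collinear}",
        )


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class FittedAmountModel:
    """Transform + mixed-model parameters on the transformed scale."""

    transform: TransformSpec
    beta: np.ndarray
    sigma2_between: float
    sigma2_within: float
    design_spec: DesignSpec
    n_persons: int
    n_recalls: int
    converged: bool
    variance_ratio_used: float | None = None  # only set by one-day fits
    method: str = "reml"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise DomainError("variance components must be non-negative")
        if self.beta.size != len(self.design_spec.column_names):
            raise DataError("beta length does not match the design specification")

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        return self.design_spec.build(frame) @ self.beta

    def person_linear_predictor(self, dataset: RecallDataset) -> pd.Series:
        """Per-person x'beta.

        Recall-level covariates (if any were included) are averaged within
        person so the prediction targets the person's typical day.
        """
        long = dataset.to_long()
        X = self.design_spec.build(long)
        xb = pd.Series(X @ self.beta, index=long["person_id"].to_numpy())
        return xb.groupby(level=0).mean().reindex(dataset.persons.index)


# ---------------------------------------------------------------------------
# Weighted REML for the random-intercept model
# ---------------------------------------------------------------------------

def _person_blocks(dataset: RecallDataset, covariate_names, transform):
    """Sort recalls by person and precompute per-person sufficient statistics."""
    long = dataset.to_long().sort_values(["person_id", "recall_index"], kind="stable")
    y = transform.apply(long["intake"].to_numpy(dtype=float))
    spec = DesignSpec.infer(long, list(covariate_names))
    X = spec.build(long)
    _check_rank(X, spec.column_names)

    pid = long["person_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
    n_i = np.diff(np.r_[starts, pid.size])
    person_ids = pid[starts]
    w = dataset.persons.loc[person_ids, "weight"].to_numpy(dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DataError("survey weights must be finite and strictly positive")
    w = w / w.mean()  # scale-free: estimates are invariant to rescaling

    # per-person sums of x and y; full weighted cross-products
    Xs = np.add.reduceat(X, starts, axis=0)            # (P, k)
    ys = np.add.reduceat(y, starts)                    # (P,)
    w_rows = np.repeat(w, n_i)
    A0 = X.T @ (X * w_rows[:, None])
    b0 = X.T @ (y * w_rows)
    c0 = float(y @ (y * w_rows))
    return spec, X, y, w, n_i, Xs, ys, A0, b0, c0, person_ids


def _reml_neg2(theta, w, n_i, Xs, ys, A0, b0, c0):
    """-2 x weighted restricted log-likelihood, profiled over beta.

    theta = (log sigma_u^2, log sigma_e^2).  The random-intercept
    covariance inverse has the closed form
    V_i^{-1} = (I - s_i J)/sigma_e^2 with s_i = sigma_u^2/(sigma_e^2 + n_i sigma_u^2).
    """
    su2, se2 = np.exp(theta)
    d = se2 + n_i * su2
    coef = w * su2 / d                                  # (P,)
    XtVX = (A0 - (Xs * coef[:, None]).T @ Xs) / se2
    XtVy = (b0 - Xs.T @ (coef * ys)) / se2
    ytVy = (c0 - float(coef @ ys**2)) / se2
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None
    quad = ytVy - float(beta @ XtVy)
    logdetV = float(w @ ((n_i - 1) * np.log(se2) + np.log(d)))
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0 or not np.isfinite(quad):
        return np.inf, None
    return logdetV + quad + logdetX, beta


def _moments_estimate(y, X, w, n_i, starts=None):
    """Weighted one-way ANOVA moment estimator (initialisation and fallback)."""
    # within: pooled variance of recalls around person means, persons with >=2
    ends = np.cumsum(n_i)
    starts = ends - n_i
    resid_within = np.empty_like(y)
    person_mean = np.empty(n_i.size)
    for p, (a, b) in enumerate(zip(starts, ends)):
        m = y[a:b].mean()
        person_mean[p] = m
        resid_within[a:b] = y[a:b] - m
    rep = n_i >= 2
    denom = float(w[rep] @ (n_i[rep] - 1))
    se2 = float((np.repeat(w, n_i) * resid_within**2).sum() / denom) if denom > 0 else 0.0
    # between: weighted variance of person means minus the within share
    Xbar = np.add.reduceat(X, starts, axis=0) / n_i[:, None]
    WX = Xbar * w[:, None]
    beta, *_ = np.linalg.lstsq(Xbar.T @ WX, Xbar.T @ (w * person_mean), rcond=None)
    r = person_mean - Xbar @ beta
    var_means = float(w @ r**2 / w.sum())
    su2 = max(var_means - se2 * float(np.mean(1.0 / n_i)), 0.0)
    return beta, su2, se2


def fit_mixed_model(dataset: RecallDataset, covariate_names=(),
                    transform: TransformSpec | None = None,
                    use_weights: bool = True) -> FittedAmountModel:
    """Weighted REML fit of the random-intercept model on the transformed scale.

    Requires repeated recalls on at least a subsample of persons — the
    within-person variance is not identified otherwise.  Survey weights
    enter as person-level weights in the (restricted) likelihood so point
    estimates are design-consistent; standard errors come from the
    replication module, not from the information matrix.

    Falls back to the weighted ANOVA moment estimator when the optimizer
    fails, with ``converged=False`` surfaced on the result.
    """
    if transform is None:
        transform = TransformSpec(lam=1.0)
    n_rep = int((dataset.recalls_per_person() >= 2).sum())
    if n_rep == 0:
        raise GuidanceError(
            "no person has repeated recalls, so within- and between-person "
            "variance cannot be separated",
            hint="use fit_one_day() with an external within:between variance "
            "ratio, and run sensitivity analyses over a range of ratios",
        )
    spec, X, y, w, n_i, Xs, ys, A0, b0, c0, _ = _person_blocks(dataset, covariate_names, transform)
    if not use_weights:
        w = np.ones_like(w)
        A0 = X.T @ X
        b0 = X.T @ y
        c0 = float(y @ y)

    beta0, su2_0, se2_0 = _moments_estimate(y, X, w, n_i)
    x0 = np.log(np.maximum([su2_0, se2_0], 1e-8))

    res = optimize.minimize(
        lambda th: _reml_neg2(np.clip(th, -50, 50), w, n_i, Xs, ys, A0, b0, c0)[0],
        x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    theta = np.clip(res.x, -50, 50)
    neg2, beta = _reml_neg2(theta, w, n_i, Xs, ys, A0, b0, c0)
    converged = bool(res.success and beta is not None and np.isfinite(neg2))
    if converged:
        su2, se2 = np.exp(theta)
        method = "reml"
    else:
        beta, su2, se2 = beta0, su2_0, se2_0
        method = "moments"
    # variances indistinguishable from the optimizer floor are true zeros
    floor = 1e-12 * max(su2 + se2, 1.0)
    su2 = 0.0 if su2 < floor else float(su2)
    se2 = 0.0 if se2 < floor else float(se2)
    return FittedAmountModel(
        transform=transform, beta=np.asarray(beta), sigma2_between=su2,
        sigma2_within=se2, design_spec=spec, n_persons=dataset.n_persons,
        n_recalls=dataset.n_recalls, converged=converged, method=method,
    )


def fit_one_day(dataset: RecallDataset, external_ratio: float | None,
                covariate_names=(), transform: TransformSpec | None = None) -> FittedAmountModel:
    """Single-recall fit using an external within:between variance ratio.

    beta is estimated by weighted least squares on the transformed scale;
    the total residual variance sigma_tot^2 is then split using
    ``r = sigma_e^2 / sigma_u^2``:

        sigma_u^2 = sigma_tot^2 / (1 + r),   sigma_e^2 = sigma_tot^2 * r / (1 + r),

    so the two components always sum to sigma_tot^2 exactly.  Because the
    ratio is borrowed, not estimated, results should be accompanied by
    sensitivity analyses over a range of plausible ratios.
    """
    if external_ratio is None:
        raise GuidanceError(
            "single-day data require an external within:between variance ratio",
            hint="supply external_ratio estimated from a similar population; "
            "a misspecified ratio biases the usual-intake distribution, so "
            "always conduct sensitivity analyses with a range of external ratios",
        )
    r = float(external_ratio)
    if not np.isfinite(r) or r < 0:
        raise DomainError(f"external variance ratio must be finite and >= 0, got {r}")
    if transform is None:
        transform = TransformSpec(lam=1.0)
    # keep the first recall per person; one-day mode ignores any extras
    first = dataset.recalls.sort_values(["person_id", "recall_index"]).groupby("person_id").head(1)
    ds = RecallDataset(recalls=first.reset_index(drop=True), persons=dataset.persons)
    long = ds.to_long()
    y = transform.apply(long["intake"].to_numpy(dtype=float))
    spec = DesignSpec.infer(long, list(covariate_names))
    X = spec.build(long)
    _check_rank(X, spec.column_names)
    w = long["weight"].to_numpy(dtype=float)
    w = w / w.mean()
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, X.T @ (w * y))
    resid = y - X @ beta
    k = X.shape[1]
    # weights are normalised to mean 1, so sum(w) ~ n and n - k is the df
    sigma_tot2 = float(w @ resid**2) / max(len(y) - k, 1)
    su2 = sigma_tot2 / (1.0 + r)
    se2 = sigma_tot2 * r / (1.0 + r)
    return FittedAmountModel(
        transform=transform, beta=beta, sigma2_between=su2, sigma2_within=se2,
        design_spec=spec, n_persons=ds.n_persons, n_recalls=ds.n_recalls,
        converged=True, variance_ratio_used=r, method="one_day",
    )
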