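"""Replication-based uncertainty: BRR with Fay adjustment, and the bootstrap.

Model-based standard errors are not valid for the pipeline's outputs —
the statistics are functionals of a simulated population produced by a
multi-stage procedure — so every SE here comes from re-running the whole
pipeline on perturbed inputs:

* **BRR** (two PSUs per stratum): replicate r multiplies the base weight
  by ``2 - F`` for one PSU of each stratum and by ``F`` for the other,
  following the columns of a Hadamard matrix;
  ``SE^2 = sum_r (theta_r - theta_0)^2 / (R (1-F)^2)``.
* **Bootstrap** (any design): persons are resampled with replacement
  within strata; SE is the sample standard deviation of the replicate
  estimates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.linalg import hadamard

from .config import AnalysisConfig, ReplicateDesign
from .errors import DataError, ReplicationError
from .pipeline import flatten_statistics, run_scenarios
from .recall_model import RecallDataset

__all__ = ["make_brr_replicates", "replicate_se", "run_with_uncertainty"]

logger = logging.getLogger(__name__)

Z_NORMAL_95 = 1.96  # normal-approximation 95% CI multiplier


def _hadamard_order(n_strata: int) -> int:
    """Smallest Sylvester order with n_strata balanced (+/-1) columns.

    Column 0 of a Hadamard matrix is all ones, so strata occupy columns
    1..n_strata; orders are powers of two.
    """
    order = 4
    while order - 1 < n_strata:
        order *= 2
    return order


def make_brr_replicates(persons: pd.DataFrame, fay: float = 0.3,
                        n_replicates: int | None = None) -> pd.DataFrame:
    """Construct BRR replicate weight columns from a 2-PSU/stratum design.

    ``persons`` must carry ``weight``, ``stratum``, ``psu``.  Returns a
    frame indexed like ``persons`` with columns ``repw_1..repw_R``.  The
    balanced half-sample property guarantees that each person's replicate
    weights average back to the base weight over the full set.
    """
    for col in ("weight", "stratum", "psu"):
        if col not in persons.columns:
            raise DataError(f"BRR needs a {col!r} column on the persons frame")
    if not (0.0 <= fay < 1.0):
        raise DataError(f"Fay coefficient must be in [0, 1), got {fay}")
    strata = persons.groupby("stratum")["psu"].unique()
    bad = {s: sorted(p.tolist()) for s, p in strata.items() if len(p) != 2}
    if bad:
        raise ReplicationError(
            f"BRR requires exactly 2 PSUs per stratum; offending strata: {bad}",
            hint="collapse or split PSUs, or use the bootstrap instead",
        )
    stratum_labels = list(strata.index)
    R = _hadamard_order(len(stratum_labels)) if n_replicates is None else int(n_replicates)
    if R & (R - 1) or R - 1 < len(stratum_labels):
        raise ReplicationError(
            f"{R} replicates cannot balance {len(stratum_labels)} strata",
            hint=f"use a power of two >= {_hadamard_order(len(stratum_labels))}",
        )
    H = hadamard(R)
    base = persons["weight"].to_numpy(dtype=float)
    s_idx = persons["stratum"].map({s: j for j, s in enumerate(stratum_labels)}).to_numpy()
    first_psu = persons["psu"].to_numpy() == np.array(
        [strata[s][0] for s in stratum_labels])[s_idx]
    out = {}
    for r in range(R):
        sel = H[r, 1 + s_idx] == 1          # which half-sample per stratum
        factor = np.where(sel == first_psu, 2.0 - fay, fay)
        out[f"repw_{r + 1}"] = base * factor
    return pd.DataFrame(out, index=persons.index)


def replicate_se(theta0: float, theta_r, method: str = "brr", fay: float = 0.3) -> float:
    """SE from replicate estimates.

    BRR: ``sqrt(sum (theta_r - theta0)^2 / (R (1-F)^2))``; bootstrap: the
    sample standard deviation (ddof=1) of the replicate estimates.
    Permutation-invariant in ``theta_r`` and equivariant under affine maps
    applied to all estimates.
    """
    tr = np.asarray(theta_r, dtype=float)
    if tr.size == 0:
        raise DataError("no replicate estimates supplied")
    if method == "brr":
        if not (0.0 <= fay < 1.0):
            raise DataError(f"Fay coefficient must be in [0, 1), got {fay}")
        return float(np.sqrt(np.sum((tr - theta0) ** 2) / (tr.size * (1.0 - fay) ** 2)))
    if method == "bootstrap":
        if tr.size == 1:
            return 0.0
        return float(np.std(tr, ddof=1))
    raise DataError(f"unknown replication method {method!r}")


def _bootstrap_dataset(dataset: RecallDataset, rng: np.random.Generator) -> RecallDataset:
    """Resample persons with replacement within strata (whole sample if none)."""
    persons = dataset.persons
    if "stratum" in persons.columns:
        chosen = []
        for _, grp in persons.groupby("stratum", sort=True):
            idx = grp.index.to_numpy()
            chosen.append(rng.choice(idx, size=idx.size, replace=True))
        chosen = np.concatenate(chosen)
    else:
        idx = persons.index.to_numpy()
        chosen = rng.choice(idx, size=idx.size, replace=True)
    # duplicated persons get distinct ids so the mixed model sees them as
    # independent persons, as bootstrap theory requires
    new_ids = pd.Index([f"{pid}#{k}" for k, pid in enumerate(chosen)])
    new_persons = persons.loc[chosen].set_axis(new_ids)
    rec_by_person = {pid: grp for pid, grp in dataset.recalls.groupby("person_id")}
    parts = []
    for new_id, pid in zip(new_ids, chosen):
        g = rec_by_person[pid].copy()
        g["person_id"] = new_id
        parts.append(g)
    recalls = pd.concat(parts, ignore_index=True)
    return RecallDataset(recalls=recalls, persons=new_persons)


def run_with_uncertainty(dataset: RecallDataset, config: AnalysisConfig) -> pd.DataFrame:
    """Point estimates with replication SEs and normal 95% CIs.

    Re-runs the full scenario pipeline once per replicate — BRR replicate
    weights (pre-supplied ``repw_*`` columns, or constructed from
    stratum/PSU) or within-stratum bootstrap resamples — using a
    replicate-specific RNG stream so random interventions are redrawn per
    replicate.  Replicate failures are logged and counted; more than
    ``max_failure_rate`` aborts the run.

    Returns the scenario table widened with ``se_<stat>``,
    ``ci_lo_<stat>``, ``ci_hi_<stat>`` columns for every statistic.
    """
    design = config.replication or ReplicateDesign()
    point = run_scenarios(dataset, config)
    theta0 = flatten_statistics(point)

    replicate_runs = []
    failures: list[tuple[int, str]] = []
    if design.method == "brr":
        repw_cols = dataset.replicate_weight_columns
        if repw_cols:
            repw = dataset.persons[repw_cols]
        else:
            repw = make_brr_replicates(dataset.persons, fay=design.fay,
                                       n_replicates=design.n_replicates)
        R = repw.shape[1]
        for r in range(R):
            seed_r = (config.seed ^ (r + 1)) & 0x7FFFFFFF
            try:
                ds_r = dataset.with_weights(repw.iloc[:, r])
                replicate_runs.append(flatten_statistics(run_scenarios(ds_r, config, seed=seed_r)))
            except Exception as exc:  # noqa: BLE001 - replicate failures are data
                failures.append((r, repr(exc)))
                logger.warning("replicate %d failed: %r", r + 1, exc)
    else:
        R = design.n_replicates or 200
        for r in range(R):
            seed_r = (config.seed ^ (r + 1)) & 0x7FFFFFFF
            rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 7070, r]))
            try:
                ds_r = _bootstrap_dataset(dataset, rng)
                replicate_runs.append(flatten_statistics(run_scenarios(ds_r, config, seed=seed_r)))
            except Exception as exc:  # noqa: BLE001
                failures.append((r, repr(exc)))
                logger.warning("replicate %d failed: %r", r + 1, exc)

    if len(failures) > design.max_failure_rate * R:
        raise ReplicationError(
            f"{len(failures)}/{R} replicates failed (threshold "
            f"{design.max_failure_rate:.0%}); first failures: {failures[:3]}",
            hint="inspect the replicate failure log; the design may be too "
            "sparse for stable refits",
        )
    if design.method == "bootstrap" and R == 1:
        logger.warning("bootstrap with a single replicate: SEs are 0 and unreliable")

    out = point.copy()
    stats = [c for c in point.columns if c not in ("scenario", "n")]
    for (scenario, subgroup), _ in point.iterrows():
        for stat in stats:
            key = f"{scenario}|{subgroup}|{stat}"
            tr = np.array([run[key] for run in replicate_runs if key in run])
            if tr.size == 0:
                se = np.nan
            else:
                se = replicate_se(theta0[key], tr, method=design.method, fay=design.fay)
            out.loc[(scenario, subgroup), f"se_{stat}"] = se
            out.loc[(scenario, subgroup), f"ci_lo_{stat}"] = theta0[key] - Z_NORMAL_95 * se
            out.loc[(scenario, subgroup), f"ci_hi_{stat}"] = theta0[key] + Z_NORMAL_95 * se
    order = ["n"] + [c for s in stats for c in
                     (s, f"se_{s}", f"ci_lo_{s}", f"ci_hi_{s}")]
    return out[order]
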