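"""Seeded replication harness for the two estimator-comparison studies.

Two designs are provided:

* the iid design — draw PQX samples at a true (alpha, theta), fit with MLE,
  MM and/or EM across a grid of sample sizes, and aggregate bias, MSE and MRE
  (mean relative estimate) per parameter;
* the INAR design — simulate INARPQX(1) paths at a true (p, alpha, theta) and
  compare CML against Yule-Walker the same way.

Aggregation metrics over N replications, per parameter i:

    Bias = sum_j (est_ij - truth_i) / N
    MSE  = sum_j (est_ij - truth_i)^2 / N
    MRE  = sum_j (est_ij / truth_i) / N

Seeding: each replication gets an independent generator seeded by
(master seed, size index, replication index), so enlarging the replication
count extends rather than reshuffles earlier replications.  Replications
whose fit fails (non-convergence, inadmissible moments) are excluded from the
aggregates and counted in the reported failure rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pqx
from .exceptions import MomentsIncompatibleError, PQXError
from .inar import CountSeries, INARModel, PQXInnovation, simulate
from .inar_fit import cml_fit, yw_fit
from .pqx import PQXParams
from .pqx_fit import IIDSample, fit_em, fit_mle, fit_mm

__all__ = ["Scenario", "SimStudyResult", "metrics", "run_iid_study", "run_inar_study"]

_IID_ESTIMATORS = ("MLE", "MM", "EM")
_INAR_ESTIMATORS = ("CML", "YW")


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario: truth, sample sizes, replication count, seed."""

    true_params: dict  # e.g. {"alpha": .5, "theta": 1.5} or {"p": .3, "alpha": .5, "theta": .5}
    n_grid: tuple
    n_reps: int
    estimators: tuple
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(n <= 0 for n in self.n_grid):
            raise ValueError("sample sizes must be positive")


@dataclass
class SimStudyResult:
    """Tidy per-(n, estimator, parameter) table of bias/MSE/MRE plus failure rates."""

    table: pd.DataFrame
    failure_rates: pd.DataFrame = field(default_factory=pd.DataFrame)


def metrics(estimates: np.ndarray, truth: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Bias, MSE and MRE per parameter from an (N, k) matrix of estimates."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    tr = np.asarray(truth, dtype=float)
    if est.shape[0] < 1 or est.shape[1] != tr.size:
        raise ValueError("estimates must be (N, k) with k matching truth")
    rows = []
    for j, name in enumerate(names):
        err = est[:, j] - tr[j]
        rows.append({
            "parameter": name,
            "bias": float(np.mean(err)),
            "mse": float(np.mean(err**2)),
            "mre": float(np.mean(est[:, j] / tr[j])),
        })
    return pd.DataFrame(rows)


def _rep_rng(seed: int, n_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([seed, n_index, rep])


def run_iid_study(scenario: Scenario) -> SimStudyResult:
    """Estimator comparison on iid PQX samples (MLE / MM / EM)."""
    bad = set(scenario.estimators) - set(_IID_ESTIMATORS)
    if bad:
        raise ValueError(f"unknown iid estimators: {sorted(bad)}")
    truth = PQXParams(scenario.true_params["alpha"], scenario.true_params["theta"])
    truth_vec = np.array([truth.alpha, truth.theta])
    tables, failures = [], []
    for ni, n in enumerate(scenario.n_grid):
        collected = {est: [] for est in scenario.estimators}
        fails = {est: 0 for est in scenario.estimators}
        for rep in range(scenario.n_reps):
            rng = _rep_rng(scenario.seed, ni, rep)
            sample = IIDSample(pqx.rvs(int(n), truth, seed=rng))
            for est in scenario.estimators:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        if est == "MLE":
                            fit = fit_mle(sample)
                        elif est == "MM":
                            fit = fit_mm(sample)
                        else:
                            fit = fit_em(sample)
                    if not fit.converged:
                        raise PQXError(fit.message)
                    collected[est].append([fit.params.alpha, fit.params.theta])
                except (PQXError, MomentsIncompatibleError):
                    fails[est] += 1
        for est in scenario.estimators:
            if not collected[est]:
                continue
            tab = metrics(np.array(collected[est]), truth_vec, ["alpha", "theta"])
            tab.insert(0, "estimator", est)
            tab.insert(0, "n", int(n))
            tables.append(tab)
            failures.append({
                "n": int(n), "estimator": est,
                "failure_rate": fails[est] / scenario.n_reps,
            })
    return SimStudyResult(
        table=pd.concat(tables, ignore_index=True),
        failure_rates=pd.DataFrame(failures),
    )


def run_inar_study(scenario: Scenario, burn_in: int = 500) -> SimStudyResult:
    """CML-vs-YW comparison on simulated INARPQX(1) paths.

    CML fits are warm-started from the YW estimate when it is admissible.
    """
    bad = set(scenario.estimators) - set(_INAR_ESTIMATORS)
    if bad:
        raise ValueError(f"unknown INAR estimators: {sorted(bad)}")
    tp = scenario.true_params
    model = INARModel(p=tp["p"], innovation=PQXInnovation(tp["alpha"], tp["theta"]))
    truth_vec = np.array([tp["p"], tp["alpha"], tp["theta"]])
    names = ["p", "alpha", "theta"]
    tables, failures = [], []
    for ni, n in enumerate(scenario.n_grid):
        collected = {est: [] for est in scenario.estimators}
        fails = {est: 0 for est in scenario.estimators}
        for rep in range(scenario.n_reps):
            rng = _rep_rng(scenario.seed, ni, rep)
            series = simulate(model, int(n), burn_in=burn_in, seed=rng)
            yw_result = None
            if "YW" in scenario.estimators or "CML" in scenario.estimators:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        yw_result = yw_fit(series)
                except PQXError:
                    yw_result = None
            if "YW" in scenario.estimators:
                if yw_result is None:
                    fails["YW"] += 1
                else:
                    m = yw_result.model
                    collected["YW"].append([m.p, *m.innovation.params])
            if "CML" in scenario.estimators:
                try:
                    init = None
                    if yw_result is not None:
                        init = (yw_result.model.p, yw_result.model.innovation)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = cml_fit(series, family="pqx", init=init)
                    if not fit.converged:
                        raise PQXError(fit.message)
                    m = fit.model
                    collected["CML"].append([m.p, *m.innovation.params])
                except PQXError:
                    fails["CML"] += 1
        for est in scenario.estimators:
            if not collected[est]:
                continue
            tab = metrics(np.array(collected[est]), truth_vec, names)
            tab.insert(0, "estimator", est)
            tab.insert(0, "n", int(n))
            tables.append(tab)
            failures.append({
                "n": int(n), "estimator": est,
                "failure_rate": fails[est] / scenario.n_reps,
            })
    return SimStudyResult(
        table=pd.concat(tables, ignore_index=True),
        failure_rates=pd.DataFrame(failures),
    )
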