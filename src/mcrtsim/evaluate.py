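"""Monte Carlo evaluation harness: run (scenario x ICC x replicate) grids.

For each cell the harness simulates trials, applies all six estimators, and
summarizes bias, empirical SD, average estimated SE, MSE, coverage of the 95%
interval, and empirical power (interval excluding zero).  Replicates on which
the GEE model fails to converge are excluded for *all* models and replaced by
freshly simulated trials at the next replicate index until the requested
number of analyzable replicates accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .designs import ScenarioSpec
from .estimators import (MODELS, FitResult, fit_model_a, fit_model_b, fit_model_c,
                         fit_model_d, fit_model_e1, fit_model_e2, per_centre_summaries)
from .simulate import RngStream, generate_trial, icc_key

__all__ = ["ReplicateRecord", "PerformanceSummary", "evaluate", "run_cell", "run_study",
           "RESULT_COLUMNS"]

RESULT_COLUMNS = ("scenario", "icc", "model", "n_reps", "mean_estimate", "emp_sd",
                  "avg_se", "mse", "coverage", "power", "n_excluded")


@dataclass
class ReplicateRecord:
    """Fits of all six models on one simulated trial."""

    replicate: int
    fits: Mapping[str, FitResult]
    excluded: bool = False


@dataclass
class PerformanceSummary:
    """Performance of one model in one (scenario, ICC) cell."""

    scenario: int
    icc: float
    model: str
    n_reps: int
    mean_estimate: float
    bias: float
    emp_sd: float
    avg_se: float
    mse: float
    coverage: float
    power: float
    n_excluded: int


def evaluate(fits: Sequence[FitResult], true_beta1: float) -> dict:
    """Six performance metrics of a collection of replicate fits.

    bias      mean(estimate) - true_beta1
    emp_sd    sample SD (n-1 denominator) of the estimates
    avg_se    mean of the estimated standard errors
    mse       mean squared deviation of the estimates from the truth (1/n)
    coverage  fraction of closed 95% intervals containing true_beta1
    power     fraction of intervals with zero strictly outside
    """
    if len(fits) == 0:
        raise ValueError("evaluate requires at least one fit")
    est = np.array([f.estimate for f in fits])
    se = np.array([f.se for f in fits])
    lo = np.array([f.ci_low for f in fits])
    hi = np.array([f.ci_high for f in fits])
    return {
        "n_reps": int(est.size),
        "mean_estimate": float(est.mean()),
        "bias": float(est.mean() - true_beta1),
        "emp_sd": float(est.std(ddof=1)) if est.size > 1 else float("nan"),
        "avg_se": float(se.mean()),
        "mse": float(np.mean((est - true_beta1) ** 2)),
        "coverage": float(np.mean((lo <= true_beta1) & (true_beta1 <= hi))),
        "power": float(np.mean((lo > 0.0) | (hi < 0.0))),
    }


def _fit_all(data) -> dict[str, FitResult]:
    """All six fits on one trial; centre summaries shared between E1 and E2."""
    summaries = per_centre_summaries(data)
    return {
        "A": fit_model_a(data),
        "B": fit_model_b(data),
        "C": fit_model_c(data),
        "D": fit_model_d(data),
        "E1": fit_model_e1(summaries),
        "E2": fit_model_e2(summaries),
    }


def run_cell(
    spec: ScenarioSpec,
    icc: float,
    n_sims: int,
    seed: int,
    keep_records: bool = False,
) -> list[PerformanceSummary] | tuple[list[PerformanceSummary], list[ReplicateRecord]]:
    """Simulate and analyze one (scenario, ICC) cell.

    Replicates are drawn on the substream path (scenario id, icc key,
    replicate index).  A replicate whose GEE fit reports non-convergence is
    excluded from every model's summary and replaced by the next replicate
    index, until ``n_sims`` analyzable replicates accumulate (cap: 10 x
    n_sims attempts).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    params = spec.params if icc == spec.params.icc else spec.params.with_icc(icc)
    per_model: dict[str, list[FitResult]] = {m: [] for m in MODELS}
    records: list[ReplicateRecord] = []
    n_excluded = 0
    accepted = 0
    attempts = 0
    cap = 10 * n_sims
    key = icc_key(icc)
    while accepted < n_sims:
        if attempts >= cap:
            raise RuntimeError(
                f"exclusion cap exceeded in scenario {spec.id} at ICC {icc}: "
                f"{n_excluded} of {attempts} replicates failed to converge"
            )
        rng = RngStream(seed, (spec.id, key, attempts)).generator()
        data = generate_trial(spec.design, params, rng)
        fits = _fit_all(data)
        excluded = not fits["D"].converged
        if keep_records:
            records.append(ReplicateRecord(attempts, fits, excluded))
        attempts += 1
        if excluded:
            n_excluded += 1
            continue
        accepted += 1
        for m in MODELS:
            per_model[m].append(fits[m])
    summaries = [
        PerformanceSummary(scenario=spec.id, icc=icc, model=m, n_excluded=n_excluded,
                           **evaluate(per_model[m], params.beta1))
        for m in MODELS
    ]
    if keep_records:
        return summaries, records
    return summaries


def summaries_to_frame(summaries: Iterable[PerformanceSummary]) -> pd.DataFrame:
    rows = [
        {col: getattr(s, col) for col in RESULT_COLUMNS}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def run_study(
    spec: ScenarioSpec,
    n_sims: int,
    seed: int,
    icc_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Map :func:`run_cell` over a scenario's ICC grid.

    Returns a long-format table with one row per (scenario, icc, model).
    """
    grid = spec.icc_grid if icc_grid is None else tuple(icc_grid)
    all_summaries: list[PerformanceSummary] = []
    for icc in grid:
        all_summaries.extend(run_cell(spec, icc, n_sims, seed))
    return summaries_to_frame(all_summaries)
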