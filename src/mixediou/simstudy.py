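"""Replicated simulation-study harness.

Runs ``n_reps`` simulate-and-fit replicates of a scenario and computes the
evaluation criteria used throughout the package's simulation studies:
convergence classification with failure-reason counts, median/IQR of
iterations among converged fits, and per-variance-parameter summaries —
bias (with Monte Carlo standard error), the empirical SD of the
unconstrained transform ``delta(nu_hat)``, the median/IQR of its estimated
standard error, and the empirical coverage of the nominal 95% interval for
``nu``.  Fixed effects get bias and coverage as well.

Summaries are computed over converged fits only; failures are always
reported by reason.  Replicate ``r`` of a study with master seed ``s``
draws from an independent stream seeded by ``(s, r)``, so results do not
depend on execution order and subsets of replicates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iou_cov import IOUParameterization
from .model_core import LongDataset
from .optimizers import FitResult, OptimizerConfig, fit
from .simulator import (
    BalancedDesign,
    TruthParams,
    UnbalancedDesign,
    gen_balanced,
    gen_unbalanced,
)
from .starting_values import empirical_start, strong_tracking_start

__all__ = ["SimStudyResult", "run_study", "mcse_coverage", "compare_scenarios"]


def mcse_coverage(p_hat: float, n: int) -> float:
    """Monte Carlo standard error of a coverage percentage.

    ``100 * sqrt(p (1 - p) / n)``; e.g. 0.689 at p=0.95, n=1000.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be a proportion in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / n))


def _truth_values(truth: TruthParams, parameterization: IOUParameterization) -> dict[str, float]:
    vp = truth.variance
    out: dict[str, float] = {}
    sd = np.sqrt(np.diag(vp.G))
    for i in range(vp.q):
        for j in range(i + 1):
            if i == j:
                out[f"re_var_{i + 1}"] = float(vp.G[i, i])
            else:
                out[f"re_corr_{i + 1}_{j + 1}"] = float(vp.G[i, j] / (sd[i] * sd[j]))
    out["alpha"] = vp.iou.alpha
    amp = parameterization.amplitude_coord
    out[amp] = vp.iou.omega if amp == "omega" else vp.iou.tau
    out["sigma2"] = vp.sigma2
    return out


@dataclass
class SimStudyResult:
    """Summaries of one simulation scenario."""

    label: str
    n_reps: int
    n_converged: int
    failure_counts: dict[str, int]
    iter_median: float
    iter_iqr: float
    params: pd.DataFrame  # per variance parameter: truth/bias/mcse/coverage...
    fixed: pd.DataFrame  # per fixed effect: truth/bias/mcse/coverage
    fits: list[FitResult] = field(default_factory=list, repr=False)


def run_study(
    design: BalancedDesign | UnbalancedDesign,
    truth: TruthParams,
    n_reps: int,
    cfg: OptimizerConfig = OptimizerConfig(),
    seed: int = 0,
    parameterization: IOUParameterization = IOUParameterization(),
    start: str = "empirical",
    label: str = "",
    keep_fits: bool = False,
) -> SimStudyResult:
    """Simulate ``n_reps`` datasets from ``truth`` and REML-fit each one."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    truth_nat = _truth_values(truth, parameterization)
    beta_truth = np.asarray(truth.beta, dtype=float)

    results: list[FitResult] = []
    failures: dict[str, int] = {}
    for r in range(n_reps):
        rep_seed = [int(seed), r]
        if isinstance(design, BalancedDesign):
            data = gen_balanced(design, truth, rep_seed)
        else:
            data = gen_unbalanced(design, truth, rep_seed)
        try:
            if start == "empirical":
                s0 = empirical_start(data, regularize_to=getattr(design, "k", 3.0)).start
            elif start == "strong":
                s0 = strong_tracking_start(data).start
            else:
                raise ValueError(f"unknown start strategy {start!r}")
            res = fit(data, s0, cfg, parameterization)
        except (ValueError, np.linalg.LinAlgError):
            failures["start_failed"] = failures.get("start_failed", 0) + 1
            continue
        results.append(res)
        if not res.converged:
            failures[res.failure_reason] = failures.get(res.failure_reason, 0) + 1

    conv = [r for r in results if r.converged]
    n_conv = len(conv)
    iters = np.array([r.n_iter for r in conv], dtype=float)
    iter_median = float(np.median(iters)) if n_conv else np.nan
    iter_iqr = (
        float(np.percentile(iters, 75) - np.percentile(iters, 25)) if n_conv else np.nan
    )

    rows = []
    if n_conv:
        labels = conv[0].rho_labels
        ci_keys = list(truth_nat)
        for key, rho_idx in zip(ci_keys, range(len(labels))):
            tv = truth_nat[key]
            est = np.array([r.estimates[key] for r in conv])
            deltas = np.array([r.rho[rho_idx] for r in conv])
            se_d = np.array([r.se_rho[rho_idx] for r in conv])
            covered = np.array([r.ci[key][0] <= tv <= r.ci[key][1] for r in conv])
            bias = float(np.mean(est) - tv)
            mcse = float(np.std(est, ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan
            rows.append(
                {
                    "parameter": key,
                    "truth": tv,
                    "bias": bias,
                    "mcse": mcse,
                    "emp_sd_delta": float(np.std(deltas, ddof=1)) if n_conv > 1 else np.nan,
                    "median_se_delta": float(np.median(se_d)),
                    "iqr_se_delta": float(
                        np.percentile(se_d, 75) - np.percentile(se_d, 25)
                    ),
                    "coverage_pct": 100.0 * float(np.mean(covered)),
                    "coverage_mcse": mcse_coverage(float(np.mean(covered)), n_conv),
                }
            )
    params = pd.DataFrame(rows)

    frows = []
    if n_conv:
        from .optimizers import Z_95

        for j, name in enumerate(conv[0].fixed.names):
            bj = np.array([r.fixed.beta[j] for r in conv])
            sej = np.array([r.fixed.se[j] for r in conv])
            tv = beta_truth[j]
            covered = np.abs(bj - tv) <= Z_95 * sej
            frows.append(
                {
                    "parameter": name,
                    "truth": tv,
                    "bias": float(np.mean(bj) - tv),
                    "mcse": float(np.std(bj, ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan,
                    "coverage_pct": 100.0 * float(np.mean(covered)),
                }
            )
    fixed = pd.DataFrame(frows)

    return SimStudyResult(
        label=label or truth.label,
        n_reps=n_reps,
        n_converged=n_conv,
        failure_counts=failures,
        iter_median=iter_median,
        iter_iqr=iter_iqr,
        params=params,
        fixed=fixed,
        fits=results if keep_fits else [],
    )


def compare_scenarios(results: list[SimStudyResult]) -> pd.DataFrame:
    """Stack per-parameter summaries, one row per (scenario, parameter)."""
    frames = []
    for res in results:
        if res.params.empty:
            continue
        t = res.params.copy()
        t.insert(0, "scenario", res.label)
        t["n_converged"] = res.n_converged
        t["n_reps"] = res.n_reps
        t["iter_median"] = res.iter_median
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["scenario", "parameter", "truth", "bias", "mcse", "emp_sd_delta",
                     "median_se_delta", "iqr_se_delta", "coverage_pct", "coverage_mcse",
                     "n_converged", "n_reps", "iter_median"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["scenario", "parameter"], kind="stable").reset_index(drop=True)
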