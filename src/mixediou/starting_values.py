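"""Starting-value strategies for REML optimization.

Three strategies:

* :func:`empirical_start` — moment-based: across-subject variances of the
  response at (regularized) measurement times; for a random-intercept IOU
  model the slope of those variances over time approximates ``omega`` and
  the intercept approximates the baseline variance.  The tracking rate
  ``alpha`` has no clean moment estimator; a heuristic based on the
  departure of the earliest variance from the fitted line is used, capped
  at 10 — under weak tracking the cap engages essentially always.
* :func:`strong_tracking_start` — fits a conditional-independence linear
  mixed model by EM and keeps its ``G`` and ``sigma^2``; ``alpha`` and
  ``omega`` start at 1 and 0.1 (a strong-derivative-tracking prior).
* :func:`alpha_grid_start` — computer-intensive: REML-optimizes the
  remaining variance parameters at each fixed ``alpha`` on a grid and
  starts from the grid point with the lowest deviance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .iou_cov import IOUParameterization, IOUParams
from .model_core import LongDataset, ReducedTheta, VarianceParams, merge_sigma, split_sigma
from .reml_engine import RemlDomainError, RemlEngine
from .optimizers import OptimizerConfig, newton_minimize

__all__ = [
    "StartValueReport",
    "empirical_start",
    "strong_tracking_start",
    "em_conditional_independence",
    "alpha_grid_start",
]

VAR_FLOOR = 1e-4
ALPHA_CAP = 10.0
ALPHA_FLOOR = 0.1


@dataclass
class StartValueReport:
    """A starting point plus how it was derived."""

    start: VarianceParams
    method: str
    diagnostics: dict = field(default_factory=dict)
    warning: str | None = None


def _per_time_variances(data: LongDataset, step: float):
    """Across-subject variances of y at regularized time points."""
    rows = []
    for i in range(data.m):
        t_reg = np.round(data.times[i] / step) * step
        # keep the first measurement per subject per regularized time
        seen = set()
        for tr, yv in zip(t_reg, data.y[i]):
            if tr not in seen:
                rows.append((i, tr, yv))
                seen.add(tr)
    df = pd.DataFrame(rows, columns=["subject", "t", "y"])
    g = df.groupby("t")["y"]
    tab = pd.DataFrame({"var": g.var(ddof=1), "n": g.size()})
    tab = tab[tab["n"] >= 2].dropna()
    return df, tab


def empirical_start(
    data: LongDataset,
    regularize_to: float = 3.0,
) -> StartValueReport:
    """Moment-based starting values (random-intercept or random-slope model).

    Requires at least two distinct regularized time points with two or more
    subjects each.
    """
    df, tab = _per_time_variances(data, regularize_to)
    if len(tab) < 2:
        raise ValueError(
            "insufficient cross-sectional replication for empirical starting values "
            "(need >= 2 regularized time points with >= 2 subjects); "
            "use strong_tracking_start instead"
        )
    tvals = tab.index.to_numpy(dtype=float)
    vvals = tab["var"].to_numpy()
    if np.all(vvals < 1e-12):
        raise ValueError("responses have zero cross-sectional variance")
    # fit the variance-versus-time line on the later points, where the IOU
    # variance is essentially linear; the earliest point then carries the
    # curvature information used for the alpha heuristic below
    late = tvals > tvals[0] if len(tvals) > 2 else np.ones(len(tvals), bool)
    slope, intercept = np.polyfit(tvals[late], vvals[late], 1)
    sigma_b2 = max(float(intercept), VAR_FLOOR)
    omega = max(float(slope), VAR_FLOOR)

    # sigma^2 from the gap between the variance at the earliest time and the
    # covariance with the next time point (for a random-intercept IOU model
    # at t=0 this gap is exactly sigma^2)
    t0, t1 = tvals[0], tvals[1]
    wide = df.pivot_table(index="subject", columns="t", values="y", aggfunc="first")
    sigma2 = VAR_FLOOR
    if t0 in wide.columns and t1 in wide.columns:
        pair = wide[[t0, t1]].dropna()
        if len(pair) >= 2:
            cov01 = float(np.cov(pair[t0], pair[t1])[0, 1])
            sigma2 = max(float(pair[t0].var(ddof=1)) - cov01, VAR_FLOOR)

    # alpha heuristic: residual of the earliest variance from the fitted
    # line estimates omega/alpha; noise usually drives this to the cap
    resid0 = float(vvals[0] - (intercept + slope * tvals[0]))
    if resid0 > 1e-8:
        alpha = float(np.clip(omega / resid0, ALPHA_FLOOR, ALPHA_CAP))
    else:
        alpha = ALPHA_CAP

    if data.q == 1:
        G = np.array([[sigma_b2]])
    else:
        # random-slope model: modest positive slope variance, zero corr
        G = np.diag([sigma_b2, max(omega / 10.0, VAR_FLOOR)])
    start = VarianceParams(G, IOUParams(alpha, omega, "omega"), sigma2)
    return StartValueReport(
        start,
        method="empirical",
        diagnostics={
            "regularize_to": regularize_to,
            "per_time_variances": tab,
            "intercept": float(intercept),
            "slope": float(slope),
            "resid0": resid0,
        },
    )


def em_conditional_independence(
    data: LongDataset, max_iter: int = 200, tol: float = 1e-8
):
    """Laird-Ware EM (ML) for the conditional-independence model Y=Xb+Zu+e.

    Returns ``(G, sigma2, beta, loglik_trace)``; the observed-data
    log-likelihood is non-decreasing across iterations.
    """
    q, p, N, m = data.q, data.p, data.n_obs, data.m
    # moment initialization
    yall = np.concatenate(data.y)
    Xall = np.vstack(data.X)
    beta, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    resid = yall - Xall @ beta
    tot = float(resid @ resid) / max(N - p, 1)
    sigma2 = max(tot / 2.0, 1e-10)
    G = np.eye(q) * max(tot / 2.0, 1e-10)
    trace: list[float] = []
    for _ in range(max_iter):
        # GLS update of beta (ECM step), then E-step moments, then M-step
        A = np.zeros((p, p))
        bv = np.zeros(p)
        Vinvs = []
        for i in range(m):
            Z = data.Z[i]
            V = Z @ G @ Z.T + sigma2 * np.eye(Z.shape[0])
            Vinv = np.linalg.inv(V)
            Vinvs.append(Vinv)
            A += data.X[i].T @ Vinv @ data.X[i]
            bv += data.X[i].T @ Vinv @ data.y[i]
        beta = np.linalg.solve(A, bv)
        ll = 0.0
        G_new = np.zeros((q, q))
        ee = 0.0
        for i in range(m):
            Z, X, y = data.Z[i], data.X[i], data.y[i]
            n_i = len(y)
            Vinv = Vinvs[i]
            r = y - X @ beta
            sign, logdet = np.linalg.slogdet(np.linalg.inv(Vinv))
            ll += -0.5 * (n_i * np.log(2 * np.pi) + logdet + float(r @ Vinv @ r))
            bhat = G @ Z.T @ Vinv @ r
            Vb = G - G @ Z.T @ Vinv @ Z @ G
            G_new += np.outer(bhat, bhat) + Vb
            e = r - Z @ bhat
            ee += float(e @ e) + float(np.einsum("ij,jk,ki->", Z, Vb, Z.T))
        trace.append(ll)
        G_next = G_new / m
        sigma2_next = ee / N
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * max(1.0, abs(trace[-2])):
            G, sigma2 = G_next, sigma2_next
            break
        G, sigma2 = G_next, sigma2_next
        if sigma2 < 1e-12:
            raise np.linalg.LinAlgError("E-step covariance degenerate (sigma^2 -> 0)")
    return G, float(sigma2), beta, trace


def strong_tracking_start(data: LongDataset, max_iter: int = 200) -> StartValueReport:
    """EM-based alternative starts assuming strong derivative tracking.

    ``G`` and ``sigma^2`` come from a conditional-independence LMM fitted by
    EM; ``alpha`` and ``omega`` start at 1 and 0.1.
    """
    warning = None
    try:
        G, sigma2, beta, trace = em_conditional_independence(data, max_iter=max_iter)
        if len(trace) == max_iter:
            warning = f"EM did not converge within {max_iter} iterations; using last iterate"
    except np.linalg.LinAlgError as e:
        raise ValueError(f"conditional-independence EM failed: {e}") from None
    # keep G safely PD
    eig = np.linalg.eigvalsh(G)
    if eig[0] < VAR_FLOOR:
        G = G + (VAR_FLOOR - min(eig[0], 0.0)) * np.eye(data.q)
    sigma2 = max(sigma2, VAR_FLOOR)
    start = VarianceParams(G, IOUParams(1.0, 0.1, "omega"), sigma2)
    return StartValueReport(
        start, method="strong_tracking",
        diagnostics={"em_loglik_trace": trace, "em_beta": beta},
        warning=warning,
    )


def alpha_grid_start(
    data: LongDataset,
    alpha_grid: Sequence[float],
    cfg: OptimizerConfig = OptimizerConfig(),
    parameterization: IOUParameterization = IOUParameterization(),
    base_start: VarianceParams | None = None,
) -> StartValueReport:
    """Profile the REML deviance over a fixed-``alpha`` grid.

    For each grid value, ``alpha`` is held fixed and the remaining variance
    parameters are REML-optimized; the grid point with the lowest deviance
    (and its conditional estimates) becomes the start.
    """
    alpha_grid = sorted(float(a) for a in alpha_grid)
    if not alpha_grid:
        raise ValueError("alpha grid must be nonempty")
    if base_start is None:
        try:
            base_start = empirical_start(data).start
        except ValueError:
            base_start = strong_tracking_start(data).start
    engine = RemlEngine(data)
    q = data.q
    nc = q * (q + 1) // 2
    profile = []
    best = None
    for alpha in alpha_grid:
        vp0 = VarianceParams(
            base_start.G, IOUParams(alpha, base_start.iou.omega, "omega"), base_start.sigma2
        )
        theta0, _ = split_sigma(vp0, parameterization)
        fixed_coord = theta0.vector[nc]
        free_idx = [i for i in range(len(theta0.vector)) if i != nc]

        def embed(vfree: np.ndarray) -> np.ndarray:
            v = np.empty(len(theta0.vector))
            v[free_idx] = vfree
            v[nc] = fixed_coord
            return v

        def objective(vfree: np.ndarray):
            th = ReducedTheta(embed(vfree), q, parameterization)
            neg2, s2, grad, infos = engine.score_info(th, kinds=("observed",))
            H = infos["observed"]
            return neg2, grad[free_idx], H[np.ix_(free_idx, free_idx)]

        try:
            vf, state = newton_minimize(objective, theta0.vector[free_idx], cfg)
            th = ReducedTheta(embed(vf), q, parameterization)
            ev = engine.evaluate(th)
            dev = ev.neg2_profiled_remllik
            profile.append((alpha, dev, state.met_tolerance))
            if state.met_tolerance and (best is None or dev < best[1]):
                best = (alpha, dev, merge_sigma(th, ev.sigma2_hat))
        except (RemlDomainError, np.linalg.LinAlgError):
            profile.append((alpha, np.nan, False))
    if best is None:
        raise ValueError("all fixed-alpha grid fits failed")
    table = pd.DataFrame(profile, columns=["alpha", "deviance", "converged"])
    return StartValueReport(
        best[2], method="alpha_grid", diagnostics={"profile": table, "best_alpha": best[0]}
    )
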