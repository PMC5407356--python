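"""Newton-type REML optimizers, convergence classification, Wald intervals.

Three schedules are provided, mirroring mixed-model practice: plain
Newton-Raphson on the observed information (``nr``), and hybrids that run
``c`` iterations of Fisher scoring (``fs_then_nr``) or the
average-information algorithm (``ai_then_nr``) before switching to NR —
the Jennrich-Sampson recipe for robustness to poor starting values.

Non-convergence is a *result*, not an exception: fits are classified as in
the simulation-study methodology (solution within ``max_iter`` iterations
and a positive-definite information matrix for the unconstrained-scale
standard errors), with the failure reason recorded.

Standard errors are computed on the unconstrained scale ``rho`` (log
standard deviations, hyperbolic arctangents of correlations, log sigma,
log amplitude, log of the alpha coordinate); 95% Wald intervals are formed
on that scale and their endpoints mapped back to the natural scale, so
interval endpoints always respect the parameter ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.stats import norm

from .iou_cov import IOUParameterization, IOUParams
from .model_core import (
    LongDataset,
    ReducedTheta,
    VarianceParams,
    FixedEffects,
    log_cholesky_encode,
    merge_sigma,
    split_sigma,
)
from .reml_engine import RemlDomainError, RemlEngine

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "fit",
    "newton_minimize",
    "classify_convergence",
    "to_unconstrained",
    "from_unconstrained",
    "wald_ci",
    "information_for_rho",
    "model_selection",
]

Z_95 = 1.959964  # 95% normal quantile, 6 d.p.

Algorithm = Literal["nr", "fs_then_nr", "ai_then_nr"]
FailureReason = Literal["none", "max_iter", "hessian_not_pd", "info_not_pd"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Optimizer schedule and convergence tolerances."""

    algorithm: Algorithm = "nr"
    c: int = 10  # switch-over iteration count for the hybrid schedules
    max_iter: int = 100
    tol_deviance: float = 1e-8  # relative change in -2l
    tol_grad: float = 1e-5  # scaled gradient
    info_pd_tol: float = 1e-6  # relative eigenvalue threshold for the info matrix
    max_halvings: int = 10

    def __post_init__(self) -> None:
        if self.c < 0 or self.max_iter < 1:
            raise ValueError("c must be >= 0 and max_iter >= 1")
        if min(self.tol_deviance, self.tol_grad, self.info_pd_tol) <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class OptState:
    """Optimizer bookkeeping used by convergence classification."""

    met_tolerance: bool
    n_iter: int
    hessian_failed: bool = False
    deviance_trace: list[float] = field(default_factory=list)


def classify_convergence(
    opt_state: OptState, info_matrix: np.ndarray | None, cfg: OptimizerConfig
) -> tuple[bool, FailureReason]:
    """Converged iff tolerances met within max_iter AND info matrix is PD."""
    if opt_state.hessian_failed:
        return False, "hessian_not_pd"
    if not opt_state.met_tolerance or opt_state.n_iter > cfg.max_iter:
        return False, "max_iter"
    if info_matrix is not None:
        eig = np.linalg.eigvalsh(info_matrix)
        if eig[-1] <= 0 or eig[0] <= cfg.info_pd_tol * eig[-1]:
            return False, "info_not_pd"
    return True, "none"


# ---------------------------------------------------------------------------
# Unconstrained transformation rho and Wald intervals
# ---------------------------------------------------------------------------


def _g_to_sd_corr(G: np.ndarray):
    sd = np.sqrt(np.diag(G))
    corr = G / np.outer(sd, sd)
    return sd, corr


def rho_names(q: int, parameterization: IOUParameterization) -> list[str]:
    names = []
    for i in range(q):
        for j in range(i + 1):
            names.append(f"log_sd_b{i + 1}" if i == j else f"atanh_corr_b{i + 1}_b{j + 1}")
    names.append({"alpha": "log_alpha", "log_alpha": "log_alpha", "inv_alpha": "log_inv_alpha"}[
        parameterization.scale_coord
    ])
    names.append("log_omega" if parameterization.amplitude_coord == "omega" else "log_tau")
    names.append("log_sigma")
    return names


def to_unconstrained(vp: VarianceParams, parameterization: IOUParameterization) -> np.ndarray:
    """Map the natural variance parameters to the unconstrained rho scale."""
    sd, corr = _g_to_sd_corr(vp.G)
    out = []
    for i in range(vp.q):
        for j in range(i + 1):
            if i == j:
                out.append(np.log(sd[i]))
            else:
                if abs(corr[i, j]) >= 1:
                    raise ValueError(f"correlation {corr[i, j]} not in (-1, 1)")
                out.append(np.arctanh(corr[i, j]))
    c = parameterization.alpha_to_coord(vp.iou.alpha)
    out.append(np.log(c) if parameterization.scale_coord != "log_alpha" else c)
    amp = vp.iou.omega if parameterization.amplitude_coord == "omega" else vp.iou.tau
    out.append(np.log(amp))
    out.append(0.5 * np.log(vp.sigma2))
    return np.array(out)


def from_unconstrained(
    rho: np.ndarray, q: int, parameterization: IOUParameterization
) -> VarianceParams:
    """Inverse of :func:`to_unconstrained`."""
    rho = np.asarray(rho, dtype=float)
    nc = q * (q + 1) // 2
    sd = np.empty(q)
    corr = np.eye(q)
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                sd[i] = np.exp(rho[k])
            else:
                corr[i, j] = corr[j, i] = np.tanh(rho[k])
            k += 1
    G = corr * np.outer(sd, sd)
    c = np.exp(rho[nc]) if parameterization.scale_coord != "log_alpha" else rho[nc]
    alpha = parameterization.coord_to_alpha(c)
    amp = np.exp(rho[nc + 1])
    iou = IOUParams(alpha, amp, parameterization.amplitude_coord)
    sigma2 = np.exp(2.0 * rho[nc + 2])
    return VarianceParams(G, iou, sigma2)


def wald_ci(rho_hat: np.ndarray, se_rho: np.ndarray, level: float = 0.95):
    """Unconstrained-scale Wald intervals ``rho_hat +- z * se``."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    se_rho = np.asarray(se_rho, dtype=float)
    if np.any(se_rho < 0):
        raise ValueError("standard errors must be nonnegative")
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(norm.ppf(0.5 + level / 2.0))
    return rho_hat - z * se_rho, rho_hat + z * se_rho


def natural_cis(
    rho_hat: np.ndarray,
    se_rho: np.ndarray,
    q: int,
    parameterization: IOUParameterization,
    level: float = 0.95,
) -> dict[str, tuple[float, float]]:
    """Back-transform rho-scale Wald intervals to the natural parameters.

    Every component map is monotone, so endpoints are transformed directly
    (and swapped where the map is decreasing, e.g. alpha under the
    reciprocal coordinate).
    """
    lo, hi = wald_ci(rho_hat, se_rho, level)
    nc = q * (q + 1) // 2
    out: dict[str, tuple[float, float]] = {}
    k = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                out[f"re_var_{i + 1}"] = (float(np.exp(2 * lo[k])), float(np.exp(2 * hi[k])))
            else:
                out[f"re_corr_{i + 1}_{j + 1}"] = (float(np.tanh(lo[k])), float(np.tanh(hi[k])))
            k += 1
    par = parameterization
    if par.scale_coord == "inv_alpha":
        a_lo, a_hi = 1.0 / np.exp(hi[nc]), 1.0 / np.exp(lo[nc])
    else:
        a_lo, a_hi = np.exp(lo[nc]), np.exp(hi[nc])
    out["alpha"] = (float(a_lo), float(a_hi))
    amp_name = par.amplitude_coord
    out[amp_name] = (float(np.exp(lo[nc + 1])), float(np.exp(hi[nc + 1])))
    out["sigma2"] = (float(np.exp(2 * lo[nc + 2])), float(np.exp(2 * hi[nc + 2])))
    return out


def information_for_rho(theta_info: np.ndarray, jacobian: np.ndarray) -> np.ndarray:
    """Reparameterize an information matrix: ``I_rho = J^{-T} I J^{-1}``.

    ``jacobian`` is ``d rho / d theta`` (square).  Raises on singular J.
    """
    J = np.asarray(jacobian, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("jacobian must be square")
    try:
        Jinv = np.linalg.inv(J)
    except np.linalg.LinAlgError:
        raise ValueError("jacobian is singular") from None
    return Jinv.T @ theta_info @ Jinv


def _phi_to_rho(phi: np.ndarray, q: int, par: IOUParameterization) -> np.ndarray:
    """Exact coordinate map from the optimizer's (theta, sigma^2) to rho."""
    nc = q * (q + 1) // 2
    theta = ReducedTheta(phi[:nc + 2], q, par)
    vp = merge_sigma(theta, float(phi[nc + 2]))
    return to_unconstrained(vp, par)


def _jacobian_rho_phi(phi: np.ndarray, q: int, par: IOUParameterization) -> np.ndarray:
    """d rho / d phi by central differences of the exact coordinate map."""
    n = len(phi)
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(phi[j]))
        ep = phi.copy(); ep[j] += h
        em = phi.copy(); em[j] -= h
        J[:, j] = (_phi_to_rho(ep, q, par) - _phi_to_rho(em, q, par)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# Newton core and fit driver
# ---------------------------------------------------------------------------


def _newton_direction(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Descent direction from a (possibly indefinite) curvature matrix.

    A Marquardt-style ridge is added until the matrix factorizes, so a
    non-PD Hessian in a flat region degrades gracefully toward steepest
    descent instead of aborting the iteration.
    """
    try:
        np.linalg.cholesky(H)
        return -np.linalg.solve(H, g)
    except np.linalg.LinAlgError:
        pass
    scale = max(np.abs(np.diag(H)).max(), 1.0)
    lam = 1e-6 * scale
    for _ in range(20):
        try:
            np.linalg.cholesky(H + lam * np.eye(len(g)))
            return -np.linalg.solve(H + lam * np.eye(len(g)), g)
        except np.linalg.LinAlgError:
            lam *= 10.0
    return -g / scale


def newton_minimize(
    objective: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
    x0: np.ndarray,
    cfg: OptimizerConfig = OptimizerConfig(),
    info_fn: Callable[[np.ndarray, int], np.ndarray] | None = None,
) -> tuple[np.ndarray, OptState]:
    """Damped Newton minimization with step halving.

    ``objective(x)`` returns ``(f, gradient, hessian)``; an optional
    ``info_fn(x, iteration)`` overrides the curvature matrix (used for the
    FS/AI phases).  On an exactly quadratic objective a single full Newton
    step reaches the optimum and iteration 2 merely certifies it.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, g, H = objective(x)
    state = OptState(met_tolerance=False, n_iter=0, deviance_trace=[f])
    for it in range(1, cfg.max_iter + 1):
        state.n_iter = it
        Hcur = info_fn(x, it) if info_fn is not None else H
        step = _newton_direction(Hcur, g)
        accepted = False
        s = 1.0
        for _ in range(cfg.max_halvings + 1):
            try:
                f_new, g_new, H_new = objective(x + s * step)
            except (RemlDomainError, FloatingPointError):
                s *= 0.5
                continue
            if np.isfinite(f_new) and f_new <= f:
                accepted = True
                break
            s *= 0.5
        if not accepted:
            # cannot decrease along this direction; stationary or stuck
            scaled_g = np.abs(g) * np.maximum(1.0, np.abs(x)) / max(1.0, abs(f))
            if scaled_g.max() < cfg.tol_grad:
                state.met_tolerance = True
            else:
                state.hessian_failed = True
            break
        x = x + s * step
        rel_df = abs(f - f_new) / max(1.0, abs(f))
        f, g, H = f_new, g_new, H_new
        state.deviance_trace.append(f)
        scaled_g = np.abs(g) * np.maximum(1.0, np.abs(x)) / max(1.0, abs(f))
        if rel_df < cfg.tol_deviance and scaled_g.max() < cfg.tol_grad:
            state.met_tolerance = True
            break
    return x, state


@dataclass
class FitResult:
    """REML fit of the linear mixed IOU model."""

    variance: VarianceParams | None
    fixed: FixedEffects | None
    parameterization: IOUParameterization
    rho: np.ndarray | None
    se_rho: np.ndarray | None
    rho_labels: list[str]
    ci: dict[str, tuple[float, float]]
    converged: bool
    failure_reason: FailureReason
    n_iter: int
    neg2_remllik: float
    aic: float
    bic: float
    n_obs: int
    n_subjects: int
    deviance_trace: list[float] = field(default_factory=list)
    info_rho: np.ndarray | None = None

    @property
    def estimates(self) -> dict[str, float]:
        """Natural-scale point estimates keyed like the CI dict."""
        if self.variance is None:
            return {}
        vp = self.variance
        out: dict[str, float] = {}
        sd, corr = _g_to_sd_corr(vp.G)
        for i in range(vp.q):
            for j in range(i + 1):
                if i == j:
                    out[f"re_var_{i + 1}"] = float(vp.G[i, i])
                else:
                    out[f"re_corr_{i + 1}_{j + 1}"] = float(corr[i, j])
        out["alpha"] = vp.iou.alpha
        out[self.parameterization.amplitude_coord] = (
            vp.iou.omega if self.parameterization.amplitude_coord == "omega" else vp.iou.tau
        )
        out["sigma2"] = vp.sigma2
        return out


def fit(
    data: LongDataset,
    start: VarianceParams,
    cfg: OptimizerConfig = OptimizerConfig(),
    parameterization: IOUParameterization = IOUParameterization(),
) -> FitResult:
    """REML-fit the linear mixed IOU model.

    The model (fixed and random design) is carried by ``data``; ``start``
    gives natural-scale starting values.  Returns a :class:`FitResult`
    whether or not the optimizer converged.
    """
    engine = RemlEngine(data)
    theta0, _ = split_sigma(start, parameterization)
    q = data.q

    def objective(v: np.ndarray):
        th = ReducedTheta(v, q, parameterization)
        neg2, s2, grad, infos = engine.score_info(th, kinds=("observed",))
        return neg2, grad, infos["observed"]

    info_fn = None
    if cfg.algorithm in ("fs_then_nr", "ai_then_nr"):
        pre_kind = "expected" if cfg.algorithm == "fs_then_nr" else "average"

        def info_fn(v: np.ndarray, it: int) -> np.ndarray:
            th = ReducedTheta(v, q, parameterization)
            kind = pre_kind if it <= cfg.c else "observed"
            _, _, _, infos = engine.score_info(th, kinds=(kind,))
            return infos[kind]

    elif cfg.algorithm != "nr":
        raise ValueError(f"unknown algorithm {cfg.algorithm!r}")

    v_opt, state = newton_minimize(objective, theta0.vector, cfg, info_fn)

    theta_hat = ReducedTheta(v_opt, q, parameterization)
    try:
        ev = engine.evaluate(theta_hat)
        _, s2, phi_score, infos_full = engine.score_info(
            theta_hat, kinds=("observed",), reduce=False
        )
        phi = np.concatenate([v_opt, [s2]])
        J = _jacobian_rho_phi(phi, q, parameterization)  # d rho / d phi
        info_rho = information_for_rho(infos_full["observed"] / 2.0, J)
        vp_hat = merge_sigma(theta_hat, s2)
        fixed = FixedEffects(ev.beta_hat, ev.cov_beta, tuple(data.fixed_names))
        neg2 = ev.neg2_profiled_remllik
    except (RemlDomainError, np.linalg.LinAlgError):
        return FitResult(
            variance=None, fixed=None, parameterization=parameterization,
            rho=None, se_rho=None, rho_labels=rho_names(q, parameterization), ci={},
            converged=False, failure_reason="hessian_not_pd", n_iter=state.n_iter,
            neg2_remllik=np.nan, aic=np.nan, bic=np.nan,
            n_obs=data.n_obs, n_subjects=data.m, deviance_trace=state.deviance_trace,
        )

    converged, reason = classify_convergence(state, info_rho, cfg)
    rho_hat = to_unconstrained(vp_hat, parameterization)
    se_rho = None
    ci: dict[str, tuple[float, float]] = {}
    if converged:
        cov_rho = np.linalg.inv(info_rho)
        se_rho = np.sqrt(np.maximum(np.diag(cov_rho), 0.0))
        ci = natural_cis(rho_hat, se_rho, q, parameterization)
    k = data.p + len(phi)
    aic = neg2 + 2.0 * k
    bic = neg2 + k * np.log(data.n_obs)
    return FitResult(
        variance=vp_hat, fixed=fixed, parameterization=parameterization,
        rho=rho_hat, se_rho=se_rho, rho_labels=rho_names(q, parameterization), ci=ci,
        converged=converged, failure_reason=reason, n_iter=state.n_iter,
        neg2_remllik=neg2, aic=aic, bic=bic,
        n_obs=data.n_obs, n_subjects=data.m, deviance_trace=state.deviance_trace,
        info_rho=info_rho,
    )


def model_selection(fit_result: FitResult) -> tuple[float, float]:
    """(AIC, BIC) of a converged fit.

    Comparable only across models with identical fixed effects fitted to
    the same data (REML likelihoods are not comparable otherwise).
    """
    if not fit_result.converged:
        raise ValueError("model selection requires a converged fit")
    return fit_result.aic, fit_result.bic
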