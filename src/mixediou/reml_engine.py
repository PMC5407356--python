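"""Profiled restricted likelihood for the linear mixed IOU model.

Writing ``V_i = sigma^2 V*_i(theta)`` the residual variance has the closed
profile ``sigma2_hat = sum_i r_i' V*_i^{-1} r_i / (N - p)`` with GLS
residuals ``r_i``, and the objective minimized over ``theta`` is

    -2 l_p(theta) = (N - p) log sigma2_hat(theta) + sum_i log|V*_i|
                    + log|sum_i X_i' V*_i^{-1} X_i|   (+ constant)

The dropped constant is ``(N - p)(1 + log 2 pi)``; it is added back for the
reported REML deviance so AIC/BIC are comparable across this package's
models.

Derivatives are analytic.  The engine computes the score and the observed /
expected / average information of the *unprofiled* objective in the full
coordinates ``phi = (theta, sigma^2)`` using the standard REML identities
(``P = V^{-1} - V^{-1} X (X'V^{-1}X)^{-1} X'V^{-1}``)::

    score_j   = tr(P dV_j) - y'P dV_j P y
    H_obs_jk  = -tr(P dV_j P dV_k) + tr(P d2V_jk)
                + 2 y'P dV_j P dV_k P y - y'P d2V_jk P y
    I_exp_jk  = tr(P dV_j P dV_k)
    I_avg_jk  = y'P dV_j P dV_k P y        (the AI quadratic form)

and then profiles them to ``theta`` by a Schur complement over the
``sigma^2`` row/column — exact for the gradient and Hessian of the profiled
objective because the ``sigma^2`` score vanishes along the profile.

Everything is accumulated subject-by-subject; subjects sharing an identical
(times, X, Z) block are pooled through the sufficient statistics
``(m_g, sum y_i, sum y_i y_i')``, so balanced designs cost O(n^3) per
evaluation regardless of the number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .iou_cov import (
    iou_cov_matrix_d2alpha,
    iou_cov_matrix_dalpha,
    iou_cov_matrix_unit,
)
from .model_core import FixedEffects, LongDataset, ReducedTheta, chol_from_log_vector

__all__ = [
    "RemlDomainError",
    "RemlEvaluation",
    "RemlEngine",
    "gls_beta",
    "sigma2_profile",
    "neg2_profiled_remllik",
    "score_and_information",
]


class RemlDomainError(ValueError):
    """Parameter point outside the model's domain (non-PD V*, bad coords)."""


@dataclass
class RemlEvaluation:
    """Point evaluation of the profiled restricted likelihood."""

    neg2_profiled_remllik: float
    sigma2_hat: float
    beta_hat: np.ndarray
    cov_beta: np.ndarray
    residuals: list[np.ndarray]

    @property
    def deviance(self) -> float:
        """Full −2 restricted log-likelihood (constant added back)."""
        return self.neg2_profiled_remllik


@dataclass
class _Group:
    times: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    count: int
    S_y: np.ndarray
    S_yy: np.ndarray
    subject_idx: list[int]


def _build_groups(data: LongDataset) -> list[_Group]:
    groups: dict[bytes, _Group] = {}
    for i in range(data.m):
        t, X, Z, y = data.times[i], data.X[i], data.Z[i], data.y[i]
        key = t.tobytes() + b"|" + X.tobytes() + b"|" + Z.tobytes()
        g = groups.get(key)
        if g is None:
            groups[key] = _Group(t, X, Z, 1, y.copy(), np.outer(y, y), [i])
        else:
            g.count += 1
            g.S_y += y
            g.S_yy += np.outer(y, y)
            g.subject_idx.append(i)
    return list(groups.values())


def _check_design_rank(data: LongDataset) -> None:
    Xall = np.vstack(data.X)
    rank = np.linalg.matrix_rank(Xall)
    if rank < data.p:
        # name the offending columns via QR column norms
        _, R = np.linalg.qr(Xall)
        bad = [
            data.fixed_names[j] if j < len(data.fixed_names) else f"column {j}"
            for j in range(data.p)
            if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))
        ]
        raise ValueError(f"fixed-effect design is rank deficient; collinear: {bad}")


class RemlEngine:
    """Caches per-dataset structure; evaluates likelihood and derivatives."""

    def __init__(self, data: LongDataset):
        _check_design_rank(data)
        self.data = data
        self.groups = _build_groups(data)
        self.N = data.n_obs
        self.p = data.p
        self.q = data.q
        if self.N <= self.p:
            raise ValueError(f"N={self.N} observations cannot support p={self.p} fixed effects")
        self.constant = (self.N - self.p) * (1.0 + np.log(2.0 * np.pi))

    # -- V* and its derivatives per group -----------------------------------

    def _gstar_derivs(self, theta: ReducedTheta, order: int):
        """Cholesky factor of G* and first/second derivative matrices."""
        v = theta.vector[: theta.n_chol]
        q = theta.q
        L = chol_from_log_vector(v)
        idx = [(i, j) for i in range(q) for j in range(i + 1)]
        dLs = []
        for k, (i, j) in enumerate(idx):
            E = np.zeros((q, q))
            E[i, j] = L[i, j] if i == j else 1.0
            dLs.append(E)
        dGs = [dL @ L.T + L @ dL.T for dL in dLs]
        d2Gs = None
        if order >= 2:
            d2Gs = {}
            for k, (i, j) in enumerate(idx):
                for l in range(k, len(idx)):
                    il, jl = idx[l]
                    M = dLs[k] @ dLs[l].T + dLs[l] @ dLs[k].T
                    if k == l and i == j:
                        # diagonal entries are exp(v): d2L = dL
                        M = M + dLs[k] @ L.T + L @ dLs[k].T
                    d2Gs[(k, l)] = M
        return L, dGs, d2Gs

    def _vstar_blocks(self, theta: ReducedTheta, g: _Group, order: int):
        """V*, dV*/dtheta_j and (optionally) d2V* for one group.

        Returns (Vstar, [W_j for theta coords], {(j,k): U_jk}) where the
        second-derivative dict only holds nonzero upper-triangle entries.
        """
        par = theta.parameterization
        nc = theta.n_chol
        c = theta.vector[nc]
        a = theta.vector[nc + 1]
        if a <= 0:
            raise RemlDomainError(f"amplitude coordinate must be positive, got {a}")
        try:
            alpha = par.coord_to_alpha(c)
        except ValueError as e:
            raise RemlDomainError(str(e)) from None
        if not np.isfinite(alpha) or alpha <= 0:
            raise RemlDomainError(f"alpha out of domain: {alpha}")

        t = g.times
        n = t.size
        Gam0 = iou_cov_matrix_unit(t, alpha)
        L, dGs, d2Gs = self._gstar_derivs(theta, order)
        Gstar = L @ L.T
        if par.amplitude_coord == "omega":
            GamStar = a * Gam0
        else:
            GamStar = (a**2 / alpha**2) * Gam0
        V = g.Z @ Gstar @ g.Z.T + GamStar + np.eye(n)
        if order == 0:
            return V, None, None

        ap = par.dalpha_dcoord(c)
        Gam0p = iou_cov_matrix_dalpha(t, alpha)
        Ws = [g.Z @ dG @ g.Z.T for dG in dGs]
        if par.amplitude_coord == "omega":
            W_c = a * Gam0p * ap
            W_a = Gam0
        else:
            B = Gam0 / alpha**2
            Bp = Gam0p / alpha**2 - 2.0 * Gam0 / alpha**3
            W_c = a**2 * Bp * ap
            W_a = 2.0 * a * B
        Ws.extend([W_c, W_a])
        if order == 1:
            return V, Ws, None

        app = par.d2alpha_dcoord2(c)
        Gam0pp = iou_cov_matrix_d2alpha(t, alpha)
        U: dict[tuple[int, int], np.ndarray] = {}
        for (k, l), M in d2Gs.items():
            U[(k, l)] = g.Z @ M @ g.Z.T
        ic, ia = nc, nc + 1
        if par.amplitude_coord == "omega":
            U[(ic, ic)] = a * (Gam0pp * ap**2 + Gam0p * app)
            U[(ic, ia)] = Gam0p * ap
            # U[(ia, ia)] = 0
        else:
            Bpp = Gam0pp / alpha**2 - 4.0 * Gam0p / alpha**3 + 6.0 * Gam0 / alpha**4
            U[(ic, ic)] = a**2 * (Bpp * ap**2 + Bp * app)
            U[(ic, ia)] = 2.0 * a * Bp * ap
            U[(ia, ia)] = 2.0 * B
        return V, Ws, U

    # -- core evaluation -----------------------------------------------------

    def _base(self, theta: ReducedTheta):
        """Factor V* per group, GLS beta, profiled sigma^2, objective."""
        if theta.q != self.q:
            raise ValueError("theta dimension does not match the dataset's q")
        per = []
        logdet_sum = 0.0
        A = np.zeros((self.p, self.p))
        bvec = np.zeros(self.p)
        for g in self.groups:
            V, _, _ = self._vstar_blocks(theta, g, order=0)
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                raise RemlDomainError("V* is not positive definite at this theta") from None
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            Vinv = cho_solve(cf, np.eye(V.shape[0]))
            logdet_sum += g.count * logdet
            XtVi = g.X.T @ Vinv
            A += g.count * (XtVi @ g.X)
            bvec += XtVi @ g.S_y
            per.append((g, Vinv, XtVi))
        try:
            cfA = cho_factor(A, lower=True)
        except np.linalg.LinAlgError:
            raise RemlDomainError("X'V*^{-1}X singular; check design rank") from None
        beta = cho_solve(cfA, bvec)
        logdetA = 2.0 * np.sum(np.log(np.diag(cfA[0])))
        C = cho_solve(cfA, np.eye(self.p))
        rss = 0.0
        for g, Vinv, _ in per:
            mu = g.X @ beta
            rss += (
                float(np.einsum("ij,ji->", Vinv, g.S_yy))
                - 2.0 * float(mu @ (Vinv @ g.S_y))
                + g.count * float(mu @ (Vinv @ mu))
            )
        dof = self.N - self.p
        sigma2 = rss / dof
        if not np.isfinite(sigma2) or sigma2 <= 0:
            raise RemlDomainError("profiled sigma^2 is not positive (degenerate residuals)")
        neg2 = dof * np.log(sigma2) + logdet_sum + logdetA + self.constant
        return per, beta, C, sigma2, neg2

    def evaluate(self, theta: ReducedTheta) -> RemlEvaluation:
        per, beta, C, sigma2, neg2 = self._base(theta)
        residuals = [self.data.y[i] - self.data.X[i] @ beta for i in range(self.data.m)]
        return RemlEvaluation(
            neg2_profiled_remllik=float(neg2),
            sigma2_hat=float(sigma2),
            beta_hat=beta,
            cov_beta=sigma2 * C,
            residuals=residuals,
        )

    def score_info(
        self,
        theta: ReducedTheta,
        kinds: tuple[str, ...] = ("observed",),
        reduce: bool = True,
    ):
        """Gradient and information matrices at ``theta``.

        Returns ``(neg2, sigma2_hat, grad, {kind: info})``.  With
        ``reduce=True`` (default) the gradient and matrices are with respect
        to theta, sigma^2 profiled out by a Schur complement; with
        ``reduce=False`` they are in the full ``phi = (theta, sigma^2)``
        coordinates of the unprofiled objective, evaluated at the profiled
        sigma^2 (used for rho-scale standard errors).  ``kinds`` may include
        "observed", "expected", "average".
        """
        want_obs = "observed" in kinds
        order = 2 if want_obs else 1
        per, beta, C, s2, neg2 = self._base(theta)
        K = theta.n_chol + 2  # theta coords; index K is sigma^2
        nphi = K + 1

        trP = np.zeros(nphi)
        quadP = np.zeros(nphi)
        F = [np.zeros((self.p, self.p)) for _ in range(nphi)]
        vvec = [np.zeros(self.p) for _ in range(nphi)]
        trPP = np.zeros((nphi, nphi))
        quadPP = np.zeros((nphi, nphi))
        E_acc = [[np.zeros((self.p, self.p)) for _ in range(nphi)] for _ in range(nphi)]
        trPU = np.zeros((nphi, nphi))
        quadPU = np.zeros((nphi, nphi))
        FU = [[np.zeros((self.p, self.p)) for _ in range(nphi)] for _ in range(nphi)]
        u_pairs: list[tuple[int, int]] = []

        for g, Vinv, XtVi in per:
            V, Ws, U = self._vstar_blocks(theta, g, order=order)
            mu = g.X @ beta
            S_rr = g.S_yy - np.outer(g.S_y, mu) - np.outer(mu, g.S_y) + g.count * np.outer(mu, mu)
            ViS = Vinv @ S_rr
            ViX = Vinv @ g.X
            s_r = g.S_y - g.count * mu
            Vis_r = Vinv @ s_r
            Wfull = list(Ws) + [V]  # sigma^2 coordinate: starred dV = V*
            AW = [Vinv @ W for W in Wfull]
            XtViW = [XtVi @ W for W in Wfull]
            for j in range(nphi):
                trP[j] += g.count * np.trace(AW[j])
                F[j] += g.count * (XtViW[j] @ ViX)
                quadP[j] += float(np.einsum("ij,ji->", AW[j], ViS))
                vvec[j] += XtViW[j] @ Vis_r
                for k in range(j, nphi):
                    trPP[j, k] += g.count * float(np.einsum("ij,ji->", AW[j], AW[k]))
                    quadPP[j, k] += float(np.einsum("ij,jk,ki->", AW[j], AW[k], ViS))
                    E_acc[j][k] += g.count * (XtViW[j] @ (Vinv @ (Wfull[k] @ ViX)))
                    if k != j:
                        E_acc[k][j] += g.count * (XtViW[k] @ (Vinv @ (Wfull[j] @ ViX)))
            if want_obs and U:
                for (j, k), Um in U.items():
                    if (j, k) not in u_pairs:
                        u_pairs.append((j, k))
                    AU = Vinv @ Um
                    trPU[j, k] += g.count * np.trace(AU)
                    quadPU[j, k] += float(np.einsum("ij,ji->", AU, ViS))
                    FU[j][k] += g.count * ((XtVi @ Um) @ ViX)
                # (theta_j, sigma^2) cross second derivative: d2V = dV*_j
                for j in range(K):
                    if (j, K) not in u_pairs:
                        u_pairs.append((j, K))
                    trPU[j, K] += g.count * np.trace(AW[j])
                    quadPU[j, K] += float(np.einsum("ij,ji->", AW[j], ViS))
                    FU[j][K] += g.count * (XtViW[j] @ ViX)

        # close the P-matrix corrections through C
        for j in range(nphi):
            trP[j] -= float(np.einsum("ij,ji->", C, F[j]))
        for j in range(nphi):
            for k in range(j, nphi):
                t3 = float(np.einsum("ij,jk,kl,li->", C, F[j], C, F[k]))
                trPP[j, k] += -float(np.einsum("ij,ji->", C, E_acc[j][k])) - float(
                    np.einsum("ij,ji->", C, E_acc[k][j])
                ) + t3
                quadPP[j, k] -= float(vvec[j] @ (C @ vvec[k]))
                trPP[k, j] = trPP[j, k]
                quadPP[k, j] = quadPP[j, k]
        if want_obs:
            for (j, k) in u_pairs:
                trPU[j, k] -= float(np.einsum("ij,ji->", C, FU[j][k]))

        # assemble phi-scale score and information with sigma^2 powers
        e = np.array([1.0] * K + [0.0])
        score = np.empty(nphi)
        for j in range(nphi):
            score[j] = s2 ** (e[j] - 1) * trP[j] - s2 ** (e[j] - 2) * quadP[j]

        infos: dict[str, np.ndarray] = {}
        if "expected" in kinds or "average" in kinds or want_obs:
            Iexp = np.empty((nphi, nphi))
            Iavg = np.empty((nphi, nphi))
            for j in range(nphi):
                for k in range(nphi):
                    pw = e[j] + e[k]
                    Iexp[j, k] = s2 ** (pw - 2) * trPP[j, k]
                    Iavg[j, k] = s2 ** (pw - 3) * quadPP[j, k]
            if "expected" in kinds:
                infos["expected"] = Iexp
            if "average" in kinds:
                infos["average"] = Iavg
            if want_obs:
                Hobs = -Iexp + 2.0 * Iavg
                for (j, k) in u_pairs:
                    f = 1.0 if (j < K and k < K) else 0.0
                    corr = s2 ** (f - 1) * trPU[j, k] - s2 ** (f - 2) * quadPU[j, k]
                    Hobs[j, k] += corr
                    if j != k:
                        Hobs[k, j] += corr
                infos["observed"] = Hobs

        if not reduce:
            return float(neg2), float(s2), score, infos
        grad = score[:K]
        out: dict[str, np.ndarray] = {}
        for kind, M in infos.items():
            Mtt = M[:K, :K]
            Mts = M[:K, K]
            Mss = M[K, K]
            if abs(Mss) > 1e-300:
                out[kind] = Mtt - np.outer(Mts, Mts) / Mss
            else:
                out[kind] = Mtt
        return float(neg2), float(s2), grad, out


# ---------------------------------------------------------------------------
# Public operation wrappers
# ---------------------------------------------------------------------------


def gls_beta(theta: ReducedTheta, data: LongDataset) -> FixedEffects:
    """GLS fixed effects at ``theta`` with REML-profiled error variance."""
    ev = RemlEngine(data).evaluate(theta)
    return FixedEffects(ev.beta_hat, ev.cov_beta, tuple(data.fixed_names))


def sigma2_profile(theta: ReducedTheta, data: LongDataset) -> float:
    """Closed-form profiled residual variance at ``theta``."""
    return RemlEngine(data).evaluate(theta).sigma2_hat


def neg2_profiled_remllik(theta: ReducedTheta, data: LongDataset) -> float:
    """−2 profiled restricted log-likelihood (constant included)."""
    return RemlEngine(data).evaluate(theta).neg2_profiled_remllik


def score_and_information(theta: ReducedTheta, data: LongDataset, kind: str = "observed"):
    """Gradient and information matrix of the profiled objective.

    ``kind`` is one of "observed", "expected", "average".  The gradient
    matches central finite differences of :func:`neg2_profiled_remllik`;
    the observed matrix matches the finite-difference Hessian.
    """
    if kind not in ("observed", "expected", "average"):
        raise ValueError(f"unknown information kind {kind!r}")
    engine = RemlEngine(data)
    neg2, s2, grad, infos = engine.score_info(theta, kinds=(kind,))
    M = infos[kind]
    if not np.all(np.isfinite(M)) or not np.all(np.isfinite(grad)):
        bad = int(np.argmax(~np.isfinite(grad))) if not np.all(np.isfinite(grad)) else -1
        raise FloatingPointError(f"non-finite derivative entries (coordinate {bad})")
    return grad, M
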