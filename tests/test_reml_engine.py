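"""REML engine: likelihood, profile, derivatives vs independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar

from mixediou.iou_cov import IOUParameterization, IOUParams
from mixediou.model_core import (
    LongDataset,
    ReducedTheta,
    VarianceParams,
    marginal_cov,
    merge_sigma,
    split_sigma,
)
from mixediou.reml_engine import (
    RemlEngine,
    gls_beta,
    neg2_profiled_remllik,
    score_and_information,
    sigma2_profile,
)

PAR = IOUParameterization("alpha", "omega")


def theta_at(vp: VarianceParams, par=PAR) -> ReducedTheta:
    theta, _ = split_sigma(vp, par)
    return theta


def dense_neg2_unprofiled(theta: ReducedTheta, sigma2: float, data: LongDataset) -> float:
    """Independent dense-stacked oracle for the full -2 REML log-likelihood.

    Forms the whole N x N block-diagonal V and uses slogdet / solves; no
    per-subject factorization, no profiling.
    """
    vp = merge_sigma(theta, sigma2)
    N, p = data.n_obs, data.p
    blocks = [marginal_cov(data.times[i], vp, data.Z[i]) for i in range(data.m)]
    from scipy.linalg import block_diag

    V = block_diag(*blocks)
    X = np.vstack(data.X)
    y = np.concatenate(data.y)
    Vinv = np.linalg.inv(V)
    A = X.T @ Vinv @ X
    beta = np.linalg.solve(A, X.T @ Vinv @ y)
    r = y - X @ beta
    s, ld_V = np.linalg.slogdet(V)
    s2, ld_A = np.linalg.slogdet(A)
    return float(ld_V + ld_A + r @ Vinv @ r + (N - p) * np.log(2 * np.pi))


class TestGlsBeta:
    def test_near_identity_vstar_recovers_ols(self, irregular_data):
        vp = VarianceParams(np.array([[1e-10]]), IOUParams(1.0, 1e-10, "omega"), 1.0)
        fe = gls_beta(theta_at(vp), irregular_data)
        X = np.vstack(irregular_data.X)
        y = np.concatenate(irregular_data.y)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fe.beta, ols, rtol=1e-6)

    def test_matches_dense_gls_oracle(self, irregular_data):
        vp = VarianceParams(np.array([[0.3]]), IOUParams(1.3, 0.2, "omega"), 0.8)
        theta = theta_at(vp)
        fe = gls_beta(theta, irregular_data)
        # dense whole-dataset GLS with the same V*
        vp1 = merge_sigma(theta, 1.0)
        from scipy.linalg import block_diag

        V = block_diag(*[marginal_cov(irregular_data.times[i], vp1, irregular_data.Z[i])
                         for i in range(irregular_data.m)])
        X = np.vstack(irregular_data.X)
        y = np.concatenate(irregular_data.y)
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        np.testing.assert_allclose(fe.beta, beta, rtol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        t = np.array([0.0, 1.0, 2.0])
        X = np.column_stack([np.ones(3), t, 2 * t])
        data = LongDataset([0, 1], [t, t], [np.ones(3), np.zeros(3)], [X, X],
                           [np.ones((3, 1))] * 2, ["const", "time", "time2x"])
        vp = VarianceParams(np.array([[0.1]]), IOUParams(1.0, 0.1, "omega"), 0.1)
        with pytest.raises(ValueError, match="collinear"):
            gls_beta(theta_at(vp), data)


class TestSigma2Profile:
    def test_iid_limit_recovers_sample_variance(self):
        rng = np.random.default_rng(5)
        y = [rng.standard_normal(4) for _ in range(6)]
        t = np.arange(4.0)
        data = LongDataset(list(range(6)), [t] * 6, y,
                           [np.ones((4, 1))] * 6, [np.ones((4, 1))] * 6, ["const"])
        vp = VarianceParams(np.array([[1e-12]]), IOUParams(1.0, 1e-12, "omega"), 1.0)
        s2 = sigma2_profile(theta_at(vp), data)
        yall = np.concatenate(y)
        assert s2 == pytest.approx(yall.var(ddof=1), rel=1e-6)

    def test_matches_1d_numeric_maximization(self, irregular_data):
        vp = VarianceParams(np.array([[0.2]]), IOUParams(1.8, 0.3, "omega"), 1.0)
        theta = theta_at(vp)
        s2_hat = sigma2_profile(theta, irregular_data)
        res = minimize_scalar(
            lambda ls2: dense_neg2_unprofiled(theta, np.exp(ls2), irregular_data),
            bounds=(np.log(s2_hat) - 2, np.log(s2_hat) + 2), method="bounded",
            options={"xatol": 1e-10},
        )
        assert np.exp(res.x) == pytest.approx(s2_hat, rel=1e-5)


class TestProfiledObjective:
    def test_scale_equivariance_in_y(self, irregular_data):
        c = 2.5
        d = irregular_data
        scaled = LongDataset(d.ids, d.times, [c * yi for yi in d.y], d.X, d.Z, d.fixed_names)
        vp = VarianceParams(np.array([[0.15]]), IOUParams(2.0, 0.4, "omega"), 0.5)
        theta = theta_at(vp)
        f0 = neg2_profiled_remllik(theta, d)
        f1 = neg2_profiled_remllik(theta, scaled)
        N, p = d.n_obs, d.p
        assert f1 - f0 == pytest.approx(2 * (N - p) * np.log(c), rel=1e-10)

    def test_balanced_one_way_closed_form(self):
        # 3 subjects x 4 replicates, intercept only: compare to the scalar
        # closed-form REML deviance of the one-way random-effects model
        rng = np.random.default_rng(9)
        m, n = 3, 4
        t = np.array([0.0, 1.0, 2.0, 3.0])
        ys = [rng.normal(2.0, 1.0, n) + rng.normal(0, 0.7) for _ in range(m)]
        data = LongDataset(list(range(m)), [t] * m, ys, [np.ones((n, 1))] * m,
                           [np.ones((n, 1))] * m, ["const"])
        sigma_b2 = 0.4
        # IOU amplitude set to a negligible level: the model is then the
        # one-way layout up to O(1e-12)
        vp = VarianceParams(np.array([[sigma_b2]]), IOUParams(1.0, 1e-13, "omega"), 1.0)
        theta = theta_at(vp)
        ours = neg2_profiled_remllik(theta, data)
        s2 = sigma2_profile(theta, data)
        N = m * n
        sb2 = sigma_b2 * s2  # theta stores G* = G/sigma^2
        yall = np.concatenate(ys)
        gm = yall.mean()
        ybar = np.array([y.mean() for y in ys])
        ssw = sum(((y - yb) ** 2).sum() for y, yb in zip(ys, ybar))
        ssb = n * ((ybar - gm) ** 2).sum()
        lam = s2 + n * sb2
        closed = (
            m * (n - 1) * np.log(s2)
            + m * np.log(lam)
            + np.log(m * n / lam)
            + ssw / s2
            + ssb / lam
            + (N - 1) * np.log(2 * np.pi)
        )
        assert ours == pytest.approx(closed, rel=1e-9)

    def test_profiled_equals_dense_unprofiled_at_profile(self, irregular_data):
        vp = VarianceParams(np.array([[0.18]]), IOUParams(1.2, 0.25, "omega"), 0.7)
        theta = theta_at(vp)
        s2_hat = sigma2_profile(theta, irregular_data)
        ours = neg2_profiled_remllik(theta, irregular_data)
        dense = dense_neg2_unprofiled(theta, s2_hat, irregular_data)
        assert ours == pytest.approx(dense, rel=1e-10)

    def test_joint_optimization_equivalence(self, irregular_data):
        # minimizing the unprofiled objective over (theta, log sigma^2)
        # reaches the same optimum as profiled NR
        from mixediou.optimizers import OptimizerConfig, fit
        from mixediou.starting_values import strong_tracking_start

        start = strong_tracking_start(irregular_data).start
        res = fit(irregular_data, start, OptimizerConfig(), PAR)
        assert res.converged

        def unprofiled(v):
            try:
                th = ReducedTheta(v[:3], 1, PAR)
                return dense_neg2_unprofiled(th, np.exp(v[3]), irregular_data)
            except Exception:
                return 1e10

        theta_hat, s2_hat = split_sigma(res.variance, PAR)
        x0 = np.concatenate([theta_hat.vector, [np.log(s2_hat)]])
        opt = minimize(unprofiled, x0 + 0.05, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        assert res.neg2_remllik == pytest.approx(opt.fun, abs=1e-4)

    def test_subject_permutation_invariance(self, irregular_data):
        d = irregular_data
        order = list(reversed(range(d.m)))
        perm = LongDataset([d.ids[i] for i in order], [d.times[i] for i in order],
                           [d.y[i] for i in order], [d.X[i] for i in order],
                           [d.Z[i] for i in order], d.fixed_names)
        vp = VarianceParams(np.array([[0.2]]), IOUParams(1.5, 0.3, "omega"), 0.6)
        theta = theta_at(vp)
        assert neg2_profiled_remllik(theta, d) == pytest.approx(
            neg2_profiled_remllik(theta, perm), rel=1e-12
        )
        g0, H0 = score_and_information(theta, d, "observed")
        g1, H1 = score_and_information(theta, perm, "observed")
        np.testing.assert_allclose(g0, g1, rtol=1e-10)
        np.testing.assert_allclose(H0, H1, rtol=1e-10)


class TestDerivatives:
    @pytest.mark.parametrize("par", [
        IOUParameterization("alpha", "omega"),
        IOUParameterization("log_alpha", "tau"),
        IOUParameterization("inv_alpha", "omega"),
        IOUParameterization("inv_alpha", "tau"),
    ])
    def test_gradient_matches_central_differences(self, irregular_data, par):
        vp = VarianceParams(np.array([[0.1]]), IOUParams(1.7, 0.04, "omega"), 0.05)
        theta, _ = split_sigma(vp, par)
        grad, _ = score_and_information(theta, irregular_data, "observed")
        v0 = theta.vector
        h = 1e-5
        for j in range(len(v0)):
            e = np.zeros(len(v0))
            e[j] = h
            fd = (
                neg2_profiled_remllik(ReducedTheta(v0 + e, 1, par), irregular_data)
                - neg2_profiled_remllik(ReducedTheta(v0 - e, 1, par), irregular_data)
            ) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_observed_info_matches_fd_hessian(self, irregular_data):
        par = PAR
        vp = VarianceParams(np.array([[0.1]]), IOUParams(1.7, 0.04, "omega"), 0.05)
        theta, _ = split_sigma(vp, par)
        _, H = score_and_information(theta, irregular_data, "observed")
        v0 = theta.vector
        h = 1e-3

        def f(v):
            return neg2_profiled_remllik(ReducedTheta(v, 1, par), irregular_data)

        K = len(v0)
        fd = np.zeros((K, K))
        for j in range(K):
            ej = np.zeros(K); ej[j] = h
            for k in range(K):
                ek = np.zeros(K); ek[k] = h
                fd[j, k] = (f(v0+ej+ek) - f(v0+ej-ek) - f(v0-ej+ek) + f(v0-ej-ek)) / (4*h*h)
        assert np.abs(H - fd).max() / max(1.0, np.abs(fd).max()) < 1e-4

    def test_expected_info_is_psd_on_random_instances(self):
        from conftest import make_irregular_dataset

        rng = np.random.default_rng(21)
        for trial in range(10):
            data, _ = make_irregular_dataset(seed=100 + trial)
            vp = VarianceParams(
                np.array([[float(rng.uniform(0.05, 0.5))]]),
                IOUParams(float(rng.uniform(0.3, 4.0)), float(rng.uniform(0.02, 0.5)), "omega"),
                float(rng.uniform(0.02, 0.3)),
            )
            _, Ie = score_and_information(theta_at(vp), data, "expected")
            eig = np.linalg.eigvalsh(Ie)
            assert eig[0] >= -1e-8 * max(eig[-1], 1.0)

    def test_average_between_observed_and_expected_at_optimum(self, irregular_data):
        from mixediou.optimizers import OptimizerConfig, fit
        from mixediou.starting_values import strong_tracking_start

        res = fit(irregular_data, strong_tracking_start(irregular_data).start)
        assert res.converged
        theta, _ = split_sigma(res.variance, PAR)
        _, Ho = score_and_information(theta, irregular_data, "observed")
        _, He = score_and_information(theta, irregular_data, "expected")
        _, Ha = score_and_information(theta, irregular_data, "average")
        scale = np.abs(He).max()
        assert np.abs(Ha - (Ho + He) / 2).max() < 0.3 * scale

    def test_gradient_near_zero_at_optimum(self, irregular_data):
        from mixediou.optimizers import fit
        from mixediou.starting_values import strong_tracking_start

        res = fit(irregular_data, strong_tracking_start(irregular_data).start)
        assert res.converged
        theta, _ = split_sigma(res.variance, PAR)
        g, _ = score_and_information(theta, irregular_data, "observed")
        assert np.abs(g).max() < 1e-4 * (1 + abs(res.neg2_remllik))


class TestParameterRecovery:
    def test_estimates_within_three_ses_of_truth(self):
        """Moderate-tracking balanced study: REML recovers the generating
        variance parameters to within three standard errors."""
        from mixediou.optimizers import fit
        from mixediou.simulator import BalancedDesign, gen_balanced, tracking_truth
        from mixediou.starting_values import empirical_start

        truth = tracking_truth("moderate")
        data = gen_balanced(BalancedDesign(200, 10, 3.0), truth, 314159)
        res = fit(data, empirical_start(data).start)
        assert res.converged
        # rho-scale |z| < 3 for sigma_b^2, omega, sigma^2
        from mixediou.optimizers import to_unconstrained

        rho_truth = to_unconstrained(truth.variance, PAR)
        for idx in (0, 2, 3):  # log sd_b, log omega, log sigma
            z = (res.rho[idx] - rho_truth[idx]) / res.se_rho[idx]
            assert abs(z) < 3.0, (idx, z)
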