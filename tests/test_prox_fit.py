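"""Proximal operator and the penalized pseudolikelihood fit."""

import numpy as np
import pytest
from scipy import optimize

from mgmsteps.core import (FitConfig, MGMParameters, MixedDataset,
                           PenaltyWeights, _layout_for, adjacency_from_parameters,
                           fit_mgm, negative_log_pseudolikelihood, penalty_value,
                           proximal_step)
from conftest import random_dataset, random_params


class TestProximalStep:
    def test_scalar_soft_threshold(self):
        params = MGMParameters.zeros(2, ())
        params.beta[0, 1] = params.beta[1, 0] = 1.0
        out = proximal_step(params, MGMParameters.zeros(2, ()), 1.0,
                            PenaltyWeights(0.4, 0, 0))
        # the zero-gradient step leaves 1.0, thresholded at 0.4 -> 0.6
        assert out.beta[0, 1] == pytest.approx(0.6)
        assert out.beta[1, 0] == pytest.approx(0.6)

    def test_group_inside_threshold_becomes_exact_zero(self):
        params = MGMParameters.zeros(1, (4,))
        params.rho[0] = [0.15, -0.15, 0.15, -0.15]  # norm 0.3
        out = proximal_step(params, MGMParameters.zeros(1, (4,)), 1.0,
                            PenaltyWeights(0, 0.5, 0))
        assert np.all(out.rho == 0.0)

    def test_group_outside_threshold_shrinks_radially(self):
        params = MGMParameters.zeros(1, (4,))
        params.rho[0] = [1.0, -1.0, 1.0, -1.0]  # norm 2
        out = proximal_step(params, MGMParameters.zeros(1, (4,)), 1.0,
                            PenaltyWeights(0, 0.5, 0))
        assert np.allclose(out.rho[0], 0.75 * params.rho[0])

    def test_unpenalized_parts_untouched_and_symmetry_restored(self, rng):
        params = random_params(3, (2, 3), rng)
        grad = random_params(3, (2, 3), rng, scale=0.1)
        grad.beta[np.diag_indices(3)] = 0.0
        out = proximal_step(params, grad, 0.5, PenaltyWeights(0.1, 0.1, 0.1))
        assert np.allclose(out.beta, out.beta.T)
        assert np.allclose(out.phi, out.phi.T)
        # sum-to-zero projection holds for every penalized block
        for s in range(3):
            for j in range(2):
                assert out.rho_block(s, j).sum() == pytest.approx(0.0, abs=1e-12)
        blk = out.phi_block(0, 1)
        assert np.allclose(blk.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(blk.sum(axis=1), 0.0, atol=1e-12)

    def test_nonpositive_step_rejected(self, small_params):
        with pytest.raises(ValueError):
            proximal_step(small_params, small_params, 0.0, PenaltyWeights(1, 1, 1))


def kkt_residual(params, data, pw):
    """Max violation of the subgradient optimality conditions on the
    sum-to-zero subspace (independent check of the fit's fixed point)."""
    from mgmsteps.core import _apply_standardizer, _grad_to_vec, _nlpl_arrays
    layout = _layout_for(params.p, params.levels)
    X, _ = _apply_standardizer(params, data)
    D = data.indicator()
    v = layout.pack(params)
    beta, alpha, R, Phi_off, phidiag = layout.unpack(v)
    _, grads = _nlpl_arrays(beta, alpha, R, Phi_off, phidiag, X, D, data.Y,
                            layout.offs, want_grad=True)
    g = _grad_to_vec(grads, layout, data.n)
    res = [np.abs(g[layout.s_bdiag]).max(), np.abs(g[layout.s_alpha]).max(),
           np.abs(g[layout.s_phidiag]).max() if layout.q else 0.0]
    b = v[layout.s_boff]
    gb = g[layout.s_boff]
    active = np.abs(b) > 0
    if active.any():
        res.append(np.abs(gb[active] + pw.lambda_cc * np.sign(b[active])).max())
    if (~active).any():
        res.append(max(0.0, np.abs(gb[~active]).max() - pw.lambda_cc))
    rho = v[layout.s_rho].reshape(layout.p, layout.Q)
    grho = g[layout.s_rho].reshape(layout.p, layout.Q)
    for s in range(layout.p):
        for j in range(layout.q):
            sl = slice(layout.offs[j], layout.offs[j + 1])
            blk, gblk = rho[s, sl], grho[s, sl]
            nrm = np.linalg.norm(blk)
            if nrm > 0:
                res.append(np.abs(gblk + pw.lambda_cd * blk / nrm).max())
            else:
                res.append(max(0.0, np.linalg.norm(gblk) - pw.lambda_cd))
    for k, (r, j) in enumerate(layout.pairs):
        sl = slice(layout.phi_bounds[k], layout.phi_bounds[k + 1])
        blk, gblk = v[layout.s_phioff][sl], g[layout.s_phioff][sl]
        nrm = np.linalg.norm(blk)
        if nrm > 0:
            res.append(np.abs(gblk + pw.lambda_dd * blk / nrm).max())
        else:
            res.append(max(0.0, np.linalg.norm(gblk) - pw.lambda_dd))
    return max(res)


class TestFit:
    def test_huge_penalty_gives_empty_graph(self, rng):
        data = random_dataset(40, 3, (2, 4), rng)
        fit = fit_mgm(data, PenaltyWeights.single(1e6))
        assert not adjacency_from_parameters(fit).any()
        assert np.all(np.diag(fit.beta) > 0)
        # alpha, beta diagonal and phi_rr survive as free parameters
        assert np.all(fit.rho == 0.0)

    def test_gaussian_closed_form_recovery(self, rng):
        """With q=0 and no penalty the pseudolikelihood optimum matches the
        inverse sample covariance of the standardized data within 2%."""
        cov = np.array([[1.0, 0.6], [0.6, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=5000)
        data = MixedDataset(X, np.zeros((5000, 0), dtype=int), ())
        fit = fit_mgm(data, PenaltyWeights.single(0.0),
                      FitConfig(tol=1e-10, max_iter=2000))
        Z = (X - X.mean(0)) / X.std(0)
        prec = np.linalg.inv(np.cov(Z.T, bias=True))
        assert np.abs(fit.beta - prec).max() / np.abs(prec).max() < 0.02

    def test_matches_derivative_free_optimizer(self, rng):
        """On a tiny instance the fit objective is at least as good as a
        generic direct-search optimizer run on the same (subspace-reduced)
        objective."""
        data = random_dataset(50, 2, (2,), rng)
        pw = PenaltyWeights(0.1, 0.1, 0.1)
        cfg = FitConfig(tol=1e-10, max_iter=3000)
        fit = fit_mgm(data, pw, cfg)
        layout = _layout_for(2, (2,))

        # orthonormal basis of the sum-to-zero subspace for the rho blocks
        basis = []
        eye = np.eye(layout.size)
        for i in range(layout.size):
            if layout.s_rho.start <= i < layout.s_rho.stop:
                continue
            basis.append(eye[i])
        for s in range(2):
            vec = np.zeros(layout.size)
            sl = layout.s_rho
            rho = np.zeros((2, 2))
            rho[s] = [1 / np.sqrt(2), -1 / np.sqrt(2)]
            vec[sl] = rho.ravel()
            basis.append(vec)
        B = np.array(basis).T

        Xs = (data.X - data.X.mean(0)) / data.X.std(0)
        sdata = MixedDataset(Xs, data.Y, data.levels)

        def objective(coef):
            v = B @ coef
            if np.any(v[layout.s_bdiag] <= 1e-4):
                return 1e10
            params = layout.to_params(v)
            return float(negative_log_pseudolikelihood(params, sdata)) / data.n \
                + penalty_value(params, pw)

        x0 = np.zeros(B.shape[1])
        x0[:2] = 1.0  # beta diagonal entries come first in the layout
        res = optimize.minimize(objective, x0, method="Powell",
                                options={"maxiter": 20000, "xtol": 1e-10,
                                         "ftol": 1e-12})
        ours = fit.fit_info["objective"]
        assert ours <= res.fun + 1e-4

    def test_kkt_residual_small_on_tiny_instance(self, rng):
        data = random_dataset(60, 3, (2, 3), rng)
        pw = PenaltyWeights(0.08, 0.08, 0.08)
        fit = fit_mgm(data, pw, FitConfig(tol=1e-12, max_iter=5000))
        assert kkt_residual(fit, data, pw) < 1e-4

    def test_group_sparsity_is_exact(self, rng):
        data = random_dataset(60, 4, (3, 3), rng)
        fit = fit_mgm(data, PenaltyWeights.single(0.15))
        layout = _layout_for(4, (3, 3))
        for s in range(4):
            for j in range(2):
                nrm = np.linalg.norm(fit.rho_block(s, j))
                assert nrm == 0.0 or nrm > 1e-10
        nrm = np.linalg.norm(fit.phi_block(0, 1))
        assert nrm == 0.0 or nrm > 1e-10

    def test_objective_invariant_to_sample_permutation(self, rng):
        data = random_dataset(40, 2, (3,), rng)
        f1 = fit_mgm(data, PenaltyWeights.single(0.1))
        f2 = fit_mgm(data.subset(rng.permutation(data.n)),
                     PenaltyWeights.single(0.1))
        assert f1.fit_info["objective"] == pytest.approx(
            f2.fit_info["objective"], rel=1e-9)

    def test_too_few_samples_rejected(self, rng):
        data = random_dataset(1, 2, (), rng)
        with pytest.raises(ValueError):
            fit_mgm(data, PenaltyWeights.single(0.1))

    def test_reports_termination_status(self, rng):
        data = random_dataset(30, 2, (2,), rng)
        fit = fit_mgm(data, PenaltyWeights.single(0.2), FitConfig(max_iter=2))
        assert fit.fit_info["status"] in ("converged", "max_iter")
        fit2 = fit_mgm(data, PenaltyWeights.single(0.2))
        assert fit2.fit_info["status"] == "converged"
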