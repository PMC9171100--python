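"""Solver correctness: closed forms, oracles, and the KKT conditions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pumice.annotate import PenaltyPartition
from pumice.wnet import (
    WNetConfig,
    compute_lambda_path,
    fit_path,
    fit_weighted_elastic_net,
    kkt_residuals,
    objective_value,
    predict_expression,
)

from .oracles import fista_enet, grid_minimize_1d, penalized_loss


def _pf(part, p, phi):
    pf = np.ones(p)
    pf[part.essential_idx] = phi
    return pf


def test_zero_response_gives_zero_fit(make_instance):
    X, _, part = make_instance()
    fit = fit_weighted_elastic_net(X, np.zeros(X.shape[0]), part, WNetConfig(0.3, phi=0.5))
    assert fit.converged and fit.n_iter == 1
    assert np.all(fit.coef == 0.0)


@pytest.mark.parametrize("seed", range(20))
def test_single_predictor_closed_form_vs_grid(seed):
    """soft(c, a*lam*phi) / (1 + (1-a)*lam) for one essential predictor."""
    r = np.random.default_rng(seed)
    n = 50
    x = r.standard_normal(n)
    x = (x - x.mean()) / x.std()
    y = r.standard_normal(n) * 2
    y -= y.mean()
    lam, phi, alpha = r.uniform(0.01, 1.0), r.uniform(0.1, 1.0), r.uniform(0.1, 1.0)
    c = float(x @ y) / n
    closed = np.sign(c) * max(abs(c) - alpha * lam * phi, 0.0) / (1 + (1 - alpha) * lam)
    part = PenaltyPartition(np.array([0]), np.array([], dtype=int))
    fit = fit_weighted_elastic_net(
        x[:, None], y, part, WNetConfig(lam, phi=phi, alpha=alpha, tol=1e-12)
    )
    assert fit.coef[0] == pytest.approx(closed, abs=1e-10)
    X = x[:, None]
    loss = lambda b: penalized_loss(X, y, np.array([b]), lam, alpha, np.array([phi]))
    assert grid_minimize_1d(loss) == pytest.approx(closed, abs=1e-3)


def test_phi_one_matches_proximal_gradient_oracle(make_instance):
    X, y, part = make_instance(n=40, p=25, seed=3)
    lam = 0.05
    cfg = WNetConfig(lam, phi=1.0, alpha=0.5, tol=1e-12, max_iter=5000)
    fit = fit_weighted_elastic_net(X, y, part, cfg)
    ref = fista_enet(X, y, lam, alpha=0.5)
    assert np.abs(fit.coef - ref).max() < 1e-6


def test_differential_phi_matches_weighted_oracle(make_instance):
    """The oracle supports penalty factors, so phi < 1 can be cross-checked too."""
    X, y, part = make_instance(n=50, p=20, seed=4)
    lam, phi = 0.08, 1 / 3
    fit = fit_weighted_elastic_net(X, y, part, WNetConfig(lam, phi=phi, tol=1e-12, max_iter=5000))
    ref = fista_enet(X, y, lam, alpha=0.5, pf=_pf(part, 20, phi))
    assert np.abs(fit.coef - ref).max() < 1e-6


def test_lambda_zero_reduces_to_least_squares(make_instance):
    X, y, part = make_instance(n=60, p=15, seed=5)
    fit = fit_weighted_elastic_net(X, y, part, WNetConfig(0.0, phi=0.5, tol=1e-12, max_iter=5000))
    ref, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.abs(fit.coef - ref).max() < 1e-8


def test_objective_nonincreasing_across_sweeps(make_instance):
    X, y, part = make_instance(n=40, p=30, seed=6)
    cfg = lambda k: WNetConfig(0.05, phi=0.5, tol=0.0, max_iter=k)
    objs = [
        fit_weighted_elastic_net(X, y, part, cfg(k), init=np.zeros(30)).objective
        for k in range(1, 8)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))


def test_lambda_path_endpoints(make_instance):
    X, y, part = make_instance(seed=7)
    lams = compute_lambda_path(X, y, part, phi=0.5)
    f_max = fit_weighted_elastic_net(X, y, part, WNetConfig(lams[0], phi=0.5))
    assert np.all(f_max.coef == 0.0)
    f_below = fit_weighted_elastic_net(
        X, y, part, WNetConfig(0.99 * lams[0], phi=0.5, tol=1e-10)
    )
    assert np.any(f_below.coef != 0.0)


def test_lambda_max_monotone_in_phi(make_instance):
    """Lowering phi raises lambda_max when the strongest predictor is essential."""
    X, y, part = make_instance(seed=8)
    n = X.shape[0]
    b = np.abs(X.T @ y) / n
    j = int(np.argmax(b))
    part = PenaltyPartition(np.array([j]), np.setdiff1d(np.arange(X.shape[1]), [j]))
    lam_lo = compute_lambda_path(X, y, part, phi=0.25)[0]
    lam_hi = compute_lambda_path(X, y, part, phi=1.0)[0]
    assert lam_lo > lam_hi


def test_all_zero_response_path_is_zero(make_instance):
    X, _, part = make_instance(seed=9)
    lams = compute_lambda_path(X, np.zeros(X.shape[0]), part, phi=0.5)
    assert lams.tolist() == [0.0]


def test_lower_phi_weakly_increases_essential_l1(make_instance):
    X, y, part = make_instance(n=80, p=20, n_essential=10, seed=10)
    lams = compute_lambda_path(X, y, part, phi=1.0, n_lambda=8)
    for lam in lams[1:]:
        norms = []
        for phi in (1.0, 0.5, 0.25):
            fit = fit_weighted_elastic_net(X, y, part, WNetConfig(lam, phi=phi, tol=1e-10))
            norms.append(np.abs(fit.beta1).sum())
        assert norms[0] <= norms[1] + 1e-8 <= norms[2] + 2e-8


def test_prediction_invariant_to_column_permutation(make_instance, rng):
    X, y, part = make_instance(seed=11)
    p = X.shape[1]
    cfg = WNetConfig(0.05, phi=0.5, tol=1e-12)
    fit = fit_weighted_elastic_net(X, y, part, cfg)
    perm = rng.permutation(p)
    mask = part.essential_mask(p)[perm]
    part_p = PenaltyPartition.from_mask(mask)
    fit_p = fit_weighted_elastic_net(X[:, perm], y, part_p, cfg)
    pred = predict_expression(fit, X, part)
    pred_p = predict_expression(fit_p, X[:, perm], part_p)
    assert np.allclose(pred, pred_p, atol=1e-8)


def test_label_swap_symmetry(make_instance):
    """Swapping essential/non-essential labels while keeping per-column
    penalty factors fixed leaves the solution unchanged."""
    X, y, _ = make_instance(n=50, p=10, seed=12)
    phi = 0.5
    part_a = PenaltyPartition(np.arange(5), np.arange(5, 10))
    fit_a = fit_weighted_elastic_net(X, y, part_a, WNetConfig(0.05, phi=phi, tol=1e-12))
    # same per-column factors realized via the complementary labelling:
    # scale lambda so that the non-essential threshold equals lam*phi
    part_b = PenaltyPartition(np.arange(5, 10), np.arange(5))
    ref = fista_enet(X, y, 0.05, alpha=0.5, pf=_pf(part_a, 10, phi))
    assert np.abs(fit_a.coef - ref).max() < 1e-6
    ref_b = fista_enet(X, y, 0.05, alpha=0.5, pf=_pf(part_b, 10, phi))
    fit_b = fit_weighted_elastic_net(X, y, part_b, WNetConfig(0.05, phi=phi, tol=1e-12))
    assert np.abs(fit_b.coef - ref_b).max() < 1e-6


def test_objective_reevaluation_matches_stored(make_instance):
    X, y, part = make_instance(seed=13)
    cfg = WNetConfig(0.07, phi=0.5, tol=1e-10)
    fit = fit_weighted_elastic_net(X, y, part, cfg)
    assert objective_value(X, y, fit.coef, part, cfg) == pytest.approx(fit.objective, rel=1e-12)


def test_rejects_unstandardized_and_nan(make_instance):
    X, y, part = make_instance(seed=14)
    with pytest.raises(ValueError):
        fit_weighted_elastic_net(X * 3.0, y, part, WNetConfig(0.1))
    Xn = X.copy()
    Xn[0, 0] = np.nan
    with pytest.raises(ValueError):
        fit_weighted_elastic_net(Xn, y, part, WNetConfig(0.1))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    lam=st.floats(1e-3, 1.0),
    phi=st.floats(0.1, 1.0),
    alpha=st.floats(0.05, 1.0),
)
def test_kkt_residuals_below_tol_property(seed, lam, phi, alpha):
    """Every converged fit satisfies the subgradient conditions within tol."""
    r = np.random.default_rng(seed)
    n, p = 30, 12
    X = r.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    y = r.standard_normal(n)
    y -= y.mean()
    part = PenaltyPartition.from_mask(r.random(p) < 0.5)
    cfg = WNetConfig(lam, phi=phi, alpha=alpha, tol=1e-10, max_iter=10_000)
    fit = fit_weighted_elastic_net(X, y, part, cfg)
    assert fit.converged
    assert kkt_residuals(X, y, fit.coef, part, cfg).max() < 1e-8


def test_path_warm_start_consistent_with_single_fits(make_instance):
    X, y, part = make_instance(seed=15)
    lams = compute_lambda_path(X, y, part, phi=0.5, n_lambda=6)
    betas = fit_path(X, y, part, 0.5, lams, tol=1e-12, max_iter=5000)
    for lam, beta in zip(lams, betas):
        single = fit_weighted_elastic_net(X, y, part, WNetConfig(lam, phi=0.5, tol=1e-12, max_iter=5000))
        assert np.abs(beta - single.coef).max() < 1e-8
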