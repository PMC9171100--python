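"""Independent reference implementations used only to check the package.

These deliberately avoid the coordinate-descent code path: the elastic-net
oracle is an accelerated proximal-gradient (FISTA) solver, and the
one-dimensional oracle is a brute grid minimizer of the penalized loss.
"""

import numpy as np


def penalized_loss(X, y, beta, lam, alpha, pf):
    """(1/2N)||y - Xb||^2 + lam * sum_j [alpha*pf_j*|b_j| + ((1-alpha)/2) b_j^2]."""
    n = X.shape[0]
    r = y - X @ beta
    return (
        0.5 * (r @ r) / n
        + lam * alpha * float(pf @ np.abs(beta))
        + lam * (1 - alpha) * 0.5 * float(beta @ beta)
    )


def fista_enet(X, y, lam, alpha=0.5, pf=None, max_iter=20000, tol=1e-12):
    """Proximal-gradient (FISTA) minimizer of the same penalized loss.

    The smooth part is the quadratic + ridge term; the L1 part enters via
    its proximal operator (soft threshold scaled by the step size).
    """
    n, p = X.shape
    pf = np.ones(p) if pf is None else np.asarray(pf, dtype=float)
    C = X.T @ X / n
    b = X.T @ y / n
    L = np.linalg.eigvalsh(C).max() + lam * (1 - alpha)
    step = 1.0 / L
    beta = np.zeros(p)
    zeta = beta.copy()
    t = 1.0
    for _ in range(max_iter):
        grad = C @ zeta - b + lam * (1 - alpha) * zeta
        x = zeta - step * grad
        thr = step * lam * alpha * pf
        beta_new = np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)
        t_new = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        zeta = beta_new + ((t - 1) / t_new) * (beta_new - beta)
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            break
        beta, t = beta_new, t_new
    return beta


def grid_minimize_1d(loss, lo=-5.0, hi=5.0, n_coarse=2001, refine=3):
    """Brute-force 1-D minimizer with successive grid refinement."""
    for _ in range(refine):
        grid = np.linspace(lo, hi, n_coarse)
        vals = np.array([loss(b) for b in grid])
        i = int(np.argmin(vals))
        lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    return 0.5 * (lo + hi)


def brute_point_in_intervals(pos, intervals):
    """O(n*m) membership scan: is `pos` inside any 1-based closed interval."""
    return any(s <= pos <= e for s, e in intervals)
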