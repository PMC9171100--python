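"""Nested cross-validation over (window, phi, lambda) and model assessment.

The outer 5-fold loop measures out-of-sample Spearman correlation; within
each outer training fold an inner 5-fold CV picks the (cis-window, phi,
lambda) triple minimizing mean squared prediction error. The deployed model
is refit on all samples with the triple selected by inner CV on the full
data. Per-fold correlations are combined into a model p-value by Stouffer's
method with z_k = r_k * sqrt(n_k - 1).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import CisWindow, EmptyWindowError, PenaltyPartition, subset_cis_variants
from .containers import Gene, GenotypeMatrix
from .wnet import compute_lambda_path, fit_path, fit_weighted_elastic_net, WNetConfig

logger = logging.getLogger("pumice")

DEFAULT_PHI_GRID = tuple(k / 6 for k in range(1, 7))


@dataclass
class TrainedModel:
    """Deployed expression prediction model for one (gene, tissue)."""

    gene_id: str
    tissue: str
    selected_w: str
    selected_phi: float
    selected_lambda: float
    weights: dict  # variant_id -> (ref, alt, weight on standardized dosages)
    cv_r: float
    cv_p: float
    significant: bool
    seed: int | None = None

    def beta_for(self, variant_ids) -> np.ndarray:
        return np.array([self.weights.get(v, ("N", "N", 0.0))[2] for v in variant_ids])


@dataclass
class CVReport:
    """Outer-fold performance and the inner-CV selection table."""

    fold_r: list
    fold_sizes: list
    inner_cv: pd.DataFrame  # window, phi, lambda, mse (full-data inner CV)


def _fold_rng(seed: int, sample_ids) -> np.random.Generator:
    # fold assignment must be a deterministic function of (seed, sample IDs)
    tag = zlib.crc32("\x00".join(map(str, sample_ids)).encode())
    return np.random.default_rng([int(seed) % (2**31), tag])


def _kfold(n: int, k: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def _standardize_train(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _spearman(pred, truth) -> float:
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        return 0.0
    r = stats.spearmanr(pred, truth).statistic
    return 0.0 if not np.isfinite(r) else float(r)


def _inner_cv_select(
    X, E, windows_cols, essential_mask, phi_grid, n_inner, rng,
    alpha, n_lambda, lambda_min_ratio, tol, max_iter,
):
    """Pick (window, phi, lambda) minimizing mean inner-CV MSE.

    ``windows_cols`` maps window kind -> column indices into X. Returns
    (kind, phi, lambda, table) where table holds the per-combination MSEs.
    """
    from .wnet import _cd_path, _penalty_factors

    n = X.shape[0]
    folds = _kfold(n, n_inner, rng)
    best = None
    rows = []
    for kind, cols in windows_cols.items():
        Xw = X[:, cols]
        p = Xw.shape[1]
        part = PenaltyPartition.from_mask(essential_mask[cols])
        Xs_full, _, _ = _standardize_train(Xw)
        Ec_full = E - E.mean()
        # per-fold covariance statistics, shared across the phi grid
        fold_stats = []
        for val_idx in folds:
            tr_mask = np.ones(n, dtype=bool)
            tr_mask[val_idx] = False
            Xtr, mu, sd = _standardize_train(Xw[tr_mask])
            Etr = E[tr_mask]
            Ec = Etr - Etr.mean()
            n_tr = Xtr.shape[0]
            C = np.ascontiguousarray(Xtr.T @ Xtr) / n_tr
            b = (Xtr.T @ Ec) / n_tr
            beta0 = (np.linalg.pinv(Xtr) @ Ec) if p <= n_tr else np.zeros(p)
            Xval = (Xw[val_idx] - mu) / sd
            fold_stats.append((C, b, beta0, Xval, E[val_idx] - Etr.mean()))
        for phi in phi_grid:
            lambdas = compute_lambda_path(
                Xs_full, Ec_full, part, phi, alpha, n_lambda, lambda_min_ratio
            )
            pf = _penalty_factors(part, p, phi)
            mse = np.zeros(len(lambdas))
            for C, b, beta0, Xval, Eval_c in fold_stats:
                betas = _cd_path(C, b, pf, lambdas, alpha, beta0, tol, max_iter)
                resid = Xval @ betas.T - Eval_c[:, None]
                mse += (resid**2).mean(axis=0)
            mse /= len(folds)
            for lam, m in zip(lambdas, mse):
                rows.append((kind, phi, lam, m))
            i = int(np.argmin(mse))
            if best is None or mse[i] < best[3]:
                best = (kind, phi, float(lambdas[i]), float(mse[i]))
    table = pd.DataFrame(rows, columns=["window", "phi", "lambda", "mse"])
    return best[0], best[1], best[2], table


def _refit(Xw, E, part, phi, lam, alpha, tol, max_iter):
    Xs, mu, sd = _standardize_train(Xw)
    Ec = E - E.mean()
    cfg = WNetConfig(lambda_=lam, phi=phi, alpha=alpha, tol=tol, max_iter=max_iter)
    fit = fit_weighted_elastic_net(Xs, Ec, part, cfg)
    return fit, mu, sd, E.mean()


def nested_cv_train(
    genotypes: GenotypeMatrix,
    expression: np.ndarray,
    gene: Gene,
    windows: list[CisWindow],
    phi_grid=DEFAULT_PHI_GRID,
    seed: int = 0,
    *,
    tissue: str = "tissue",
    n_folds: int = 5,
    n_inner: int = 5,
    alpha: float = 0.5,
    n_lambda: int = 10,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 1000,
    essential_mask: np.ndarray | None = None,
) -> tuple[TrainedModel, CVReport]:
    """Train one gene's model with nested 5x5 cross-validation.

    ``essential_mask`` flags the essential variants among ``genotypes``
    columns (all non-essential when omitted). Standardization statistics are
    always computed on training folds only. Raises ``EmptyWindowError`` when
    no candidate window covers >= 2 variants.
    """
    E = np.asarray(expression, dtype=float)
    n = genotypes.n_samples
    if len(E) != n:
        raise ValueError("expression length does not match sample count")
    if n < n_folds * 5:
        raise ValueError(f"need >= {n_folds * 5} samples for {n_folds}-fold nested CV")
    if essential_mask is None:
        essential_mask = np.zeros(genotypes.n_variants, dtype=bool)
    essential_mask = np.asarray(essential_mask, dtype=bool)

    windows_cols = {}
    for w in windows:
        try:
            _, cols = subset_cis_variants(genotypes, w)
        except EmptyWindowError:
            continue
        windows_cols[w.kind] = cols
    if not windows_cols:
        raise EmptyWindowError(f"gene {gene.gene_id}: no candidate window with >= 2 variants")

    rng = _fold_rng(seed, genotypes.samples)
    X = genotypes.dosages
    folds = _kfold(n, n_folds, rng)

    fold_preds, fold_truth = [], []
    for f, test_idx in enumerate(folds):
        tr_mask = np.ones(n, dtype=bool)
        tr_mask[test_idx] = False
        kind, phi, lam, _ = _inner_cv_select(
            X[tr_mask], E[tr_mask], windows_cols, essential_mask, phi_grid,
            n_inner, rng, alpha, n_lambda, lambda_min_ratio, tol, max_iter,
        )
        cols = windows_cols[kind]
        part = PenaltyPartition.from_mask(essential_mask[cols])
        fit, mu, sd, e_mu = _refit(
            X[tr_mask][:, cols], E[tr_mask], part, phi, lam, alpha, tol, max_iter
        )
        Xte = (X[test_idx][:, cols] - mu) / sd
        pred = Xte @ fit.coef + e_mu
        fold_preds.append(pred)
        fold_truth.append(E[test_idx])

    cv_r, cv_p = assess_performance(fold_preds, fold_truth)

    # final model: triple selected by inner CV on the full data, refit on all samples
    kind, phi, lam, table = _inner_cv_select(
        X, E, windows_cols, essential_mask, phi_grid,
        n_inner, rng, alpha, n_lambda, lambda_min_ratio, tol, max_iter,
    )
    cols = windows_cols[kind]
    part = PenaltyPartition.from_mask(essential_mask[cols])
    fit, _, _, _ = _refit(X[:, cols], E, part, phi, lam, alpha, tol, max_iter)
    var = genotypes.variants.iloc[cols]
    weights = {
        str(v.variant_id): (str(v.ref), str(v.alt), float(w))
        for v, w in zip(var.itertuples(index=False), fit.coef)
        if w != 0.0
    }
    model = TrainedModel(
        gene_id=gene.gene_id,
        tissue=tissue,
        selected_w=kind,
        selected_phi=float(phi),
        selected_lambda=float(lam),
        weights=weights,
        cv_r=cv_r,
        cv_p=cv_p,
        significant=bool(cv_r > 0.1 and cv_p < 0.05),
        seed=int(seed),
    )
    report = CVReport(
        fold_r=[_spearman(p, t) for p, t in zip(fold_preds, fold_truth)],
        fold_sizes=[len(t) for t in fold_truth],
        inner_cv=table,
    )
    return model, report


def assess_performance(fold_predictions, fold_truth) -> tuple[float, float]:
    """Average per-fold Spearman r and Stouffer-combined one-sided p-value.

    Each fold contributes z_k = r_k * sqrt(n_k - 1) (the asymptotic null
    standard error of Spearman's r is 1/sqrt(n-1)); the combined statistic
    sum(z_k)/sqrt(K) is referred to the upper tail of the standard normal.
    Constant predictions in a fold contribute r = 0.
    """
    if len(fold_predictions) < 2:
        raise ValueError("need >= 2 folds")
    rs, zs = [], []
    for pred, truth in zip(fold_predictions, fold_truth):
        r = _spearman(np.asarray(pred), np.asarray(truth))
        rs.append(r)
        zs.append(r * np.sqrt(len(truth) - 1))
    combined = np.sum(zs) / np.sqrt(len(zs))
    return float(np.mean(rs)), float(stats.norm.sf(combined))


def is_significant(model: TrainedModel) -> bool:
    """Deployment rule: average Spearman r > 0.1 and Stouffer p < 0.05."""
    return bool(model.cv_r > 0.1 and model.cv_p < 0.05)
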