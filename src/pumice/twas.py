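"""Summary-statistic gene-trait association and p-value combination.

The gene-level statistic is S = b'Z / sqrt(b' Sigma_reg b) where b are the
prediction-model weights, Z the (harmonized, possibly imputed) GWAS z-scores
of the model variants and Sigma_reg = (1-shrink)*Sigma + shrink*I the
regularized LD correlation matrix. Under the null S is standard normal, so
the two-sided p-value is 2*Phi(-|S|). Model variants absent from the GWAS
get Gaussian-imputed z-scores from the observed ones. P-values from
different methods/tissues are combined with the Cauchy combination test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


@dataclass
class LDReference:
    """Correlation matrix among a variant panel."""

    variant_ids: list
    corr: np.ndarray
    shrink: float = 0.0

    def __post_init__(self):
        self.corr = np.asarray(self.corr, dtype=float)
        k = len(self.variant_ids)
        if self.corr.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")

    def submatrix(self, variant_ids) -> np.ndarray:
        idx = [self.variant_ids.index(v) for v in variant_ids]
        return self.corr[np.ix_(idx, idx)]

    def regularized(self, shrink: float) -> np.ndarray:
        return regularize_ld(self.corr, shrink)


def regularize_ld(corr: np.ndarray, shrink: float) -> np.ndarray:
    """(1-shrink)*Sigma + shrink*I; keeps the unit diagonal."""
    if not 0 <= shrink <= 1:
        raise ValueError("shrink must lie in [0, 1]")
    k = corr.shape[0]
    return (1.0 - shrink) * corr + shrink * np.eye(k)


@dataclass
class TWASResult:
    gene_id: str
    tissue: str
    S: float
    p: float
    n_model_snps_used: int
    n_imputed: int
    low_confidence: bool = False


def impute_missing_z(
    z_observed: np.ndarray,
    observed_mask: np.ndarray,
    ld: np.ndarray,
    ridge: float = 0.1,
) -> np.ndarray:
    """Gaussian imputation of unobserved z-scores.

    ``z_observed`` carries z at positions where ``observed_mask`` is True
    (other entries ignored); ``ld`` is the correlation matrix over all model
    variants. Unobserved entries get
    Z_u = Sigma_uo (Sigma_oo + ridge*I)^-1 Z_o — the conditional MVN mean
    with a ridge on the observed block for stability.
    """
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if not observed_mask.any():
        raise ValueError("no observed variants: gene untestable")
    z = np.array(z_observed, dtype=float)
    if observed_mask.all():
        return z
    o = np.flatnonzero(observed_mask)
    u = np.flatnonzero(~observed_mask)
    s_oo = ld[np.ix_(o, o)] + ridge * np.eye(len(o))
    s_uo = ld[np.ix_(u, o)]
    z[u] = s_uo @ np.linalg.solve(s_oo, z[o])
    return z


def twas_association(
    beta: np.ndarray,
    z: np.ndarray,
    ld: np.ndarray,
    shrink: float = 0.1,
    *,
    gene_id: str = "",
    tissue: str = "",
    n_imputed: int = 0,
    weight_mass_observed: float = 1.0,
) -> TWASResult:
    """Gene-level association from weights, z-scores and LD.

    Positive S means genetically elevated expression associates with higher
    trait values. Genes where less than half the absolute weight mass had
    observed GWAS z-scores are flagged low-confidence.
    """
    beta = np.asarray(beta, dtype=float)
    z = np.asarray(z, dtype=float)
    sigma = regularize_ld(np.asarray(ld, dtype=float), shrink)
    denom = float(beta @ sigma @ beta)
    if denom <= 0:
        raise ValueError("b' Sigma_reg b <= 0; LD regularization failed")
    S = float(beta @ z) / np.sqrt(denom)
    p = float(2.0 * stats.norm.sf(abs(S)))
    return TWASResult(
        gene_id=gene_id,
        tissue=tissue,
        S=S,
        p=p,
        n_model_snps_used=len(beta),
        n_imputed=int(n_imputed),
        low_confidence=bool(weight_mass_observed < 0.5),
    )


def cauchy_combine(p_values, weights=None) -> float:
    """Cauchy combination of p-values (valid under arbitrary dependence).

    T = sum_i w_i * tan((0.5 - p_i) * pi); combined p = 0.5 - arctan(T)/pi.
    Weights default to equal and must be nonnegative summing to 1. Inputs
    are clipped to [1e-300, 1 - 1e-16].
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("cauchy_combine needs >= 1 p-value")
    if ((p <= 0) | (p >= 1)).any():
        p = np.clip(p, P_FLOOR, P_CEIL)
    p = np.clip(p, P_FLOOR, P_CEIL)
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
    T = float(w @ np.tan((0.5 - p) * np.pi))
    return float(np.clip(0.5 - np.arctan(T) / np.pi, P_FLOOR, P_CEIL))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-tissue significance threshold alpha / number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
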