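"""Copula-based fine-mapping of gene-level association results.

Gene p-values (plain or Cauchy-combined) are transformed to z-scale
statistics T = Phi^-1(1 - p); correlations between gene statistics are
estimated by Monte Carlo simulation of null SNP z-scores through each
gene's statistic pipeline; loci are defined iteratively around the most
significant unassigned gene; within a locus, approximate Bayes factors
ABF = (psi^2+1)^{-1/2} exp(psi^2 z^2 / (2(1+psi^2))) yield posterior
inclusion probabilities PIP = ABF / sum(ABF) and credible sets. Secondary
signals are handled by conditioning the z-scores on the top gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .twas import P_CEIL, P_FLOOR, regularize_ld

logger = logging.getLogger("pumice")

DEFAULT_PSI = 0.05


def pvalue_to_zscore(p) -> np.ndarray | float:
    """Upper-tail standard normal quantile of 1 - p (clipped to stay finite)."""
    arr = np.asarray(p, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        arr = np.clip(arr, P_FLOOR, P_CEIL)
    if ((arr <= 0) | (arr >= 1)).any():
        raise ValueError("p-values must lie in (0, 1)")
    z = stats.norm.isf(arr)
    return float(z) if np.isscalar(p) else z


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    gene_ids: list
    top_gene: str


def define_loci(
    results: pd.DataFrame,
    ld_blocks: pd.DataFrame | None = None,
    fallback_radius: int = 1_000_000,
) -> list[Locus]:
    """Iterative locus definition around the most significant genes.

    ``results`` needs columns gene_id, chrom, tss, p. Starting from the most
    significant unassigned gene, its containing LD block (or gene TSS +/-
    ``fallback_radius`` when no block covers it) becomes a locus collecting
    every unassigned gene whose TSS falls inside; repeat until exhausted.
    """
    df = results.sort_values("p", kind="mergesort").reset_index(drop=True)
    unassigned = df.copy()
    loci = []
    while len(unassigned):
        top = unassigned.iloc[0]
        block = None
        if ld_blocks is not None and len(ld_blocks):
            sub = ld_blocks[ld_blocks["chrom"].astype(str) == str(top.chrom)]
            hit = sub[(sub["start"] <= top.tss) & (sub["end"] >= top.tss)]
            if len(hit):
                block = (int(hit.iloc[0]["start"]), int(hit.iloc[0]["end"]))
        if block is None:
            if ld_blocks is not None and len(ld_blocks):
                logger.warning(
                    "gene %s outside every LD block; using +/- %d fallback",
                    top.gene_id, fallback_radius,
                )
            block = (max(1, int(top.tss) - fallback_radius), int(top.tss) + fallback_radius)
        inside = (
            (unassigned["chrom"].astype(str) == str(top.chrom))
            & (unassigned["tss"] >= block[0])
            & (unassigned["tss"] <= block[1])
        )
        members = unassigned[inside]
        loci.append(
            Locus(
                chrom=str(top.chrom),
                start=block[0],
                end=block[1],
                gene_ids=list(members["gene_id"]),
                top_gene=str(top.gene_id),
            )
        )
        unassigned = unassigned[~inside]
    return loci


def linear_statistic(beta: np.ndarray, sigma: np.ndarray):
    """Statistic function for the plain gene-level z: S = b'Z / sqrt(b'Sigma b).

    Returns a callable mapping a (reps x m) matrix of SNP z-draws to the
    per-draw statistic, already on the z scale (sign preserved).
    """
    beta = np.asarray(beta, dtype=float)
    denom = np.sqrt(float(beta @ sigma @ beta))

    def fn(z_draws: np.ndarray) -> np.ndarray:
        return (z_draws @ beta) / denom

    return fn


def copula_statistic(p_from_z):
    """Statistic function for combined-p pipelines.

    ``p_from_z`` maps a (reps x m) z-draw matrix to per-draw p-values (for
    example a Cauchy combination of several per-method TWAS p-values); the
    returned callable applies the copula transform Phi^-1(1 - p), matching
    how observed combined p-values are transformed before fine-mapping.
    """

    def fn(z_draws: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(p_from_z(z_draws), dtype=float), P_FLOOR, P_CEIL)
        return stats.norm.isf(p)

    return fn


def _mvn_draws(sigma: np.ndarray, reps: int, rng) -> np.ndarray:
    """MVN(0, sigma) draws via an eigenvalue-floored factorization."""
    vals, vecs = np.linalg.eigh(np.asarray(sigma, dtype=float))
    vals = np.maximum(vals, 0.0)
    root = vecs * np.sqrt(vals)
    return rng.standard_normal((reps, sigma.shape[0])) @ root.T


def estimate_statistic_correlation(
    stat_a,
    stat_b,
    snp_ld: np.ndarray,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Monte-Carlo correlation between two gene-level statistics.

    ``stat_a``/``stat_b`` map a (reps x m) matrix of null SNP z-draws (over
    the shared SNP panel whose correlation is ``snp_ld``) to per-draw
    statistics on the z scale — see :func:`linear_statistic` and
    :func:`copula_statistic`. SNP z-scores are drawn from MVN(0, snp_ld).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    z = _mvn_draws(snp_ld, reps, rng)
    ta = np.asarray(stat_a(z), dtype=float)
    tb = np.asarray(stat_b(z), dtype=float)
    if np.std(ta) == 0 or np.std(tb) == 0:
        raise ValueError("degenerate (zero-variance) statistic stream")
    return float(np.corrcoef(ta, tb)[0, 1])


def conditional_adjust(z_vector: np.ndarray, corr_matrix: np.ndarray, top_index: int):
    """Residual z-scores after conditioning on the top gene.

    z'_j = (z_j - r_{j,top} z_top) / sqrt(1 - r_{j,top}^2) for j != top; the
    top entry is removed. Near-collinear genes (|r| >= 1 - 1e-8) get
    conditional z = 0 with a warning.
    """
    z = np.asarray(z_vector, dtype=float)
    r = np.asarray(corr_matrix, dtype=float)[:, top_index]
    keep = np.arange(len(z)) != top_index
    rj = r[keep]
    out = np.zeros(keep.sum())
    ok = np.abs(rj) < 1 - 1e-8
    out[ok] = (z[keep][ok] - rj[ok] * z[top_index]) / np.sqrt(1.0 - rj[ok] ** 2)
    if (~ok).any():
        logger.warning("%d collinear gene(s) set to conditional z = 0", int((~ok).sum()))
    return out, np.flatnonzero(keep)


def approximate_bayes_factor(z, psi: float = DEFAULT_PSI):
    """Wakefield-style ABF; computed in log space to avoid overflow."""
    if psi <= 0:
        raise ValueError("psi must be > 0")
    z = np.asarray(z, dtype=float)
    log_abf = -0.5 * np.log(psi**2 + 1.0) + (psi**2 * z**2) / (2.0 * (1.0 + psi**2))
    return np.exp(log_abf) if z.ndim else float(np.exp(log_abf))


def log_abf(z, psi: float = DEFAULT_PSI) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    return -0.5 * np.log(psi**2 + 1.0) + (psi**2 * z**2) / (2.0 * (1.0 + psi**2))


def posterior_inclusion_probabilities(abf_list=None, *, log_abfs=None) -> np.ndarray:
    """PIP_g = ABF_g / sum_l ABF_l, computed stably in log space."""
    if log_abfs is None:
        abf = np.asarray(abf_list, dtype=float)
        if (abf <= 0).any():
            raise ValueError("ABFs must be positive")
        log_abfs = np.log(abf)
    la = np.asarray(log_abfs, dtype=float)
    if la.size == 0:
        raise ValueError("empty locus")
    la = la - la.max()
    w = np.exp(la)
    return w / w.sum()


def credible_set(pips: np.ndarray, level: float = 0.9, p_values=None, gene_ids=None) -> np.ndarray:
    """Smallest PIP-descending prefix with cumulative PIP >= level.

    Returns indices into ``pips``. Ties broken by smaller p-value then
    lexicographic gene id when provided.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pips = np.asarray(pips, dtype=float)
    n = len(pips)
    p_key = np.asarray(p_values, dtype=float) if p_values is not None else np.zeros(n)
    g_key = np.asarray(gene_ids, dtype=object) if gene_ids is not None else np.array([""] * n, dtype=object)
    order = sorted(range(n), key=lambda i: (-pips[i], p_key[i], str(g_key[i])))
    cum = 0.0
    chosen = []
    for i in order:
        chosen.append(i)
        cum += pips[i]
        if cum >= level:
            break
    return np.array(chosen, dtype=int)


@dataclass
class FineMapResult:
    """Per-gene fine-mapping output for one locus and conditioning round."""

    table: pd.DataFrame  # gene_id, z, abf, pip, in_credible_set, round


def finemap_locus(
    gene_ids,
    z_scores,
    stat_corr: np.ndarray,
    p_values=None,
    psi: float = DEFAULT_PSI,
    level: float = 0.9,
    conditional_threshold: float | None = None,
    max_rounds: int = 3,
) -> FineMapResult:
    """Fine-map one locus with iterative conditioning on the top gene.

    Round 1 uses the marginal transformed statistics; if, after conditioning
    on the round's top gene, any conditional p-value stays below
    ``conditional_threshold``, another round is run on the residual
    statistics (at most ``max_rounds`` rounds).
    """
    gene_ids = list(gene_ids)
    z = np.asarray(z_scores, dtype=float)
    corr = np.asarray(stat_corr, dtype=float)
    pv = np.asarray(p_values, dtype=float) if p_values is not None else stats.norm.sf(z)
    rows = []
    active = np.arange(len(gene_ids))
    for rnd in range(1, max_rounds + 1):
        la = log_abf(z, psi)
        pips = posterior_inclusion_probabilities(log_abfs=la)
        cs = set(credible_set(pips, level, p_values=pv, gene_ids=[gene_ids[i] for i in active]).tolist())
        for k, i in enumerate(active):
            rows.append(
                (gene_ids[i], float(z[k]), float(np.exp(la[k])), float(pips[k]), k in cs, rnd)
            )
        if conditional_threshold is None or len(active) < 2:
            break
        top = int(np.argmax(np.abs(z)))
        z, kept = conditional_adjust(z, corr, top)
        corr_resid = corr[np.ix_(kept, kept)]
        active = active[kept]
        pv = stats.norm.sf(z)
        corr = corr_resid
        if not (pv < conditional_threshold).any():
            break
    return FineMapResult(
        table=pd.DataFrame(rows, columns=["gene_id", "z", "abf", "pip", "in_credible_set", "round"])
    )
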