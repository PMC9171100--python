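"""Simulation framework: synthetic genotypes, expression, GWAS z-scores,
and end-to-end type-I-error / power evaluation.

The generative model: causal cis-variants split into essential (annotated)
and non-essential groups; per-SNP weight variances h2_epi/M_epi and
h2_notepi/M_notepi with the essential enrichment factor
EF = (h2_epi/M_epi) / (h2_notepi/M_notepi) and h2_epi + h2_notepi = h2_e;
expression E = X w + eps with eps ~ N(0, 1 - h2_e); GWAS z-scores drawn from
MVN(Sigma_G * sqrt(N_gwas * h2_p) * w, Sigma_G) with Sigma_G the cis-LD
matrix estimated from a large reference sample. Genotypes come from a
block-LD generator (latent MVN with AR(1) correlation within blocks,
thresholded twice per haplotype to dosages at target allele frequencies)
standing in for the real cohort genotypes the design was run on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import build_candidate_windows, classify_essential
from .containers import Gene, GenotypeMatrix, make_variant_table
from .train import DEFAULT_PHI_GRID, nested_cv_train
from .twas import twas_association

logger = logging.getLogger("pumice")

WINDOW_MODES = ("1Mb", "250kb", "3D", "mixed")


@dataclass
class SingleTissueSimConfig:
    """One scenario of the single-tissue simulation grid.

    Scenario axes follow the study design: n_causal in {2, 8, 32, 64},
    p_causal_epi in {0.4, 0.8, 1}, window_mode in {1Mb, 250kb, 3D, mixed},
    (h2_e, h2_p) in {(0.025, 0.02), (0.05, 0.01), (0.1, 0.005)} (h2_p = 0 for
    the null), EF in {2, 4}, n_train in {100, 200, 300}, n_gwas = 500000.
    """

    n_causal: int = 8
    p_causal_epi: float = 1.0
    window_mode: str = "1Mb"
    h2_e: float = 0.1
    h2_p: float = 0.005
    EF: float = 2.0
    n_train: int = 200
    n_gwas: int = 500_000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h2_e < 1:
            raise ValueError("h2_e must lie in (0, 1)")
        if self.h2_p < 0:
            raise ValueError("h2_p must be >= 0")
        if self.EF < 1:
            raise ValueError("EF must be >= 1")
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"window_mode must be one of {WINDOW_MODES}")


@dataclass
class MultiTissueSimConfig:
    """Cross-tissue scenario: genetic correlation rho between the causal
    tissue and n_corr correlated tissues; residual cross-tissue correlation
    is the identity."""

    rho: float = 0.3
    n_corr: int = 24
    n_uncorr: int = 23
    h2_e: float = 0.1
    tissue_n: int = 200
    seed: int = 0

    def __post_init__(self):
        if not -1 < self.rho < 1:
            raise ValueError("|rho| must be < 1")


@dataclass
class GenotypeFixtureConfig:
    """Block-LD genotype generator settings (the stand-in for real cohorts)."""

    m_snps: int = 30
    block_size: int = 6
    within_block_r: float = 0.7
    maf_range: tuple = (0.05, 0.5)
    n_ref: int = 5000  # reference sample size for estimating Sigma_G
    background_essential_frac: float = 0.3
    tad_flank: int = 400_000


@dataclass
class SimReplicate:
    """Everything generated for one simulated gene."""

    genotypes: GenotypeMatrix
    essential_mask: np.ndarray
    causal_idx_epi: np.ndarray
    causal_idx_notepi: np.ndarray
    weights: np.ndarray  # full-length weight vector (zeros off the causal set)
    expression: np.ndarray
    gwas_z: np.ndarray
    sigma_g: np.ndarray
    windows: list
    gene: Gene


@dataclass
class PowerReport:
    type1: float | None
    power: float | None
    n_null: int
    n_nonnull: int
    type1_threshold: float = 0.05
    power_threshold: float = 5e-5


def _sub_seed(seed: int, *tags) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31)] + [int(t) % (2**31) for t in tags])


def simulate_ld_genotypes(
    n: int,
    m: int,
    block_size: int = 6,
    within_block_r: float = 0.7,
    maf_range=(0.05, 0.5),
    seed: int = 0,
    positions=None,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Block-correlated dosages: latent MVN with AR(1) correlation within
    consecutive blocks, thresholded twice per haplotype at the target allele
    frequency. Deterministic given seed."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie inside (0, 0.5]")
    rng = _sub_seed(seed, 11)
    mafs = rng.uniform(lo, hi, size=m)
    thresholds = stats.norm.isf(mafs)

    def haplotypes():
        h = np.empty((n, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            k = stop - start
            idx = np.arange(k)
            R = within_block_r ** np.abs(idx[:, None] - idx[None, :])
            L = np.linalg.cholesky(R + 1e-12 * np.eye(k))
            h[:, start:stop] = rng.standard_normal((n, k)) @ L.T
        return h

    dosages = (haplotypes() > thresholds).astype(float) + (haplotypes() > thresholds).astype(float)
    if positions is None:
        positions = np.sort(rng.choice(np.arange(1, 10_000_000), size=m, replace=False))
    variants = make_variant_table(
        [f"{chrom}:{p}:A:G" for p in positions],
        [chrom] * m,
        positions,
        ["A"] * m,
        ["G"] * m,
        dosages.mean(axis=0) / 2.0,
    )
    samples = np.array([f"S{i:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def simulate_effect_weights(M_epi: int, M_notepi: int, h2_e: float, EF: float, seed=0):
    """Draw causal effect weights with the essential enrichment split.

    h2_epi = h2_e * EF * M_epi / (EF * M_epi + M_notepi) is the unique split
    with h2_epi + h2_notepi = h2_e and per-SNP variance ratio EF; weights are
    normal with per-SNP variances h2_epi/M_epi and h2_notepi/M_notepi.
    """
    if M_epi + M_notepi < 1:
        raise ValueError("need at least one causal variant")
    if EF <= 0:
        raise ValueError("EF must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else _sub_seed(seed, 13)
    if M_epi == 0:
        if EF != 1:
            logger.warning("M_epi = 0: enrichment undefined, h2_epi = 0")
        h2_epi = 0.0
    else:
        h2_epi = h2_e * EF * M_epi / (EF * M_epi + M_notepi)
    h2_notepi = h2_e - h2_epi
    w_epi = rng.normal(0.0, np.sqrt(h2_epi / M_epi), size=M_epi) if M_epi else np.empty(0)
    w_notepi = (
        rng.normal(0.0, np.sqrt(h2_notepi / M_notepi), size=M_notepi) if M_notepi else np.empty(0)
    )
    return w_epi, w_notepi


def simulate_expression(X: np.ndarray, w_epi, w_notepi, h2_e: float, seed=0) -> np.ndarray:
    """E = X [w_epi, w_notepi] + eps, eps ~ N(0, 1 - h2_e) i.i.d.

    X must be standardized with its essential causal columns first, matching
    the weight ordering.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _sub_seed(seed, 17)
    w = np.concatenate([np.asarray(w_epi, dtype=float), np.asarray(w_notepi, dtype=float)])
    if X.shape[1] != len(w):
        raise ValueError("genotype columns do not match weight length")
    eps = rng.normal(0.0, np.sqrt(1.0 - h2_e), size=X.shape[0])
    return X @ w + eps


def simulate_gwas_z(
    Sigma_G: np.ndarray,
    weights: np.ndarray,
    n_gwas: int,
    h2_p: float,
    seed=0,
    normalize: bool = False,
) -> np.ndarray:
    """One draw of GWAS z-scores: MVN(Sigma_G sqrt(N h2_p) w, Sigma_G).

    With ``normalize`` the weight vector is scaled by 1/sqrt(w' Sigma_G w)
    first so the gene explains exactly h2_p of phenotypic variance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else _sub_seed(seed, 19)
    sigma = np.asarray(Sigma_G, dtype=float)
    w = np.asarray(weights, dtype=float)
    if sigma.shape[0] != len(w):
        raise ValueError("Sigma_G dimension does not match weights")
    if normalize and h2_p > 0 and (w != 0).any():
        w = w / np.sqrt(float(w @ sigma @ w))
    mean = sigma @ (np.sqrt(n_gwas * h2_p) * w)
    vals, vecs = np.linalg.eigh(sigma)
    root = vecs * np.sqrt(np.maximum(vals, 0.0))
    return mean + root @ rng.standard_normal(len(w))


def simulate_multitissue(
    X_per_tissue: dict,
    causal_weights: np.ndarray,
    rho: float,
    n_corr: int,
    n_uncorr: int,
    h2_e: float,
    seed=0,
    weight_variances=None,
):
    """Per-tissue expression under cross-tissue genetic correlation.

    The first tissue in ``X_per_tissue`` is causal with weights
    ``causal_weights``; the next ``n_corr`` tissues get weights
    w_corr ~ N(rho * w_causal, (1 - rho^2) * v) per SNP (v the causal
    per-SNP weight variance, so corr(w_corr, w_causal) = rho and
    heritability is preserved); the remaining ``n_uncorr`` tissues use the
    same model with rho = 0. Residuals are N(0, 1 - h2_e), independent
    across tissues (identity cross-tissue residual correlation).
    """
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else _sub_seed(seed, 23)
    names = list(X_per_tissue)
    if len(names) != 1 + n_corr + n_uncorr:
        raise ValueError("X_per_tissue must hold 1 + n_corr + n_uncorr tissues")
    w0 = np.asarray(causal_weights, dtype=float)
    if weight_variances is None:
        nz = w0 != 0
        v = np.zeros_like(w0)
        if nz.any():
            v[nz] = h2_e / nz.sum()
    else:
        v = np.asarray(weight_variances, dtype=float)
    out = {}
    for t, name in enumerate(names):
        X = np.asarray(X_per_tissue[name], dtype=float)
        if t == 0:
            w = w0
        else:
            r = rho if t <= n_corr else 0.0
            w = r * w0 + rng.normal(0.0, 1.0, size=len(w0)) * np.sqrt((1.0 - r**2) * v)
        eps = rng.normal(0.0, np.sqrt(1.0 - h2_e), size=X.shape[0])
        out[name] = (X @ w + eps, w)
    return out


def evaluate_error_rates(
    p_values,
    truth_null_flags,
    type1_threshold: float = 0.05,
    power_threshold: float = 5e-5,
) -> PowerReport:
    """Type-I error (null genes, p < 0.05) and power (non-null, p < 5e-5).

    NaN p-values (untestable genes) are excluded from the rates; class
    counts refer to tested genes. An empty class reports None.
    """
    p = np.asarray(p_values, dtype=float)
    null = np.asarray(truth_null_flags, dtype=bool)
    if len(p) != len(null):
        raise ValueError("p_values and truth flags must align")
    ok = np.isfinite(p)
    n_null = int((null & ok).sum())
    n_nonnull = int((~null & ok).sum())
    type1 = float((p[null & ok] < type1_threshold).mean()) if n_null else None
    power = float((p[~null & ok] < power_threshold).mean()) if n_nonnull else None
    return PowerReport(
        type1=type1,
        power=power,
        n_null=n_null,
        n_nonnull=n_nonnull,
        type1_threshold=type1_threshold,
        power_threshold=power_threshold,
    )


# ---------------------------------------------------------------------------
# end-to-end replicates


def _gene_layout(fixture: GenotypeFixtureConfig, rng):
    """Gene coordinates, SNP positions and the synthetic 3D interval."""
    gene = Gene("GSIM", "1", 2_000_000, 2_010_000)
    lo, hi = gene.tss - 1_000_000, gene.end + 1_000_000
    positions = np.sort(rng.choice(np.arange(lo, hi), size=fixture.m_snps, replace=False))
    tad = pd.DataFrame(
        {
            "chrom": ["1"],
            "start": [max(1, gene.tss - fixture.tad_flank)],
            "end": [gene.end + fixture.tad_flank],
            "label": ["tad0"],
        }
    )
    return gene, positions, tad


def generate_replicate(config: SingleTissueSimConfig, fixture: GenotypeFixtureConfig, rep: int) -> SimReplicate:
    """Generate genotypes, annotation, weights, expression and GWAS z for
    one simulated gene; causal SNPs are placed inside the designated window
    and annotation tracks are synthesized so that exactly the intended
    causal fraction is essential."""
    rng = _sub_seed(config.seed, 101, rep)
    gene, positions, tad = _gene_layout(fixture, rng)
    genotypes = simulate_ld_genotypes(
        config.n_train,
        fixture.m_snps,
        fixture.block_size,
        fixture.within_block_r,
        fixture.maf_range,
        seed=int(rng.integers(2**31)),
        positions=positions,
    )
    reference = simulate_ld_genotypes(
        fixture.n_ref,
        fixture.m_snps,
        fixture.block_size,
        fixture.within_block_r,
        fixture.maf_range,
        seed=int(rng.integers(2**31)),
        positions=positions,
    )
    sigma_g = reference.correlation()

    windows = build_candidate_windows(gene, (250_000, 1_000_000), tad_set=tad)
    mode = config.window_mode
    if mode == "mixed":
        mode = rng.choice(["1Mb", "250kb", "3D"])
    kind = {"1Mb": "linear_1mb", "250kb": "linear_250kb", "3D": "tad"}[mode]
    designated = next(w for w in windows if w.kind == kind)

    inside = np.array([designated.contains("1", p) for p in positions])
    candidates = np.flatnonzero(inside)
    if len(candidates) < config.n_causal:
        raise ValueError(
            f"designated window holds {len(candidates)} SNPs < n_causal = {config.n_causal}; "
            "increase m_snps"
        )
    causal = rng.choice(candidates, size=config.n_causal, replace=False)
    m_epi = int(round(config.n_causal * config.p_causal_epi))
    causal_epi = causal[:m_epi]
    causal_notepi = causal[m_epi:]

    essential = np.zeros(fixture.m_snps, dtype=bool)
    essential[causal_epi] = True
    noncausal = np.setdiff1d(np.arange(fixture.m_snps), causal)
    background = noncausal[rng.random(len(noncausal)) < fixture.background_essential_frac]
    essential[background] = True

    tracks = pd.DataFrame(
        {
            "chrom": "1",
            "start": positions[essential],
            "end": positions[essential],
            "label": "mark",
        }
    )
    partition = classify_essential(genotypes.variants, tracks if essential.any() else None)
    essential_mask = partition.essential_mask(fixture.m_snps)

    w_epi, w_notepi = simulate_effect_weights(
        m_epi, config.n_causal - m_epi, config.h2_e, config.EF, seed=rng
    )
    weights = np.zeros(fixture.m_snps)
    weights[causal_epi] = w_epi
    weights[causal_notepi] = w_notepi

    Xs = genotypes.standardize().dosages
    expression = Xs @ weights + rng.normal(0.0, np.sqrt(1.0 - config.h2_e), size=config.n_train)
    gwas_z = simulate_gwas_z(sigma_g, weights, config.n_gwas, config.h2_p, seed=rng)

    return SimReplicate(
        genotypes=genotypes,
        essential_mask=essential_mask,
        causal_idx_epi=causal_epi,
        causal_idx_notepi=causal_notepi,
        weights=weights,
        expression=expression,
        gwas_z=gwas_z,
        sigma_g=sigma_g,
        windows=windows,
        gene=gene,
    )


def run_replicate(
    config: SingleTissueSimConfig,
    fixture: GenotypeFixtureConfig,
    rep: int,
    *,
    phi_grid=DEFAULT_PHI_GRID,
    n_lambda: int = 5,
    lambda_min_ratio: float = 0.05,
    shrink: float = 0.1,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> dict:
    """Train on one replicate and run the gene-level test against its
    simulated GWAS z-scores. Returns a flat record for the replicate table."""
    sim = generate_replicate(config, fixture, rep)
    model, report = nested_cv_train(
        sim.genotypes,
        sim.expression,
        sim.gene,
        sim.windows,
        phi_grid=phi_grid,
        seed=(config.seed * 1_000_003 + rep) % (2**31),
        essential_mask=sim.essential_mask,
        n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio,
        tol=tol,
        max_iter=max_iter,
    )
    vids = list(model.weights)
    if vids:
        all_ids = list(sim.genotypes.variants["variant_id"])
        idx = [all_ids.index(v) for v in vids]
        beta = model.beta_for(vids)
        res = twas_association(
            beta,
            sim.gwas_z[idx],
            sim.sigma_g[np.ix_(idx, idx)],
            shrink=shrink,
            gene_id=sim.gene.gene_id,
        )
        S, p = res.S, res.p
    else:
        S, p = np.nan, np.nan
    n_causal_recovered = len(
        set(np.flatnonzero(sim.weights != 0)) & {all_ids.index(v) for v in vids}
    ) if vids else 0
    return {
        "rep": rep,
        "S": S,
        "p_twas": p,
        "cv_r": model.cv_r,
        "cv_p": model.cv_p,
        "model_significant": model.significant,
        "selected_phi": model.selected_phi,
        "selected_window": model.selected_w,
        "n_nonzero": len(vids),
        "n_causal_recovered": n_causal_recovered,
        "truth_null": config.h2_p == 0.0,
    }


def run_simulation_study(
    config: SingleTissueSimConfig,
    n_replicates: int = 1000,
    seed: int | None = None,
    fixture: GenotypeFixtureConfig | None = None,
    progress: bool = False,
    **train_opts,
) -> tuple[PowerReport, pd.DataFrame]:
    """Run the full per-replicate pipeline and aggregate error rates.

    Deterministic given (config, seed): the replicate table is identical
    across runs. ``train_opts`` forwards to :func:`run_replicate`.
    """
    if seed is not None:
        config = replace(config, seed=int(seed))
    fixture = fixture or GenotypeFixtureConfig()
    rows = []
    for rep in range(n_replicates):
        rows.append(run_replicate(config, fixture, rep, **train_opts))
        if progress and (rep + 1) % 50 == 0:
            logger.info("replicate %d/%d", rep + 1, n_replicates)
    table = pd.DataFrame(rows)
    report = evaluate_error_rates(table["p_twas"], table["truth_null"])
    return report, table
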