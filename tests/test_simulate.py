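"""Generative model checks: genotypes, weights, expression, GWAS z-scores."""

import numpy as np
import pytest
from scipy import stats

from pumice.simulate import (
    GenotypeFixtureConfig,
    SingleTissueSimConfig,
    evaluate_error_rates,
    generate_replicate,
    simulate_effect_weights,
    simulate_expression,
    simulate_gwas_z,
    simulate_ld_genotypes,
    simulate_multitissue,
)


# --- genotype fixture ------------------------------------------------------


def test_genotypes_deterministic_given_seed():
    a = simulate_ld_genotypes(50, 12, seed=9)
    b = simulate_ld_genotypes(50, 12, seed=9)
    assert np.array_equal(a.dosages, b.dosages)
    c = simulate_ld_genotypes(50, 12, seed=10)
    assert not np.array_equal(a.dosages, c.dosages)


def test_genotype_mafs_close_to_targets():
    gm = simulate_ld_genotypes(2000, 20, maf_range=(0.1, 0.4), seed=3)
    # empirical MAFs should track the latent thresholds
    emp = gm.dosages.mean(axis=0) / 2
    assert (np.abs(emp - np.clip(emp, 0.05, 0.45)) < 0.05).all()
    assert emp.min() > 0.03 and emp.max() < 0.5


def test_unlinked_blocks_nearly_independent():
    gm = simulate_ld_genotypes(3000, 12, block_size=1, within_block_r=0.0, seed=4)
    corr = gm.correlation()
    off = corr[~np.eye(12, dtype=bool)]
    assert np.abs(off).mean() < 3 / np.sqrt(3000)


def test_within_block_ld_positive():
    gm = simulate_ld_genotypes(3000, 12, block_size=6, within_block_r=0.8, seed=5)
    corr = gm.correlation()
    assert corr[0, 1] > 0.4  # adjacent in block
    assert abs(corr[0, 7]) < 0.1  # across blocks


def test_maf_range_validation():
    with pytest.raises(ValueError):
        simulate_ld_genotypes(10, 5, maf_range=(0.0, 0.6))


# --- effect weights and the enrichment factor ------------------------------


def test_effect_weight_split_symmetric_when_ef_one():
    w_epi, w_notepi = simulate_effect_weights(4, 4, h2_e=0.2, EF=1, seed=0)
    assert len(w_epi) == 4 and len(w_notepi) == 4
    # h2_epi = h2_notepi = h2_e/2 => per-SNP variances match
    draws_e, draws_n = [], []
    for s in range(400):
        we, wn = simulate_effect_weights(4, 4, 0.2, 1, seed=s)
        draws_e.append(we); draws_n.append(wn)
    ve, vn = np.var(np.ravel(draws_e)), np.var(np.ravel(draws_n))
    assert ve == pytest.approx(0.2 / 2 / 4, rel=0.2)
    assert vn == pytest.approx(0.2 / 2 / 4, rel=0.2)


def test_effect_weight_split_hand_example():
    """EF=4, M_epi=2, M_notepi=6, h2_e=0.1 -> h2_epi = 0.1 * 8/14."""
    h2_epi = 0.1 * 4 * 2 / (4 * 2 + 6)
    assert h2_epi == pytest.approx(0.1 * 8 / 14)
    draws = [simulate_effect_weights(2, 6, 0.1, 4, seed=s)[0] for s in range(2000)]
    emp_var = np.var(np.ravel(draws))
    assert emp_var == pytest.approx(h2_epi / 2, rel=0.1)


def test_ef_identity_recovered_exactly():
    """Recomputing EF from the generated variance split returns EF exactly."""
    for EF in (1, 2, 4):
        M_epi, M_notepi, h2_e = 3, 5, 0.1
        h2_epi = h2_e * EF * M_epi / (EF * M_epi + M_notepi)
        h2_notepi = h2_e - h2_epi
        assert (h2_epi / M_epi) / (h2_notepi / M_notepi) == pytest.approx(EF, rel=1e-12)
        assert h2_epi + h2_notepi == pytest.approx(h2_e, rel=1e-12)


def test_all_essential_edge_case():
    w_epi, w_notepi = simulate_effect_weights(5, 0, 0.1, 4, seed=1)
    assert len(w_notepi) == 0
    assert np.var([simulate_effect_weights(5, 0, 0.1, 4, seed=s)[0] for s in range(500)]) == pytest.approx(0.1 / 5, rel=0.15)


# --- expression ------------------------------------------------------------


def test_expression_variance_near_one():
    # with independent SNPs E[w' Sigma w] = h2_e, so Var(E) ~ 1; under LD the
    # quadratic form fluctuates around h2_e and no rescaling is applied
    n, m = 5000, 8
    gm = simulate_ld_genotypes(n, m, block_size=1, within_block_r=0.0, seed=6)
    X = gm.standardize().dosages
    vs = []
    for s in range(12):
        w_epi, w_notepi = simulate_effect_weights(4, 4, h2_e=0.3, EF=2, seed=s)
        vs.append(simulate_expression(X, w_epi, w_notepi, 0.3, seed=8 + s).var())
    assert abs(np.mean(vs) - 1.0) < 0.1


def test_expression_zero_weights_pure_noise():
    X = np.zeros((4000, 2))
    E = simulate_expression(X, np.zeros(1), np.zeros(1), 0.3, seed=9)
    assert E.var() == pytest.approx(0.7, rel=0.1)
    E2 = simulate_expression(X, np.zeros(1), np.zeros(1), 0.3, seed=9)
    assert np.array_equal(E, E2)


def test_expression_shape_mismatch():
    with pytest.raises(ValueError):
        simulate_expression(np.zeros((10, 3)), np.zeros(1), np.zeros(1), 0.1)


# --- GWAS z ----------------------------------------------------------------


def test_gwas_z_null_mean_zero():
    sigma = np.eye(6)
    draws = np.array([simulate_gwas_z(sigma, np.zeros(6), 500_000, 0.0, seed=s) for s in range(1000)])
    assert np.abs(draws.mean(axis=0)).max() < 3 / np.sqrt(1000)


def test_gwas_z_causal_mean():
    """Sigma = I, one causal SNP: E[Z_causal] = sqrt(N h2_p) * w."""
    w = np.zeros(5); w[2] = 0.1
    n_gwas, h2_p = 500_000, 0.005
    draws = np.array([simulate_gwas_z(np.eye(5), w, n_gwas, h2_p, seed=s) for s in range(2000)])
    expected = np.sqrt(n_gwas * h2_p) * 0.1
    assert draws[:, 2].mean() == pytest.approx(expected, abs=3 / np.sqrt(2000))


def test_gwas_z_covariance_recovered():
    idx = np.arange(10)
    sigma = 0.6 ** np.abs(idx[:, None] - idx[None, :])
    draws = np.array([simulate_gwas_z(sigma, np.zeros(10), 1, 0.0, seed=s) for s in range(5000)])
    emp = np.cov(draws.T)
    assert np.linalg.norm(emp - sigma) < 0.1 * np.linalg.norm(sigma) + 0.35


def test_gwas_z_dimension_mismatch():
    with pytest.raises(ValueError):
        simulate_gwas_z(np.eye(3), np.zeros(4), 100, 0.0)


# --- multi-tissue ----------------------------------------------------------


@pytest.mark.parametrize("rho", [0.0, 0.3, 0.7])
def test_multitissue_weight_correlation_recovers_rho(rho):
    reps = 600
    pairs = []
    rng = np.random.default_rng(77)
    X = {name: np.zeros((5, 4)) for name in ["causal", "c1", "u1"]}
    for _ in range(reps):
        w0 = rng.normal(0, np.sqrt(0.1 / 4), size=4)
        out = simulate_multitissue(X, w0, rho, 1, 1, h2_e=0.1, seed=rng,
                                   weight_variances=np.full(4, 0.1 / 4))
        pairs.append(np.c_[w0, out["c1"][1]])
    flat = np.concatenate(pairs)
    c = np.corrcoef(flat.T)[0, 1]
    se = (1 - rho**2) / np.sqrt(flat.shape[0])
    assert abs(c - rho) < 3 * se + 0.01


def test_multitissue_uncorrelated_tissue_independent():
    rng = np.random.default_rng(78)
    X = {name: np.zeros((5, 4)) for name in ["causal", "c1", "u1"]}
    pairs = []
    for _ in range(500):
        w0 = rng.normal(0, np.sqrt(0.1 / 4), size=4)
        out = simulate_multitissue(X, w0, 0.7, 1, 1, h2_e=0.1, seed=rng,
                                   weight_variances=np.full(4, 0.1 / 4))
        pairs.append(np.c_[w0, out["u1"][1]])
    flat = np.concatenate(pairs)
    assert abs(np.corrcoef(flat.T)[0, 1]) < 3 / np.sqrt(flat.shape[0]) + 0.01


def test_multitissue_counts_and_validation():
    X = {n: np.zeros((5, 3)) for n in ["causal", "c1", "c2"]}
    out = simulate_multitissue(X, np.zeros(3), 0.3, 2, 0, 0.1, seed=1)
    assert set(out) == {"causal", "c1", "c2"}
    with pytest.raises(ValueError):
        simulate_multitissue(X, np.zeros(3), 1.5, 2, 0, 0.1)


# --- error rates -----------------------------------------------------------


def test_error_rate_all_null_uniform(rng):
    p = rng.uniform(size=1000)
    rep = evaluate_error_rates(p, np.ones(1000, dtype=bool))
    lo, hi = stats.binom.interval(0.99, 1000, 0.05)
    assert lo / 1000 <= rep.type1 <= hi / 1000
    assert rep.power is None


def test_error_rate_power_and_nan_handling():
    p = np.array([1e-9, 1.0, np.nan, 0.03])
    null = np.array([False, False, True, True])
    rep = evaluate_error_rates(p, null)
    assert rep.power == pytest.approx(0.5)
    assert rep.type1 == pytest.approx(1.0)  # only the non-NaN null gene
    assert rep.n_null == 1


def test_all_p_one_gives_zero_power():
    rep = evaluate_error_rates(np.ones(10), np.zeros(10, dtype=bool))
    assert rep.power == 0.0


# --- end-to-end replicate generation ---------------------------------------


def test_replicate_causal_placement_and_annotation():
    for mode in ("1Mb", "250kb", "3D"):
        cfg = SingleTissueSimConfig(window_mode=mode, p_causal_epi=0.8, n_causal=8,
                                    h2_p=0.0, seed=11)
        sim = generate_replicate(cfg, GenotypeFixtureConfig(), 0)
        kind = {"1Mb": "linear_1mb", "250kb": "linear_250kb", "3D": "tad"}[mode]
        win = next(w for w in sim.windows if w.kind == kind)
        pos = sim.genotypes.variants["pos"].to_numpy()
        causal = np.flatnonzero(sim.weights != 0)
        assert all(win.contains("1", pos[i]) for i in causal)
        # essential labels honor p_causal_epi among causal SNPs
        n_epi_causal = sim.essential_mask[causal].sum()
        assert n_epi_causal == round(8 * 0.8)
        assert set(sim.causal_idx_epi) <= set(np.flatnonzero(sim.essential_mask))


def test_replicate_deterministic():
    cfg = SingleTissueSimConfig(seed=12, h2_p=0.0)
    a = generate_replicate(cfg, GenotypeFixtureConfig(), 3)
    b = generate_replicate(cfg, GenotypeFixtureConfig(), 3)
    assert np.array_equal(a.expression, b.expression)
    assert np.array_equal(a.gwas_z, b.gwas_z)


def test_mixed_mode_uses_all_window_kinds():
    cfg = SingleTissueSimConfig(window_mode="mixed", n_causal=2, h2_p=0.0, seed=13)
    fixture = GenotypeFixtureConfig()
    kinds = set()
    for rep in range(30):
        sim = generate_replicate(cfg, fixture, rep)
        pos = sim.genotypes.variants["pos"].to_numpy()
        causal = np.flatnonzero(sim.weights != 0)
        for w in sim.windows:
            if all(w.contains("1", pos[i]) for i in causal):
                kinds.add(w.kind)
    assert {"linear_1mb", "linear_250kb", "tad"} <= kinds
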