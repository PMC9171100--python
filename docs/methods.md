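# Methods

## Prediction model

For one gene and tissue, let `E` be the residualized expression of N
reference samples and `X` the standardized dosages (mean 0, variance 1,
population scaling) of the cis-variants inside a candidate window. Variants
overlapping the union of the tissue's H3K27ac, H3K4me3, DNase and CTCF
tracks are *essential* (`X₁`); the rest are non-essential (`X₂`). The fitted
objective is

    L(β) = (1/2N) ‖E − Xβ‖² + λ Σⱼ [ α φⱼ |βⱼ| + ((1−α)/2) βⱼ² ],

with `φⱼ = φ ∈ (0, 1]` for essential predictors and 1 otherwise. Two points
about this loss are deliberate design choices rather than oversights:

* **L1-only differential weighting.** The cyclic coordinate-descent updates
  use the soft threshold `αλφⱼ` but a shared denominator
  `(1/N)XⱼᵀXⱼ + (1−α)λ`; the ridge term is therefore *not* φ-weighted. We
  treat the coordinate updates as the operational definition of the
  estimator and the loss above is the exact function they minimize; the
  solver is verified against an independent proximal-gradient (FISTA)
  minimizer of that same loss, including φ < 1.
* **α = 0.5 default.** This reproduces the half-lasso/half-ridge weighting
  of the loss as usually written (L1 coefficient λ/2, L2 coefficient λ/4
  after the 1/2N scaling); α is exposed because the updates are valid for
  any α ∈ [0, 1].

Numerical details: coordinate descent runs on the covariance statistics
C = XᵀX/N and b = XᵀE/N (cost per sweep O(p²), independent of N);
convergence is declared when the largest absolute coefficient change in a
sweep falls below `tol` (default 1e−6, 1e−4 inside large simulation sweeps);
`max_iter` defaults to 1000. Initialization is the least-squares
pseudo-inverse solution when p ≤ N and the zero vector when p > N (least
squares is undefined there); λ-paths are warm-started from the previous
solution. Updates are deterministic given the input column order, so no tie
breaking is needed. Converged fits satisfy the subgradient (KKT) conditions
coordinate-wise; this is asserted in tests rather than assumed.

The λ grid is log-spaced and descending from
`λ_max = maxⱼ |XⱼᵀE| / (N α φⱼ)` — the smallest λ whose solution is exactly
zero — down to `λ_max · lambda_min_ratio` (default ratio 0.01; 0.05 in the
simulation study). The φ grid is {1/6, 2/6, …, 1}; φ = 1 reduces the model
to a plain elastic net.

## Cis-windows

Candidate windows per gene: linear flanks (gene body ± 250 kb and ± 1 Mb,
clipped at position 1) and, where 3D data exist, the TAD/contact-domain
interval(s) overlapping the gene body (union when the gene spans two), and
loop/pcHi-C windows equal to the gene body ∪ promoter plus every anchor
whose mate anchor touches the promoter or body. The promoter is TSS ± 2 kb
(configurable; no standard definition exists). 3D window kinds with no
qualifying interval are omitted; a window covering fewer than two variants
is skipped. Anchors are matched against both promoter and gene body — the
more inclusive of the plausible conventions.

## Training and assessment

Nested 5×5 cross-validation: the outer loop measures performance, the inner
loop (within each outer training fold) selects the `(w, φ, λ)` triple
minimizing mean squared prediction error, with standardization statistics
always computed on training folds only. The deployed model refits all
samples with the triple chosen by inner CV on the full data (rather than a
vote over outer folds — simpler and uses all data for selection). Fold
assignment is a deterministic function of (seed, sample IDs), so results
are bit-for-bit reproducible.

Per-fold Spearman correlations r_k are combined as z_k = r_k √(n_k − 1)
(asymptotic null variance of Spearman's r is 1/(n − 1)), summed, and
divided by √K; the model p-value is the one-sided upper tail. One-sided is
the coherent choice given the directional deployment rule
`mean(r_k) > 0.1`. Folds with constant predictions contribute r = 0. A
model is significant when cv_r > 0.1 *and* cv_p < 0.05 (strict
inequalities).

## Association, combination, fine-mapping

The gene-level statistic is S = βᵀZ / √(βᵀΣ_reg β) with
Σ_reg = (1−θ)Σ + θI, θ = 0.1 by default (the regularization keeps Σ
invertible and well-conditioned; the constant is configurable and recorded).
Model variants missing from the GWAS get the conditional-MVN imputation
Ẑ_u = Σ_uo (Σ_oo + 0.1·I)⁻¹ Z_o; genes with under half their absolute
weight mass observed are flagged low-confidence. Allele harmonization flips
Z signs for ref/alt swaps, resolves strand flips by complementing, and
drops strand-ambiguous (A/T, C/G) variants outright, since allele
frequencies are not guaranteed in summary files.

Cauchy combination: T = Σ wᵢ tan((0.5 − pᵢ)π), p_comb = 0.5 − arctan(T)/π,
equal weights by default, inputs clipped to [1e−300, 1 − 1e−16]. The
operation is n-ary; the "+" pipeline uses exactly two inputs
(single-tissue + multi-tissue p-value).

Fine-mapping transforms p-values by T = Φ⁻¹(1 − p), the standard copula
convention (this transform is occasionally mis-written as 1 − Φ⁻¹(p),
which is a different function; we implement the former).
Loci are defined iteratively: the most significant unassigned gene anchors
a locus equal to its containing LD block (or TSS ± 1 Mb without blocks),
absorbing all genes with TSS inside. Correlations between gene statistics
are estimated by Monte Carlo (default 1000 reps): null SNP z-scores are
drawn from MVN(0, Σ) over the union panel and pushed through each gene's
statistic pipeline. For the plain linear statistic the pipeline returns S
itself (sign preserved; its correlation has the closed form
β₁ᵀΣβ₂/√(β₁ᵀΣβ₁·β₂ᵀΣβ₂), used as a test oracle); for combined-p pipelines
it returns Φ⁻¹(1 − p_comb), matching how observed combined p-values enter.
Folding the plain statistic through a two-sided p first would destroy the
sign and the closed form — hence the statistic-level interface.

Within a locus, ABF(g) = (ψ²+1)^{−1/2} exp(ψ²z²/(2(1+ψ²))) with ψ = 0.05,
computed in log space; PIPs are ABFs normalized to sum 1; the credible set
is the smallest PIP-descending prefix reaching the level (default 0.90),
ties broken by smaller p then gene id. Secondary signals: conditioning on
the top gene via z′_j = (z_j − r_{j,top} z_top)/√(1 − r²_{j,top}), with
another fine-mapping round while any conditional p stays below the
per-tissue Bonferroni threshold, at most 3 rounds (no principled stopping
rule exists beyond exhaustion; collinear duplicates get conditional z = 0).

## Simulation framework

The generator emulates the study conditions the method was validated under:

* **Genotypes.** Real cohort genotypes are replaced by a block-LD
  generator: latent MVN with AR(1) correlation (r = 0.7) within consecutive
  blocks of 6 SNPs, thresholded twice per haplotype at a uniform random MAF
  in [0.05, 0.5]. Default m = 30 cis-SNPs per gene spread uniformly over
  the ±1 Mb window; the LD matrix Σ_G for z-score simulation is estimated
  from an independent reference draw of 5000 samples from the same process.
* **Annotation and windows.** Causal SNPs are placed inside the designated
  window (±1 Mb, ±250 kb, a synthetic TAD of gene ± 400 kb, or one of the
  three at random in "mixed" mode); `round(n_causal · p_causal_epi)` causal
  SNPs are made essential, non-causal SNPs are essential with background
  probability 0.3 (a realistic mark-union coverage), and tracks are
  synthesized so the classifier reproduces exactly these labels.
* **Effects.** h²_epi = h²_e · EF·M_epi / (EF·M_epi + M_notepi) — the
  unique split with total h²_e and per-SNP variance ratio EF; weights are
  normal with per-SNP variances h²_epi/M_epi, h²_notepi/M_notepi.
* **Expression.** E = Xw + ε, ε ~ N(0, 1 − h²_e). No post-hoc rescaling:
  under LD the realized genetic variance fluctuates around h²_e.
* **GWAS.** Z ~ MVN(Σ_G √(N_gwas h²_p) w, Σ_G), N_gwas = 500,000, one draw
  per replicate via an eigenvalue-floored factorization. An optional flag
  normalizes w by √(wᵀΣ_G w) first so the gene explains exactly h²_p; the
  default leaves w unscaled, matching the formula as printed.
* **Multi-tissue.** Correlated tissues draw per-SNP weights
  w_corr ~ N(ρ·w_causal, (1−ρ²)·v) with v the causal per-SNP weight
  variance, giving corr(w_corr, w_causal) = ρ exactly and preserving h²_e;
  uncorrelated tissues use ρ = 0; residuals are independent across tissues.

Type I error is the fraction of null genes (h²_p = 0) with p < 0.05; power
is the fraction of non-null genes with p < 5×10⁻⁵ (the Bonferroni threshold
for 1000 simulated genes). Genes whose selected model has no nonzero
weights are untestable and excluded from the rates (their count is
reported).

What passing simulations do *not* show: the generator has no allele-
frequency spectrum matched to real cohorts, no long-range LD, no
population structure, uniform SNP density, a single synthetic TAD, and
annotation tracks that are point intervals — so calibration and power here
validate the statistical machinery, not performance on any particular
real tissue or trait.

## Problem sizes and defaults used in shipped checks

Simulation-backed checks use m = 30 SNPs, a 5-value λ grid
(lambda_min_ratio 0.05), the full 6-value φ grid, solver tol 1e−4 with
max_iter 200, and 1000 replicates for the null-calibration check, 300 per
point for the power sweep, and 200 for the φ-preference check — scaled-down
replicate counts chosen as the package's own desk-scale defaults. The
"no-preference" control for the φ mechanism uses EF = 1 with the causal
essential fraction equal to the background essential fraction (0.3), which
makes annotation carry no information; "preference for small φ" is
measured by a one-sided sign test on selections in the lower (φ ≤ 1/2)
versus upper (φ ≥ 2/3) half of the grid (the grid has no middle element).
The one-sided form is deliberate: without enrichment, reduced penalties on
a random subset only add cross-validation noise, so control selections
concentrate at φ = 1 — a real effect in the direction opposite to the
enrichment mechanism, and not evidence of it.

## Known limitations

* Dosage-TSV inputs without `chrom:pos:ref:alt`-style ids lose coordinates
  and cannot be window-subset or harmonized.
* The model store keeps weights on the standardized-dosage scale; applying
  them to a new cohort assumes comparable allele frequencies.
* Fine-mapping conditions on gene-level statistics only; flanking
  single-variant signals are not modelled.
* The CLI `twas` command requires a single LD matrix file covering all
  model variants — adequate at desk scale, not genome-wide.
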