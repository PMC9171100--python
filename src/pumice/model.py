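"""Model/Results front end for gene expression prediction.

``PumiceModel`` bundles the data for one gene (cis-genotypes, residualized
expression, candidate cis-windows, essential-variant annotation); ``fit``
runs the nested cross-validation over (window, phi, lambda) and returns a
``PumiceResults`` carrying the deployed weights, cross-validated performance
and a summary table. Association against GWAS summary statistics hangs off
the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import build_candidate_windows, classify_essential
from .containers import Gene, GenotypeMatrix
from .train import DEFAULT_PHI_GRID, CVReport, TrainedModel, nested_cv_train
from .twas import impute_missing_z, twas_association


class PumiceModel:
    """Differential-penalty elastic-net expression model for one gene.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        Raw cis-dosages (standardization happens per training fold).
    expression : array-like
        Residualized expression for the same samples, in order.
    gene : Gene
        Gene coordinates (start = TSS).
    windows : list of CisWindow, optional
        Candidate cis-windows; built from ``tad_set``/``domain_set``/
        ``loop_set``/``pchic_set`` tables when omitted.
    tracks : DataFrame, optional
        Union of epigenomic mark intervals defining essential variants.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        expression,
        gene: Gene,
        windows=None,
        tracks=None,
        *,
        tissue: str = "tissue",
        essential_mask=None,
        tad_set=None,
        domain_set=None,
        loop_set=None,
        pchic_set=None,
        linear_sizes=(250_000, 1_000_000),
    ):
        self.genotypes = genotypes
        self.expression = np.asarray(expression, dtype=float)
        self.gene = gene
        self.tissue = tissue
        self.windows = windows if windows is not None else build_candidate_windows(
            gene, linear_sizes, tad_set=tad_set, domain_set=domain_set,
            loop_set=loop_set, pchic_set=pchic_set,
        )
        if essential_mask is not None:
            from .annotate import PenaltyPartition

            self.partition = PenaltyPartition.from_mask(essential_mask)
        else:
            self.partition = classify_essential(genotypes.variants, tracks)
        self.essential_mask = self.partition.essential_mask(genotypes.n_variants)

    @classmethod
    def from_tables(cls, genotypes, expression_table, gene, **kwargs):
        """Build from an ExpressionTable, aligning samples by identifier."""
        gm = genotypes.align_samples(expression_table.samples)
        return cls(gm, expression_table.gene_vector(gene.gene_id), gene, **kwargs)

    def fit(self, seed: int = 0, phi_grid=DEFAULT_PHI_GRID, **cv_opts) -> "PumiceResults":
        model, report = nested_cv_train(
            self.genotypes,
            self.expression,
            self.gene,
            self.windows,
            phi_grid=phi_grid,
            seed=seed,
            tissue=self.tissue,
            essential_mask=self.essential_mask,
            **cv_opts,
        )
        return PumiceResults(self, model, report)


class PumiceResults:
    """Fitted model: deployed weights plus cross-validated diagnostics."""

    def __init__(self, model: PumiceModel, trained: TrainedModel, report: CVReport):
        self.model = model
        self.trained = trained
        self.report = report

    # estimates -------------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Nonzero weights (standardized-dosage scale), indexed by variant."""
        return pd.Series({v: w for v, (_, _, w) in self.trained.weights.items()}, dtype=float)

    @property
    def cv_r(self) -> float:
        return self.trained.cv_r

    @property
    def cv_p(self) -> float:
        return self.trained.cv_p

    @property
    def significant(self) -> bool:
        return self.trained.significant

    def predict(self, genotypes: GenotypeMatrix) -> np.ndarray:
        """Predicted expression on new standardized genotypes."""
        gm = genotypes.standardize()
        beta = self.trained.beta_for(list(gm.variants["variant_id"]))
        return gm.dosages @ beta

    def association(self, gwas, ld, shrink: float = 0.1, ridge: float = 0.1):
        """Summary-statistic gene-trait association using this model.

        ``gwas`` is a harmonized GWASSummaryTable; ``ld`` an LDReference
        covering the model variants. Missing z-scores are Gaussian-imputed.
        """
        vids = list(self.trained.weights)
        beta = self.trained.beta_for(vids)
        z = gwas.z_for(vids).to_numpy(dtype=float)
        observed = np.isfinite(z)
        sigma = ld.submatrix(vids)
        z = impute_missing_z(np.where(observed, z, 0.0), observed, sigma, ridge=ridge)
        mass = float(np.abs(beta[observed]).sum() / np.abs(beta).sum()) if np.abs(beta).sum() else 0.0
        return twas_association(
            beta, z, sigma, shrink=shrink,
            gene_id=self.trained.gene_id, tissue=self.trained.tissue,
            n_imputed=int((~observed).sum()), weight_mass_observed=mass,
        )

    def summary(self) -> str:
        t = self.trained
        lines = [
            "PUMICE expression model",
            "=" * 47,
            f"gene:                {t.gene_id}",
            f"tissue:              {t.tissue}",
            f"selected window:     {t.selected_w}",
            f"selected phi:        {t.selected_phi:.4g}",
            f"selected lambda:     {t.selected_lambda:.4g}",
            f"nonzero weights:     {len(t.weights)}",
            f"cv Spearman r:       {t.cv_r:.4f}",
            f"cv p (Stouffer):     {t.cv_p:.3g}",
            f"significant model:   {t.significant}",
            "-" * 47,
            "fold Spearman r: " + ", ".join(f"{r:.3f}" for r in self.report.fold_r),
        ]
        return "\n".join(lines)

    def __repr__(self):
        t = self.trained
        return (
            f"<PumiceResults {t.gene_id} window={t.selected_w} phi={t.selected_phi:.3g} "
            f"cv_r={t.cv_r:.3f}>"
        )
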