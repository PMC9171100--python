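"""In-memory containers shared across the pipeline.

Genotypes are held as a dense sample x variant dosage matrix with a pandas
variant table carrying coordinates and alleles; expression as a sample x gene
table of residualized (covariate-adjusted) values. All genomic positions are
1-based internally; BED-style inputs are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: columns every variant table must carry
VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "maf")


def make_variant_table(variant_id, chrom, pos, ref, alt, maf) -> pd.DataFrame:
    """Assemble a variant table and enforce its invariants.

    ``maf`` is folded into [0, 0.5]; duplicate variant ids or non-positive
    positions raise ``ValueError``.
    """
    tbl = pd.DataFrame(
        {
            "variant_id": np.asarray(variant_id, dtype=object),
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": np.asarray(ref, dtype=object),
            "alt": np.asarray(alt, dtype=object),
            "maf": np.minimum(np.asarray(maf, dtype=float), 1.0 - np.asarray(maf, dtype=float)),
        }
    )
    dup = tbl["variant_id"][tbl["variant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant ids: {sorted(set(dup))}")
    if (tbl["pos"] < 1).any():
        raise ValueError("variant positions must be 1-based (pos >= 1)")
    if ((tbl["maf"] < 0) | (tbl["maf"] > 0.5)).any():
        raise ValueError("maf must fold into [0, 0.5]")
    return tbl.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with variant metadata.

    ``dosages`` holds additively coded dosages in [0, 2] when raw, or
    column-standardized values (mean 0, variance 1, ddof=0) when
    ``standardized`` is True.
    """

    samples: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray
    standardized: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def standardize(self) -> "GenotypeMatrix":
        """Return a copy with each column centered and scaled to unit variance.

        Zero-variance columns are centered only (scale 1) so downstream code
        sees exact zeros rather than NaNs; such columns should normally have
        been removed by the monomorphic filter.
        """
        if self.standardized:
            return self
        mu = self.dosages.mean(axis=0)
        sd = self.dosages.std(axis=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        return replace(self, dosages=(self.dosages - mu) / sd, standardized=True)

    def take_variants(self, idx) -> "GenotypeMatrix":
        """Column subset (order preserved as given by ``idx``)."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def align_samples(self, sample_ids) -> "GenotypeMatrix":
        order = pd.Index(self.samples).get_indexer(sample_ids)
        if (order < 0).any():
            missing = [s for s, o in zip(sample_ids, order) if o < 0]
            raise KeyError(f"samples absent from genotype matrix: {missing}")
        return replace(self, samples=np.asarray(sample_ids, dtype=object), dosages=self.dosages[order])

    def correlation(self) -> np.ndarray:
        """Pairwise dosage correlation (the LD matrix of this sample)."""
        x = self.standardize().dosages
        return (x.T @ x) / x.shape[0]


@dataclass
class ExpressionTable:
    """Sample x gene residualized expression values (unitless)."""

    samples: np.ndarray
    genes: np.ndarray
    values: np.ndarray
    standardized_per_gene: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError("expression value shape does not match samples x genes")

    def gene_vector(self, gene_id: str) -> np.ndarray:
        j = np.flatnonzero(self.genes == gene_id)
        if len(j) == 0:
            raise KeyError(f"gene {gene_id!r} not in expression table")
        return self.values[:, j[0]]


@dataclass
class Gene:
    """Gene coordinates; ``start`` is the TSS, ``end`` the TES (1-based)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def tss(self) -> int:
        return self.start


@dataclass
class GWASSummaryTable:
    """Harmonized GWAS summary statistics aligned to a variant table.

    Z-score signs follow the variant table's alt allele.
    """

    table: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, z, n
    n_dropped: int = 0
    n_flipped: int = 0

    def z_for(self, variant_ids) -> pd.Series:
        s = self.table.set_index("variant_id")["z"]
        return s.reindex(variant_ids)
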