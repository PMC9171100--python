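"""Readers and writers for the standard formats the pipeline touches.

VCF parsing goes through cyvcf2; BED/BEDPE/TSV through pandas. BED inputs are
0-based half-open and are converted to 1-based closed coordinates here, at the
boundary — nothing downstream sees BED conventions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GWASSummaryTable, Gene, GenotypeMatrix, make_variant_table

logger = logging.getLogger("pumice")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format_hint=None, maf_min=0.01) -> GenotypeMatrix:
    """Load a dosage matrix from a VCF or a headered dosage TSV.

    Variants with folded MAF below ``maf_min`` (or monomorphic) are removed.
    Non-biallelic VCF records are skipped with a logged count; duplicate
    variant ids raise.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    fmt = format_hint
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    gm = _read_vcf(path) if fmt == "vcf" else _read_dosage_tsv(path)
    return _filter_maf(gm, maf_min)


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ds = None
        try:
            arr = rec.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).ravel()
        except Exception:
            ds = None
        if ds is None:
            gts = rec.genotype.array()[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(ds)
    if n_multi:
        logger.info("skipped %d non-biallelic records in %s", n_multi, path)
    dosages = np.asarray(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    # mean-impute sporadic missing genotypes
    if dosages.size and np.isnan(dosages).any():
        col_mean = np.nanmean(dosages, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = col_mean[nan_c]
    maf = dosages.mean(axis=0) / 2.0 if dosages.size else np.empty(0)
    variants = make_variant_table(ids, chroms, poss, refs, alts, maf)
    return GenotypeMatrix(samples=np.asarray(samples, dtype=object), variants=variants, dosages=dosages)


def _read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage TSV dialect: header row of variant ids, first column sample id,
    values in [0, 2]. Variant coordinates are parsed from ids of the form
    ``chrom:pos:ref:alt`` when available, else left as placeholders."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    chroms, poss, refs, alts = [], [], [], []
    for vid in ids:
        parts = vid.split(":")
        if len(parts) == 4:
            chroms.append(parts[0]); poss.append(int(parts[1])); refs.append(parts[2]); alts.append(parts[3])
        else:
            chroms.append("NA"); poss.append(1); refs.append("N"); alts.append("N")
    dosages = df.to_numpy(dtype=float)
    maf = dosages.mean(axis=0) / 2.0 if dosages.size else np.empty(0)
    variants = make_variant_table(ids, chroms, poss, refs, alts, maf)
    return GenotypeMatrix(samples=df.index.to_numpy(dtype=object), variants=variants, dosages=dosages)


def _filter_maf(gm: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    var = gm.dosages.var(axis=0) if gm.n_variants else np.empty(0)
    keep = np.flatnonzero((gm.variants["maf"].to_numpy() >= maf_min) & (var > 0))
    dropped = gm.n_variants - len(keep)
    if dropped:
        logger.info("dropped %d variants (maf < %g or monomorphic)", dropped, maf_min)
    return gm.take_variants(keep)


# ---------------------------------------------------------------------------
# intervals and interactions


def read_intervals(path) -> pd.DataFrame:
    """Read BED3+ into a table of 1-based closed intervals.

    Columns: chrom, start, end, label. Records with start >= end (in BED
    coordinates) are rejected with a message. Overlapping intervals are
    preserved unmerged.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end ({start} >= {end})")
            rows.append((f[0], start + 1, end, f[3] if len(f) > 3 else ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])


def read_interactions(path) -> pd.DataFrame:
    """Read a BEDPE-like six-column file of paired anchors.

    Returns 1-based closed anchors with a ``trans`` flag for pairs whose
    anchors sit on different chromosomes (kept, but excluded from cis-window
    construction downstream).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: BEDPE needs >= 6 columns, got {len(f)}")
            ca, sa, ea, cb, sb, eb = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            rows.append((ca, sa + 1, ea, cb, sb + 1, eb, ca != cb))
    return pd.DataFrame(
        rows,
        columns=["chromA", "startA", "endA", "chromB", "startB", "endB", "trans"],
    )


def read_genes(path) -> list[Gene]:
    """Gene coordinates from BED4 or a 4-column TSV (gene_id, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    first = str(df.iloc[0, 1])
    if first.isdigit():  # gene_id  chrom  start  end  (1-based TSV)
        return [Gene(str(r[0]), str(r[1]), int(r[2]), int(r[3])) for r in df.itertuples(index=False)]
    # BED: chrom start end name
    return [Gene(str(r[3]), str(r[0]), int(r[1]) + 1, int(r[2])) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# GWAS summary statistics


def read_gwas(path, variant_table: pd.DataFrame) -> GWASSummaryTable:
    """Read GWAS summary statistics and harmonize Z signs to the variant
    table's alt allele.

    Matching is by variant_id; allele flips negate Z, strand flips are
    resolved by complementing, and strand-ambiguous (A/T, C/G) variants are
    dropped. Unmatchable rows are dropped with counts logged.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "z" not in cols:
        raise ValueError(f"{path}: missing Z column")

    def col(*names, required=True):
        for n in names:
            if n in cols:
                return cols[n]
        if required:
            raise ValueError(f"{path}: missing one of columns {names}")
        return None

    vid_c = col("variant_id", "snp", "id")
    ea_c = col("effect_allele", "a1")
    oa_c = col("other_allele", "a2")
    n_c = col("n", "sample_size", required=False)

    ref_tbl = variant_table.set_index("variant_id")
    out_rows, n_dropped, n_flipped = [], 0, 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        vid = str(d[vid_c])
        if vid not in ref_tbl.index:
            n_dropped += 1
            continue
        ea, oa = str(d[ea_c]).upper(), str(d[oa_c]).upper()
        if _is_palindromic(ea, oa):
            n_dropped += 1
            continue
        ref, alt = ref_tbl.loc[vid, "ref"].upper(), ref_tbl.loc[vid, "alt"].upper()
        z = float(d[cols["z"]])
        cea, coa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
        if (ea, oa) == (alt, ref) or (cea, coa) == (alt, ref):
            pass  # effect allele is alt: sign already aligned
        elif (ea, oa) == (ref, alt) or (cea, coa) == (ref, alt):
            z = -z
            n_flipped += 1
        else:
            n_dropped += 1
            continue
        out_rows.append(
            (
                vid,
                ref_tbl.loc[vid, "chrom"],
                int(ref_tbl.loc[vid, "pos"]),
                alt,
                ref,
                z,
                int(d[n_c]) if n_c else 0,
            )
        )
    if n_dropped:
        logger.info("read_gwas: dropped %d rows (unmatched/ambiguous)", n_dropped)
    table = pd.DataFrame(
        out_rows,
        columns=["variant_id", "chrom", "pos", "effect_allele", "other_allele", "z", "n"],
    )
    if not np.isfinite(table["z"]).all():
        raise ValueError("non-finite Z after harmonization")
    return GWASSummaryTable(table=table, n_dropped=n_dropped, n_flipped=n_flipped)


# ---------------------------------------------------------------------------
# LD matrices (square TSV, variant ids as header and index)


def write_ld_matrix(variant_ids, corr, path) -> None:
    pd.DataFrame(np.asarray(corr, dtype=float), index=list(variant_ids), columns=list(variant_ids)).to_csv(
        path, sep="\t"
    )


def read_ld_matrix(path):
    from .twas import LDReference

    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDReference(variant_ids=[str(c) for c in df.columns], corr=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# model store (TSV of weights + JSON sidecar of metadata)

STORE_VERSION = "1"


@dataclass
class ModelStore:
    """Persisted per-(gene, tissue) prediction models."""

    weights: pd.DataFrame  # gene_id, tissue, variant_id, ref, alt, weight
    meta: dict = field(default_factory=dict)  # (gene_id, tissue) -> metadata dict

    def models(self):
        return list(self.meta)


def write_model_store(models, path) -> None:
    """Write trained models to ``path`` (directory): weights.tsv + meta.json.

    ``models`` is an iterable of :class:`pumice.train.TrainedModel`.
    """
    os.makedirs(path, exist_ok=True)
    rows, meta = [], {}
    for m in models:
        for vid, (ref, alt, w) in m.weights.items():
            rows.append((m.gene_id, m.tissue, vid, ref, alt, w))
        meta[f"{m.gene_id}\t{m.tissue}"] = {
            "selected_w": m.selected_w,
            "selected_phi": m.selected_phi,
            "selected_lambda": m.selected_lambda,
            "cv_r": m.cv_r,
            "cv_p": m.cv_p,
            "significant": bool(m.significant),
            "seed": m.seed,
            "version": STORE_VERSION,
        }
    pd.DataFrame(rows, columns=["gene_id", "tissue", "variant_id", "ref", "alt", "weight"]).to_csv(
        os.path.join(path, "weights.tsv"), sep="\t", index=False
    )
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_model_store(path) -> ModelStore:
    weights = pd.read_csv(os.path.join(path, "weights.tsv"), sep="\t", dtype={"gene_id": str, "tissue": str, "variant_id": str})
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    for key, m in meta.items():
        if m.get("version") != STORE_VERSION:
            logger.warning("model store %s: version mismatch for %s", path, key)
    return ModelStore(weights=weights, meta=meta)
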