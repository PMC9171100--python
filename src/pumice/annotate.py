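"""Essential-variant classification and candidate cis-window construction.

A cis-variant is "essential" when it overlaps the union of the supplied
epigenomic mark tracks (H3K27ac, H3K4me3, DNase hypersensitivity, CTCF);
essential predictors later receive the reduced penalty phi*lambda. Candidate
cis-windows come in two flavours: linear flanks around the gene body, and
3D-genome informed regions (TAD, contact domain, chromatin loop, pcHi-C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import Gene, GenotypeMatrix

logger = logging.getLogger("pumice")

WINDOW_KINDS = ("linear_250kb", "linear_1mb", "loop", "tad", "domain", "pchic")


@dataclass
class PenaltyPartition:
    """Split of cis-variant column indices into essential / non-essential."""

    essential_idx: np.ndarray
    nonessential_idx: np.ndarray

    def __post_init__(self):
        self.essential_idx = np.asarray(self.essential_idx, dtype=int)
        self.nonessential_idx = np.asarray(self.nonessential_idx, dtype=int)
        if np.intersect1d(self.essential_idx, self.nonessential_idx).size:
            raise ValueError("essential and non-essential index sets overlap")

    @property
    def n_variants(self) -> int:
        return len(self.essential_idx) + len(self.nonessential_idx)

    def essential_mask(self, p: int | None = None) -> np.ndarray:
        p = self.n_variants if p is None else p
        mask = np.zeros(p, dtype=bool)
        mask[self.essential_idx] = True
        return mask

    @classmethod
    def from_mask(cls, mask) -> "PenaltyPartition":
        mask = np.asarray(mask, dtype=bool)
        return cls(np.flatnonzero(mask), np.flatnonzero(~mask))

    def restrict(self, idx) -> "PenaltyPartition":
        """Partition of the column subset ``idx`` (indices renumbered)."""
        mask = self.essential_mask()
        return PenaltyPartition.from_mask(mask[np.asarray(idx, dtype=int)])


@dataclass
class CisWindow:
    """A candidate cis-region for one gene (1-based closed intervals)."""

    gene_id: str
    kind: str
    intervals: list  # [(chrom, start, end), ...]

    def __post_init__(self):
        if self.kind not in WINDOW_KINDS and not self.kind.startswith("linear_"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if not self.intervals:
            raise ValueError("cis-window must contain at least one interval")

    def contains(self, chrom, pos) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.intervals)


def _norm_chrom(c: str) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def _build_trees(tracks: pd.DataFrame) -> dict:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in tracks.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(grp["start"], grp["end"]):
            t.addi(int(s), int(e) + 1)  # closed -> half-open for the tree
        trees[_norm_chrom(chrom)] = t
    return trees


def classify_essential(variants: pd.DataFrame, tracks: pd.DataFrame | None) -> PenaltyPartition:
    """Mark variants overlapping >= 1 interval of the track union as essential.

    ``tracks`` is the union of the mark interval tables (1-based closed, as
    produced by :func:`pumice.io.read_intervals`); ``None`` or empty means no
    annotation, so every variant is non-essential. Chromosome names are
    normalized ("chr1" vs "1") with a single warning when they differ.
    """
    p = len(variants)
    if tracks is None or len(tracks) == 0:
        return PenaltyPartition(np.empty(0, dtype=int), np.arange(p))
    v_chroms = set(map(str, variants["chrom"].unique()))
    t_chroms = set(map(str, tracks["chrom"].unique()))
    if v_chroms and t_chroms and not (v_chroms & t_chroms):
        logger.warning("chromosome naming differs between variants and tracks; normalizing")
    trees = _build_trees(tracks)
    mask = np.zeros(p, dtype=bool)
    chroms = variants["chrom"].map(_norm_chrom).to_numpy()
    poss = variants["pos"].to_numpy()
    for i in range(p):
        tree = trees.get(chroms[i])
        if tree is not None and tree.overlaps_point(int(poss[i])):
            mask[i] = True
    return PenaltyPartition.from_mask(mask)


def _union_intervals(ivals):
    """Union of 1-based closed intervals on a single chromosome."""
    ivals = sorted(ivals)
    merged = []
    for s, e in ivals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_candidate_windows(
    gene: Gene,
    linear_sizes=(250_000, 1_000_000),
    tad_set: pd.DataFrame | None = None,
    domain_set: pd.DataFrame | None = None,
    loop_set: pd.DataFrame | None = None,
    pchic_set: pd.DataFrame | None = None,
    promoter_flank: int = 2_000,
) -> list[CisWindow]:
    """Construct the candidate cis-window set w for one gene.

    Linear windows flank the gene body by each size in ``linear_sizes``
    (clipped at position 1). TAD/domain windows are the union of intervals
    overlapping the gene body. Loop/pcHi-C windows are the gene body plus
    promoter (TSS +/- ``promoter_flank``) unioned with every anchor whose mate
    anchor overlaps the promoter or body. 3D kinds with no qualifying
    interval are omitted.
    """
    chrom = _norm_chrom(gene.chrom)
    g_start, g_end = min(gene.start, gene.end), max(gene.start, gene.end)
    windows: list[CisWindow] = []

    for s in sorted(linear_sizes):
        name = f"linear_{s // 1000}kb" if s < 1_000_000 else f"linear_{s // 1_000_000}mb"
        windows.append(
            CisWindow(gene.gene_id, name, [(chrom, max(1, g_start - s), g_end + s)])
        )

    def overlapping(iset):
        if iset is None or len(iset) == 0:
            return []
        sub = iset[iset["chrom"].map(_norm_chrom) == chrom]
        hits = sub[(sub["start"] <= g_end) & (sub["end"] >= g_start)]
        return list(zip(hits["start"], hits["end"]))

    for kind, iset in (("tad", tad_set), ("domain", domain_set)):
        hits = overlapping(iset)
        if hits:
            windows.append(
                CisWindow(gene.gene_id, kind, [(chrom, s, e) for s, e in _union_intervals(hits)])
            )

    prom_start = max(1, gene.tss - promoter_flank)
    prom_end = gene.tss + promoter_flank
    anchor_lo, anchor_hi = min(prom_start, g_start), max(prom_end, g_end)

    for kind, pairs in (("loop", loop_set), ("pchic", pchic_set)):
        if pairs is None or len(pairs) == 0:
            continue
        cis = pairs[~pairs["trans"]]
        cis = cis[cis["chromA"].map(_norm_chrom) == chrom]
        ivals = [(max(1, anchor_lo), anchor_hi)]  # gene body + promoter always included
        hit = False
        for row in cis.itertuples(index=False):
            a = (row.startA, row.endA)
            b = (row.startB, row.endB)
            a_touches = a[0] <= anchor_hi and a[1] >= anchor_lo
            b_touches = b[0] <= anchor_hi and b[1] >= anchor_lo
            if a_touches:
                ivals.append(b)
                hit = True
            if b_touches:
                ivals.append(a)
                hit = True
        if hit:
            windows.append(
                CisWindow(gene.gene_id, kind, [(chrom, s, e) for s, e in _union_intervals(ivals)])
            )
    return windows


class EmptyWindowError(ValueError):
    """Raised when a cis-window covers fewer than 2 variants."""


def subset_cis_variants(genotypes: GenotypeMatrix, window: CisWindow) -> tuple[GenotypeMatrix, np.ndarray]:
    """Restrict genotype columns to variants inside the window.

    Returns the subset matrix and the column indices used (order preserved).
    Raises :class:`EmptyWindowError` when the window covers fewer than 2
    variants, which callers treat as "skip this w".
    """
    chroms = genotypes.variants["chrom"].map(_norm_chrom).to_numpy()
    poss = genotypes.variants["pos"].to_numpy()
    mask = np.zeros(len(poss), dtype=bool)
    for c, s, e in window.intervals:
        mask |= (chroms == _norm_chrom(c)) & (poss >= s) & (poss <= e)
    idx = np.flatnonzero(mask)
    if len(idx) < 2:
        raise EmptyWindowError(f"window {window.kind} for {window.gene_id} has < 2 variants")
    return genotypes.take_variants(idx), idx
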