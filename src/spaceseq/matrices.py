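"""Spot x genomic-tile and spot x gene matrices, and cross-modality
concordance of accessibility-derived gene scores with gene expression.

Matrices are held as scipy CSR with explicit row (barcode) and column
(tile/gene) name lists, and serialize as MatrixMarket triplet text plus
sidecar TSVs so that everything stays plain text.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from intervaltree import IntervalTree
from scipy.stats import mannwhitneyu, pearsonr

from .fragments import iter_insertions
from .io import Fragment

TILE_WIDTH = 5000  # 5-kb tiles


@dataclass
class TileMatrix:
    """Sparse barcode x tile insertion-count matrix.

    Tiles cover every contig end to end; the last tile of a contig may be
    short.  Tile starts are multiples of the tile width.
    """

    tiles: list[tuple[str, int, int]]  # (contig, start, width)
    barcodes: list[str]
    counts: sp.csr_matrix

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tile_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def barcode_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), self.counts.tocoo())
        with open(prefix.parent / (prefix.name + ".barcodes.tsv"), "w") as fh:
            fh.write("".join(f"{b}\n" for b in self.barcodes))
        with open(prefix.parent / (prefix.name + ".tiles.tsv"), "w") as fh:
            fh.write("".join(f"{c}\t{s}\t{w}\n" for c, s, w in self.tiles))

    @classmethod
    def load(cls, prefix: str | Path) -> "TileMatrix":
        prefix = Path(prefix)
        counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
        barcodes = (prefix.parent / (prefix.name + ".barcodes.tsv")).read_text().split()
        tiles = []
        for line in (prefix.parent / (prefix.name + ".tiles.tsv")).read_text().splitlines():
            c, s, w = line.split("\t")
            tiles.append((c, int(s), int(w)))
        return cls(tiles, barcodes, counts)


@dataclass
class GeneMatrix:
    """Sparse barcode x gene score matrix (non-negative scores)."""

    genes: pd.DataFrame  # columns name, contig, start, end, strand
    barcodes: list[str]
    scores: sp.csr_matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores.toarray(), index=self.barcodes, columns=list(self.genes["name"])
        )


def build_tile_matrix(
    fragments: Iterable[Fragment],
    contig_lengths: Mapping[str, int],
    tile_width: int = TILE_WIDTH,
    count_mode: str = "both",
) -> TileMatrix:
    """Bin insertion events into fixed-width genomic tiles per barcode.

    Each fragment contributes its end positions (per ``count_mode``) to the
    tiles containing them.  A fragment extending beyond its contig's stated
    length is a hard error: it means fragments and genome disagree.
    """
    tiles: list[tuple[str, int, int]] = []
    tile_offset: dict[str, int] = {}
    for contig in contig_lengths:
        length = int(contig_lengths[contig])
        tile_offset[contig] = len(tiles)
        for start in range(0, length, tile_width):
            tiles.append((contig, start, min(tile_width, length - start)))

    barcode_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for frag in fragments:
        if frag.contig not in tile_offset:
            raise ValueError(f"fragment on unknown contig {frag.contig!r}")
        if frag.end > contig_lengths[frag.contig]:
            raise ValueError(
                f"fragment [{frag.start}, {frag.end}) exceeds {frag.contig} "
                f"length {contig_lengths[frag.contig]}"
            )
        b = barcode_index.setdefault(frag.barcode, len(barcode_index))
        ends = (frag.start, frag.end - 1) if count_mode == "both" else (frag.start,)
        for pos in ends:
            rows.append(b)
            cols.append(tile_offset[frag.contig] + pos // tile_width)
            vals.append(1)  # unique fragments, not reads: count is metadata
    barcodes = list(barcode_index)
    counts = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(barcodes), len(tiles)), dtype=np.int64
    ).tocsr()
    return TileMatrix(tiles, barcodes, counts)


def gene_score(
    fragments: Iterable[Fragment],
    genes: pd.DataFrame,
    promoter_upstream: int = 2000,
    count_mode: str = "both",
) -> GeneMatrix:
    """Count insertions in each gene body plus its promoter window.

    The score for (barcode, gene) is the number of insertion events falling
    inside the gene body or within ``promoter_upstream`` bases 5' of the TSS
    (strand-aware).  Overlapping genes each receive shared insertions.  This
    is a deliberately transparent counting model, not a distance-decay gene
    activity model.
    """
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(genes.itertuples(index=False)):
        if g.strand == "+":
            lo, hi = g.start - promoter_upstream, g.end
        else:
            lo, hi = g.start, g.end + promoter_upstream
        trees.setdefault(g.contig, IntervalTree()).addi(max(lo, 0), hi, gi)

    barcode_index: dict[str, int] = {}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for frag in fragments:
        tree = trees.get(frag.contig)
        if tree is None:
            continue
        b = barcode_index.setdefault(frag.barcode, len(barcode_index))
        ends = (frag.start, frag.end - 1) if count_mode == "both" else (frag.start,)
        for pos in ends:
            for iv in tree.at(pos):
                rows.append(b)
                cols.append(iv.data)
                vals.append(1.0)
    barcodes = list(barcode_index)
    scores = sp.coo_matrix(
        (vals, (rows, cols)), shape=(len(barcodes), len(genes)), dtype=np.float64
    ).tocsr()
    return GeneMatrix(genes.reset_index(drop=True), barcodes, scores)


def _cp10k(mat: np.ndarray) -> np.ndarray:
    """Library-size normalization: counts per 10,000 per barcode."""
    lib = mat.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return mat / lib * 1e4


def concordance(
    gene_scores: GeneMatrix,
    gene_expression: GeneMatrix,
    clusters: Mapping[str, str],
    lfc_min: float = 1.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Cross-modality concordance of accessibility gene scores and expression.

    For every gene shared between the two matrices: per-cluster means of each
    modality (on counts-per-10k values), a rank-sum test and log2 fold change
    of means (pseudocount 1) for every cluster pair in each modality, a pass
    flag that is true when any cluster pair reaches p <= p_max with
    |log2FC| >= lfc_min in either modality, and the Pearson correlation of
    per-cluster means between the two modalities.

    No multiple-testing correction is applied: the filter is on raw p-values
    by design.  Requires at least 2 clusters.
    """
    score_df = gene_scores.to_frame()
    expr_df = gene_expression.to_frame()
    shared_bc = sorted(set(score_df.index) & set(expr_df.index) & set(clusters))
    shared_genes = [g for g in score_df.columns if g in set(expr_df.columns)]
    if not shared_bc or not shared_genes:
        raise ValueError("no shared barcodes/genes between modalities")
    labels = pd.Series({b: clusters[b] for b in shared_bc})
    cluster_names = sorted(labels.unique())
    if len(cluster_names) < 2:
        raise ValueError(f"need >= 2 clusters, got {len(cluster_names)}")

    mats = {}
    for name, df in (("score", score_df), ("expr", expr_df)):
        mats[name] = pd.DataFrame(
            _cp10k(df.loc[shared_bc, shared_genes].to_numpy(dtype=float)),
            index=shared_bc,
            columns=shared_genes,
        )
    members = {c: labels.index[labels == c] for c in cluster_names}

    records = []
    for gene in shared_genes:
        passes = False
        for modality in ("score", "expr"):
            col = mats[modality][gene]
            for a, b in combinations(cluster_names, 2):
                xa = col.loc[members[a]].to_numpy()
                xb = col.loc[members[b]].to_numpy()
                lfc = np.log2((xa.mean() + 1.0) / (xb.mean() + 1.0))
                if abs(lfc) < lfc_min:
                    continue
                p = mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue
                if p <= p_max:
                    passes = True
                    break
            if passes:
                break
        means_score = np.array([mats["score"][gene].loc[members[c]].mean() for c in cluster_names])
        means_expr = np.array([mats["expr"][gene].loc[members[c]].mean() for c in cluster_names])
        if np.ptp(means_score) == 0 or np.ptp(means_expr) == 0:
            corr = np.nan
        else:
            corr = pearsonr(means_score, means_expr).statistic
        records.append({"gene": gene, "correlation": corr, "passes": passes})
    return pd.DataFrame(records).set_index("gene")
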