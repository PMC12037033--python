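"""Spot-resolved mitochondrial variant calling and heteroplasmy.

Candidate substitutions are assembled from per-barcode, per-strand allele
counts over the mitochondrial contig.  The pass filter is the strand
concordance test used in single-cell mtDNA genotyping: a genuine variant's
forward- and reverse-strand alternate-allele counts co-vary across spots
(both track the spot's mtDNA content and heteroplasmy), while strand-specific
artifacts do not.  Variants pass when the Pearson correlation of the two
strands' alt counts across covered spots is at least 0.25.

Positions are reported 1-based to match mtDNA nomenclature; everything else
in this package is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .io import AlignmentRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STRAND_CORR_MIN = 0.25
MIN_BARCODES = 5


@dataclass
class AlleleCounts:
    """Per-barcode stranded base counts along the mitochondrial contig.

    ``counts`` has shape (n_barcodes, 2 strands [fwd, rev], 4 bases, length);
    ``positions`` are implicit 0-based array indices (report 1-based).
    """

    barcodes: list[str]
    reference: str
    counts: np.ndarray  # int64 (B, 2, 4, L)

    @property
    def length(self) -> int:
        return self.counts.shape[3]

    def coverage(self) -> np.ndarray:
        """(B, L) total coverage per barcode/position, both strands."""
        return self.counts.sum(axis=(1, 2))

    def ref_index(self) -> np.ndarray:
        return np.array([_BASE_INDEX.get(b, -1) for b in self.reference.upper()])


@dataclass
class MitoVariant:
    position: int  # 1-based
    ref: str
    alt: str
    strand_correlation: float  # NaN when undefined
    mean_heteroplasmy: float
    n_supporting_barcodes: int
    passes: bool


def count_alleles(
    records: Iterable[AlignmentRecord],
    reference: str,
    min_base_quality: int = 0,
) -> AlleleCounts:
    """Build stranded per-barcode allele counts from mito-contig alignments.

    Every aligned base (the records here are ungapped single-end alignments)
    increments (barcode, strand, base, position).  Bases below the quality
    floor are skipped when qualities are available; reads without sequences
    contribute reference-allele counts over their span.  A record extending
    past the reference end is a hard error.
    """
    reference = reference.upper()
    length = len(reference)
    ref_arr = np.frombuffer(reference.encode(), dtype=np.uint8)
    barcode_index: dict[str, int] = {}
    chunks: list[tuple[int, int, int, int, str | None, tuple[int, ...] | None]] = []
    for rec in records:
        if rec.barcode is None:
            raise ValueError(f"read {rec.read_name!r} lacks a barcode")
        if rec.end > length:
            raise ValueError(
                f"read {rec.read_name!r} extends past reference end "
                f"({rec.end} > {length})"
            )
        b = barcode_index.setdefault(rec.barcode, len(barcode_index))
        s = 0 if rec.strand == "+" else 1
        chunks.append((b, s, rec.pos, rec.aligned_length, rec.sequence, rec.qualities))

    counts = np.zeros((len(barcode_index), 2, 4, length), dtype=np.int64)
    # Coverage via a difference array per (barcode, strand); mismatches and
    # quality-masked bases are corrected afterwards.
    cov_diff = np.zeros((len(barcode_index), 2, length + 1), dtype=np.int64)
    mism = np.zeros((len(barcode_index), 2, 4, length), dtype=np.int64)
    masked_diffs: list[tuple[int, int, np.ndarray]] = []
    for b, s, pos, alen, seq, quals in chunks:
        cov_diff[b, s, pos] += 1
        cov_diff[b, s, pos + alen] -= 1
        if seq is None:
            continue
        seq_arr = np.frombuffer(seq[:alen].upper().encode(), dtype=np.uint8)
        span_ref = ref_arr[pos : pos + alen]
        bad = np.zeros(alen, dtype=bool)
        if quals is not None and min_base_quality > 0:
            bad = np.array(quals[:alen]) < min_base_quality
            if bad.any():
                masked_diffs.append((b, s, pos + np.flatnonzero(bad)))
        mismatch = (seq_arr != span_ref) & ~bad
        for off in np.flatnonzero(mismatch):
            base = chr(seq_arr[off])
            bi = _BASE_INDEX.get(base)
            if bi is None:  # N call: treat as masked
                masked_diffs.append((b, s, np.array([pos + off])))
                continue
            mism[b, s, bi, pos + off] += 1

    coverage = np.cumsum(cov_diff[:, :, :-1], axis=2)
    # Remove quality-masked / N positions from coverage entirely.
    for b, s, positions in masked_diffs:
        np.subtract.at(coverage[b, s], positions, 1)
    ref_idx = np.array([_BASE_INDEX.get(chr(c), -1) for c in ref_arr])
    valid = ref_idx >= 0
    mism_total = mism.sum(axis=2)
    ref_counts = coverage - mism_total
    for b in range(counts.shape[0]):
        for s in range(2):
            counts[b, s][ref_idx[valid], np.flatnonzero(valid)] += ref_counts[b, s][valid]
    counts += mism
    return AlleleCounts(list(barcode_index), reference, counts)


def call_variants(
    counts: AlleleCounts,
    strand_corr_min: float = STRAND_CORR_MIN,
    min_barcodes: int = MIN_BARCODES,
    use_frequencies: bool = False,
) -> list[MitoVariant]:
    """Call candidate substitutions and apply the strand-correlation filter.

    For every (position, alt != ref) with a nonzero alt count, the strand
    correlation is the Pearson correlation between forward- and
    reverse-strand alt counts across barcodes with nonzero total coverage at
    that position.  It is undefined (NaN, fail) when either strand's counts
    have zero variance or fewer than ``min_barcodes`` barcodes carry the alt.
    Pass filter: strand_correlation >= strand_corr_min.

    ``use_frequencies`` correlates per-strand alt frequencies instead of raw
    counts (default raw counts).
    """
    ref_idx = counts.ref_index()
    cov = counts.coverage()  # (B, L)
    out: list[MitoVariant] = []
    alt_any = counts.counts.sum(axis=1)  # (B, 4, L)
    total_by_pos = cov.sum(axis=0)  # (L,)
    for pos in range(counts.length):
        ri = ref_idx[pos]
        if ri < 0 or total_by_pos[pos] == 0:
            continue
        for ai, alt in enumerate(BASES):
            if ai == ri:
                continue
            total_alt = int(alt_any[:, ai, pos].sum())
            if total_alt == 0:
                continue
            covered = cov[:, pos] > 0
            fwd = counts.counts[covered, 0, ai, pos].astype(float)
            rev = counts.counts[covered, 1, ai, pos].astype(float)
            if use_frequencies:
                fwd_cov = counts.counts[covered, 0, :, pos].sum(axis=1)
                rev_cov = counts.counts[covered, 1, :, pos].sum(axis=1)
                fwd = np.divide(fwd, fwd_cov, out=np.zeros_like(fwd), where=fwd_cov > 0)
                rev = np.divide(rev, rev_cov, out=np.zeros_like(rev), where=rev_cov > 0)
            n_supporting = int(np.count_nonzero(alt_any[:, ai, pos]))
            if (
                n_supporting < min_barcodes
                or len(fwd) < 2
                or np.ptp(fwd) == 0
                or np.ptp(rev) == 0
            ):
                corr = float("nan")
            else:
                corr = float(pearsonr(fwd, rev).statistic)
            mean_het = total_alt / float(total_by_pos[pos])
            passes = bool(np.isfinite(corr) and corr >= strand_corr_min)
            out.append(
                MitoVariant(
                    position=pos + 1,
                    ref=BASES[ri],
                    alt=alt,
                    strand_correlation=corr,
                    mean_heteroplasmy=mean_het,
                    n_supporting_barcodes=n_supporting,
                    passes=passes,
                )
            )
    return out


def heteroplasmy_per_spot(
    variant: MitoVariant, counts: AlleleCounts
) -> dict[str, float]:
    """Per-barcode heteroplasmy of one variant: alt / total coverage at its
    position (both strands pooled).  Barcodes with zero coverage map to NaN
    and should be excluded from spatial maps."""
    pos = variant.position - 1
    ai = _BASE_INDEX[variant.alt]
    alt = counts.counts[:, :, ai, pos].sum(axis=1)
    total = counts.counts[:, :, :, pos].sum(axis=(1, 2))
    out: dict[str, float] = {}
    for i, barcode in enumerate(counts.barcodes):
        out[barcode] = float(alt[i] / total[i]) if total[i] > 0 else float("nan")
    return out


def variants_to_frame(variants: Sequence[MitoVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (v.position, v.ref, v.alt, v.strand_correlation, v.mean_heteroplasmy,
             v.n_supporting_barcodes, v.passes)
            for v in variants
        ],
        columns=["position", "ref", "alt", "strand_correlation",
                 "mean_heteroplasmy", "n_barcodes", "pass"],
    )
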