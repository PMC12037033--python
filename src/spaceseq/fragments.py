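"""Synthetic paired-end fragments from deduplicated single-end reads, plus
per-spot QC.

Only the read's 5' end marks a genuine Tn5 insertion; the 3' end of each
fragment is synthetic (the end of the trimmed alignment).  Both ends are
nevertheless counted as insertions by default so that the fragments file
behaves like one produced from true paired-end data; a ``start``-only
counting mode is available where that bias matters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentRecord, Fragment, SpotBarcode

#: Default Tn5 insertion-site correction: +4 on the fragment start, -5 on the
#: fragment end.  (0, 0) disables the correction.
DEFAULT_TN5_SHIFT = (4, -5)


@dataclass
class QCMetrics:
    barcode: str
    n_fragments: int
    tss_enrichment: float = float("nan")
    frac_mito: float = float("nan")


def make_fragment(
    record: AlignmentRecord,
    tn5_shift: tuple[int, int] = DEFAULT_TN5_SHIFT,
) -> Fragment | None:
    """Turn one deduplicated read into a fragment interval, or None if the
    Tn5 shift collapses the interval (degenerately short alignment).

    The interval is [pos + plus_shift, pos + aligned_length + minus_shift),
    the standard start+4/end-5 correction that places both fragment ends at
    Tn5 insertion centers.  ``count`` carries the read's multiplicity.
    """
    if not record.mapped:
        raise ValueError(f"read {record.read_name!r} is unmapped")
    if record.barcode is None:
        raise ValueError(f"read {record.read_name!r} lacks a barcode")
    plus_shift, minus_shift = tn5_shift
    start = record.pos + plus_shift
    end = record.pos + record.aligned_length + minus_shift
    if start >= end or start < 0:
        return None
    return Fragment(record.contig, start, end, record.barcode, record.multiplicity)


def build_fragments_file(
    records: Iterable[AlignmentRecord],
    layout: Sequence[SpotBarcode],
    keep_off_tissue: bool = True,
    tn5_shift: tuple[int, int] = DEFAULT_TN5_SHIFT,
    mito_contig: str = "chrM",
) -> tuple[list[Fragment], pd.DataFrame, dict[str, int]]:
    """Build the sorted fragment list and per-barcode QC from deduplicated
    records.

    Barcodes absent from the layout are dropped; off-tissue barcodes are kept
    by default (QC thresholds are reported, never enforced — retention is
    deliberately permissive).  No fragment-size filtering is applied.

    Returns (fragments sorted by (contig, start, end, barcode), QC table with
    columns barcode/n_fragments/frac_mito, summary counts).
    """
    allowed = {
        s.barcode for s in layout if keep_off_tissue or s.in_tissue
    }
    summary = {
        "n_input": 0,
        "n_dropped_barcode": 0,
        "n_dropped_degenerate": 0,
        "n_fragments": 0,
        "read_mass_in": 0,
        "read_mass_out": 0,
        "read_mass_dropped": 0,
    }
    fragments: list[Fragment] = []
    for rec in records:
        summary["n_input"] += 1
        summary["read_mass_in"] += rec.multiplicity
        if rec.barcode not in allowed:
            summary["n_dropped_barcode"] += 1
            summary["read_mass_dropped"] += rec.multiplicity
            continue
        frag = make_fragment(rec, tn5_shift)
        if frag is None:
            summary["n_dropped_degenerate"] += 1
            summary["read_mass_dropped"] += rec.multiplicity
            continue
        fragments.append(frag)
        summary["read_mass_out"] += frag.count
    fragments.sort(key=lambda f: f.sort_key)
    summary["n_fragments"] = len(fragments)

    qc_rows = []
    frame = pd.DataFrame(
        [(f.barcode, f.contig, f.count) for f in fragments],
        columns=["barcode", "contig", "count"],
    )
    mito_frac = mito_fraction(fragments, mito_contig)
    if len(frame):
        n_frag = frame.groupby("barcode").size()
    else:
        n_frag = pd.Series(dtype=int)
    for spot in layout:
        if spot.barcode not in allowed:
            continue
        qc_rows.append(
            {
                "barcode": spot.barcode,
                "n_fragments": int(n_frag.get(spot.barcode, 0)),
                "frac_mito": mito_frac.get(spot.barcode, 0.0),
            }
        )
    qc = pd.DataFrame(qc_rows, columns=["barcode", "n_fragments", "frac_mito"])
    return fragments, qc, summary


def iter_insertions(
    fragments: Iterable[Fragment],
    count_mode: str = "both",
    weight_by_count: bool = False,
):
    """Yield (contig, position, weight) insertion events from fragments.

    ``both`` counts each fragment end (start and end-1) as an insertion;
    ``start`` counts only the start.  Each unique fragment contributes weight
    1 per end by default — the count column records PCR duplicates and is not
    a weight; ``weight_by_count`` restores read weighting where wanted.
    """
    if count_mode not in ("both", "start"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    for frag in fragments:
        w = frag.count if weight_by_count else 1
        yield frag.contig, frag.start, w
        if count_mode == "both":
            yield frag.contig, frag.end - 1, w


def insertion_frame(
    fragments: Iterable[Fragment], count_mode: str = "both"
) -> pd.DataFrame:
    """Columnar table of insertion events: contig, pos, barcode (one row per
    insertion; unique fragments, not reads)."""
    rows = []
    for frag in fragments:
        rows.append((frag.contig, frag.start, frag.barcode))
        if count_mode == "both":
            rows.append((frag.contig, frag.end - 1, frag.barcode))
    return pd.DataFrame(rows, columns=["contig", "pos", "barcode"])


def tss_enrichment(
    fragments: Iterable[Fragment],
    tss: Sequence[tuple[str, int, str]],
    window: int = 2000,
    flank: int = 100,
    center: int = 50,
    count_mode: str = "both",
) -> dict[str, float]:
    """Per-barcode TSS enrichment score.

    Insertions are aggregated into a strand-oriented profile over +/-window
    around every TSS, normalized by the mean count in the outermost ``flank``
    bases on each side, and the score is the normalized profile averaged over
    +/-``center`` bases of the TSS.  Barcodes with zero flank signal score 0
    with a warning.  The score is invariant under uniform scaling of
    fragment counts.
    """
    if window <= flank:
        raise ValueError(f"window ({window}) must exceed flank ({flank})")
    if not tss:
        raise ValueError("tss list is empty")
    tss_by_contig: dict[str, list[tuple[int, str]]] = {}
    for contig, pos, strand in tss:
        tss_by_contig.setdefault(contig, []).append((pos, strand))
    for contig in tss_by_contig:
        tss_by_contig[contig].sort()
    positions = {
        c: np.array([p for p, _ in v], dtype=np.int64) for c, v in tss_by_contig.items()
    }
    strand_sign = {
        c: np.array([1 if s == "+" else -1 for _, s in v], dtype=np.int64)
        for c, v in tss_by_contig.items()
    }

    width = 2 * window + 1
    profiles: dict[str, np.ndarray] = {}
    for frag in fragments:
        if frag.contig not in positions:
            continue
        tpos = positions[frag.contig]
        sign = strand_sign[frag.contig]
        ends = (frag.start, frag.end - 1) if count_mode == "both" else (frag.start,)
        profile = profiles.get(frag.barcode)
        if profile is None:
            profile = profiles[frag.barcode] = np.zeros(width, dtype=np.float64)
        for pos in ends:
            lo = np.searchsorted(tpos, pos - window, side="left")
            hi = np.searchsorted(tpos, pos + window, side="right")
            if lo == hi:
                continue
            offsets = (pos - tpos[lo:hi]) * sign[lo:hi] + window
            np.add.at(profile, offsets, float(frag.count))

    scores: dict[str, float] = {}
    center_sl = slice(window - center, window + center + 1)
    for barcode, profile in profiles.items():
        flank_mean = (profile[:flank].sum() + profile[-flank:].sum()) / (2 * flank)
        if flank_mean == 0:
            warnings.warn(
                f"barcode {barcode!r} has zero flank signal; TSS score set to 0",
                stacklevel=2,
            )
            scores[barcode] = 0.0
        else:
            scores[barcode] = float(profile[center_sl].mean() / flank_mean)
    return scores


def mito_fraction(
    fragments: Iterable[Fragment], mito_contig: str = "chrM"
) -> dict[str, float]:
    """Read-weighted fraction of each barcode's fragments on the
    mitochondrial contig; 0.0 for barcodes with no fragments at all."""
    total: dict[str, int] = {}
    mito: dict[str, int] = {}
    for frag in fragments:
        total[frag.barcode] = total.get(frag.barcode, 0) + frag.count
        if frag.contig == mito_contig:
            mito[frag.barcode] = mito.get(frag.barcode, 0) + frag.count
    return {
        bc: (mito.get(bc, 0) / t if t else 0.0) for bc, t in total.items()
    }
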