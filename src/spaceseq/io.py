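"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Fragments and all BED-like inputs use 0-based half-open intervals, matching
the de-facto fragments-file standard.  Mitochondrial variant positions are
the one exception: :mod:`spaceseq.mito` reports them 1-based to match mtDNA
nomenclature, and says so at the type level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

#: Spot barcode length in bases (Visium-style 16-mer).
BARCODE_LENGTH = 16
#: Unique molecular identifier length in bases.
UMI_LENGTH = 12

FRAGMENT_COLUMNS = ("contig", "start", "end", "barcode", "count")


class FormatError(ValueError):
    """A file violated its format contract."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One single-end mapped read.

    ``pos`` is the 0-based leftmost mapped base; ``aligned_length`` is the
    number of reference bases the alignment consumes.  ``sequence`` and
    ``qualities`` are optional and only needed for base-level operations
    (mitochondrial allele counting).  ``multiplicity`` counts how many raw
    reads this record represents; it is 1 until deduplication collapses
    duplicates onto a representative.
    """

    read_name: str
    contig: str
    pos: int
    strand: str  # "+" or "-"
    aligned_length: int
    mapped: bool = True
    barcode: str | None = None
    umi: str | None = None
    multiplicity: int = 1
    sequence: str | None = None
    qualities: tuple[int, ...] | None = None

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.pos + self.aligned_length

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's 5' end (the Tn5 insertion)."""
        return self.pos if self.strand == "+" else self.pos + self.aligned_length - 1


@dataclass(frozen=True)
class SpotBarcode:
    barcode: str
    in_tissue: bool
    array_row: int
    array_col: int
    pixel_x: float
    pixel_y: float


@dataclass(frozen=True)
class Fragment:
    """A deduplicated accessibility fragment, 0-based half-open."""

    contig: str
    start: int
    end: int
    barcode: str
    count: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment start must precede end, got [{self.start}, {self.end})"
            )
        if self.count < 1:
            raise ValueError(f"fragment count must be >= 1, got {self.count}")

    @property
    def sort_key(self) -> tuple[str, int, int, str]:
        return (self.contig, self.start, self.end, self.barcode)


@dataclass(frozen=True)
class BarcodeAssignment:
    read_name: str
    barcode: str
    umi: str


class IntervalSet:
    """Immutable set of 0-based half-open genomic intervals.

    Intervals are normalized on construction: per contig they are sorted and
    overlapping/abutting intervals are merged, so membership and coverage
    queries are binary searches on flat arrays.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            if start >= end:
                raise FormatError(
                    f"interval start >= end on {contig}: [{start}, {end})"
                )
            per_contig.setdefault(contig, []).append((int(start), int(end)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for contig, ivs in per_contig.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[contig] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[contig] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in self.contigs:
            for s, e in zip(self._starts[contig], self._ends[contig]):
                out.append((contig, int(s), int(e)))
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals() == other.intervals()

    def contains(self, contig: str, positions: np.ndarray | int) -> np.ndarray | bool:
        """Vectorized point membership test."""
        scalar = np.isscalar(positions)
        pos = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if contig not in self._starts:
            res = np.zeros(pos.shape, dtype=bool)
        else:
            idx = np.searchsorted(self._starts[contig], pos, side="right") - 1
            res = (idx >= 0) & (pos < self._ends[contig][np.maximum(idx, 0)])
        return bool(res[0]) if scalar else res

    def coverage_in(self, contig: str, start: int, end: int) -> int:
        """Number of bases of [start, end) covered by the set."""
        if contig not in self._starts or start >= end:
            return 0
        s = self._starts[contig]
        e = self._ends[contig]
        lo = np.clip(s, start, end)
        hi = np.clip(e, start, end)
        return int(np.sum(hi - lo))

    def mask(self, contig: str, length: int) -> np.ndarray:
        """Boolean per-base mask of the first ``length`` bases of a contig."""
        m = np.zeros(length, dtype=bool)
        if contig in self._starts:
            for s, e in zip(self._starts[contig], self._ends[contig]):
                m[max(0, s) : min(length, e)] = True
        return m


# ---------------------------------------------------------------------------
# SAM alignments


def _record_from_pysam(seg: pysam.AlignedSegment, with_sequence: bool) -> AlignmentRecord:
    barcode = seg.get_tag("CB") if seg.has_tag("CB") else None
    umi = seg.get_tag("UB") if seg.has_tag("UB") else None
    mapped = not seg.is_unmapped
    seq = None
    quals = None
    if with_sequence and seg.query_sequence is not None:
        seq = seg.query_sequence
        if seg.query_qualities is not None:
            quals = tuple(seg.query_qualities)
    return AlignmentRecord(
        read_name=seg.query_name,
        contig=seg.reference_name if mapped else "*",
        pos=seg.reference_start if mapped else 0,
        strand="-" if seg.is_reverse else "+",
        aligned_length=(seg.reference_length or 0) if mapped else 0,
        mapped=mapped,
        barcode=barcode,
        umi=umi,
        sequence=seq,
        qualities=quals,
    )


def read_alignments(
    path: str | Path,
    require_mapped: bool = True,
    with_sequence: bool = False,
) -> Iterator[AlignmentRecord]:
    """Stream :class:`AlignmentRecord` from a SAM-format text file.

    Secondary and supplementary records are always dropped; unmapped records
    are dropped when ``require_mapped``.  Barcode and UMI are parsed from the
    ``CB``/``UB`` tags when present.  Malformed records and records placed on
    contigs absent from the header raise :class:`FormatError` naming the
    offending record.
    """
    path = str(path)
    n_header = 0
    contigs: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@"):
                n_header += 1
                if line.startswith("@SQ"):
                    for field_ in line.rstrip("\n").split("\t")[1:]:
                        if field_.startswith("SN:"):
                            contigs.add(field_[3:])
                continue
            fields = line.split("\t", 4)
            if len(fields) < 4:
                raise FormatError(f"{path}: malformed SAM record at line {lineno}")
            rname = fields[2]
            if rname != "*" and rname not in contigs:
                raise FormatError(
                    f"{path}: record at line {lineno} maps to contig {rname!r} "
                    "absent from the header"
                )
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        record_no = 0
        it = iter(sam)
        while True:
            record_no += 1
            try:
                seg = next(it)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise FormatError(
                    f"{path}: malformed SAM record at line {n_header + record_no}: {exc}"
                ) from exc
            if seg.is_secondary or seg.is_supplementary:
                continue
            if (seg.flag & 0x4) == 0 and seg.reference_id < 0:
                raise FormatError(
                    f"{path}: record at line {n_header + record_no} maps to a "
                    "contig absent from the header"
                )
            rec = _record_from_pysam(seg, with_sequence)
            if require_mapped and not rec.mapped:
                continue
            yield rec


def write_alignments(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> int:
    """Write records as SAM text; returns the number of records written."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": int(l)} for c, l in contig_lengths.items()],
        }
    )
    n = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_name
            seg.flag = (16 if rec.strand == "-" else 0) | (0 if rec.mapped else 4)
            if rec.mapped:
                seg.reference_id = header.get_tid(rec.contig)
                seg.reference_start = rec.pos
                seg.mapping_quality = 60
                seg.cigarstring = f"{rec.aligned_length}M"
            if rec.sequence is not None:
                seg.query_sequence = rec.sequence
                if rec.qualities is not None:
                    seg.query_qualities = list(rec.qualities)
            tags = []
            if rec.barcode is not None:
                tags.append(("CB", rec.barcode))
            if rec.umi is not None:
                tags.append(("UB", rec.umi))
            if tags:
                seg.set_tags(tags)
            out.write(seg)
            n += 1
    return n


# ---------------------------------------------------------------------------
# Fragments files


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> int:
    """Write a fragments file: TSV of contig/start/end/barcode/count, no header.

    Sortedness by (contig, start, end, barcode) is the caller's contract;
    unsorted input is a hard error, not silently fixed.
    """
    n = 0
    prev: tuple[str, int, int, str] | None = None
    with open(path, "w") as fh:
        for frag in fragments:
            key = frag.sort_key
            if prev is not None and key < prev:
                raise FormatError(
                    f"fragments not sorted: {key} follows {prev}"
                )
            prev = key
            fh.write(
                f"{frag.contig}\t{frag.start}\t{frag.end}\t{frag.barcode}\t{frag.count}\n"
            )
            n += 1
    return n


def read_fragments(path: str | Path) -> list[Fragment]:
    """Read a 5-column fragments file written by :func:`write_fragments`."""
    out: list[Fragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            contig, start, end, barcode, count = parts
            try:
                out.append(
                    Fragment(contig, int(start), int(end), barcode, int(count))
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def fragments_to_frame(fragments: Iterable[Fragment]) -> pd.DataFrame:
    """Columnar view of a fragment stream (fast path for numeric modules)."""
    return pd.DataFrame(
        [(f.contig, f.start, f.end, f.barcode, f.count) for f in fragments],
        columns=list(FRAGMENT_COLUMNS),
    )


# ---------------------------------------------------------------------------
# Spot layout (tissue-position list)

_PIXEL_ALIASES = {
    "pixel_x": ("pixel_x", "pixel x", "pxl_col_in_fullres", "pxl_x"),
    "pixel_y": ("pixel_y", "pixel y", "pxl_row_in_fullres", "pxl_y"),
}


def read_spot_layout(path: str | Path) -> list[SpotBarcode]:
    """Read a tissue-position CSV: barcode, in_tissue, array_row, array_col,
    pixel x, pixel y.  Duplicate barcodes or duplicate array coordinates are
    hard errors (one spot, one barcode, one grid cell)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    for canon, aliases in _PIXEL_ALIASES.items():
        for alias in aliases:
            if alias in df.columns:
                df = df.rename(columns={alias: canon})
                break
    required = {"barcode", "in_tissue", "array_row", "array_col", "pixel_x", "pixel_y"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing layout columns: {sorted(missing)}")
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise FormatError(f"{path}: duplicate barcode {dup!r}")
    if df.duplicated(subset=["array_row", "array_col"]).any():
        raise FormatError(f"{path}: duplicate (array_row, array_col) pair")
    return [
        SpotBarcode(
            barcode=str(r.barcode),
            in_tissue=bool(int(r.in_tissue)),
            array_row=int(r.array_row),
            array_col=int(r.array_col),
            pixel_x=float(r.pixel_x),
            pixel_y=float(r.pixel_y),
        )
        for r in df.itertuples(index=False)
    ]


def write_spot_layout(spots: Sequence[SpotBarcode], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.barcode, int(s.in_tissue), s.array_row, s.array_col, s.pixel_x, s.pixel_y)
            for s in spots
        ],
        columns=["barcode", "in_tissue", "array_row", "array_col", "pixel_x", "pixel_y"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# BED / blacklist


def read_blacklist(path: str | Path) -> IntervalSet:
    """Read BED (3+ columns, 0-based half-open) into a normalized IntervalSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            intervals.append((contig, start, end))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals.intervals():
            fh.write(f"{contig}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Gene / TSS annotation (BED-like TSV)


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV of gene annotations: contig, start, end, name,
    strand (tab-separated, no header)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "strand"],
        dtype={"contig": str, "start": int, "end": int, "name": str, "strand": str},
    )
    bad = df[df.start >= df.end]
    if len(bad):
        raise FormatError(f"{path}: gene with start >= end: {bad.iloc[0]['name']}")
    if not df.strand.isin(["+", "-"]).all():
        raise FormatError(f"{path}: strand column must be '+' or '-'")
    return df
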