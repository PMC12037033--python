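"""Transfer corrected spot barcodes/UMIs between alignment streams and
remove PCR duplicates.

The spatially barcoded library is aligned twice: once through the vendor
pipeline, which corrects barcodes and leaves them as ``CB``/``UB`` tags, and
once through a conventional genome aligner, which knows nothing about
barcodes.  This module joins the two streams on read name and then collapses
PCR duplicates per (barcode, contig, strand, 5' position) group, merging
sequencing-error UMIs with the directional network rule.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import AlignmentRecord, BarcodeAssignment


@dataclass
class TransferSummary:
    """Bookkeeping for tag transfer: how many reads made it, how many didn't."""

    n_input: int = 0
    n_output: int = 0
    n_dropped_untagged: int = 0
    n_dropped_missing: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_dropped_untagged": self.n_dropped_untagged,
            "n_dropped_missing": self.n_dropped_missing,
        }


def build_read_barcode_table(
    barcode_alignments: Iterable[AlignmentRecord],
) -> tuple[list[BarcodeAssignment], TransferSummary]:
    """Build the read-name -> (barcode, UMI) table from the barcode-resolved
    alignment stream.

    One row per read name carrying both annotations; reads lacking either tag
    are dropped and counted.  A read name seen with two conflicting
    (barcode, UMI) pairs is a hard error — it means the two streams are not
    from the same library.
    """
    summary = TransferSummary()
    table: dict[str, tuple[str, str]] = {}
    for rec in barcode_alignments:
        summary.n_input += 1
        if rec.barcode is None or rec.umi is None:
            summary.n_dropped_untagged += 1
            continue
        pair = (rec.barcode, rec.umi)
        existing = table.get(rec.read_name)
        if existing is not None:
            if existing != pair:
                raise ValueError(
                    f"read {rec.read_name!r} carries conflicting annotations: "
                    f"{existing} vs {pair}"
                )
            continue
        table[rec.read_name] = pair
    rows = [BarcodeAssignment(name, bc, umi) for name, (bc, umi) in table.items()]
    summary.n_output = len(rows)
    return rows, summary


def attach_barcodes(
    genome_alignments: Iterable[AlignmentRecord],
    table: Sequence[BarcodeAssignment] | dict[str, tuple[str, str]],
) -> tuple[list[AlignmentRecord], TransferSummary]:
    """Copy barcode/UMI annotations onto genome alignments by read name.

    Reads absent from the table are dropped and counted in the summary.
    """
    if not isinstance(table, dict):
        table = {row.read_name: (row.barcode, row.umi) for row in table}
    summary = TransferSummary()
    out: list[AlignmentRecord] = []
    for rec in genome_alignments:
        summary.n_input += 1
        pair = table.get(rec.read_name)
        if pair is None:
            summary.n_dropped_missing += 1
            continue
        out.append(
            AlignmentRecord(
                read_name=rec.read_name,
                contig=rec.contig,
                pos=rec.pos,
                strand=rec.strand,
                aligned_length=rec.aligned_length,
                mapped=rec.mapped,
                barcode=pair[0],
                umi=pair[1],
                multiplicity=rec.multiplicity,
                sequence=rec.sequence,
                qualities=rec.qualities,
            )
        )
    summary.n_output = len(out)
    return out, summary


# ---------------------------------------------------------------------------
# UMI-aware duplicate removal


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def directional_clusters(counts: dict[str, int]) -> list[tuple[str, list[str]]]:
    """Cluster UMIs with the directional network rule.

    Starting from the highest-count UMI, an edge high -> low exists when the
    two UMIs are within Hamming distance 1 and
    ``count_high >= 2 * count_low - 1``; each connected component reachable
    through such edges collapses into its root.  Ties in count break toward
    the lexicographically smaller UMI, which therefore absorbs.

    Returns ``[(root_umi, [members...]), ...]`` sorted by root UMI.
    """
    order = sorted(counts, key=lambda u: (-counts[u], u))
    assigned: set[str] = set()
    clusters: list[tuple[str, list[str]]] = []
    for root in order:
        if root in assigned:
            continue
        members = [root]
        assigned.add(root)
        queue = [root]
        while queue:
            node = queue.pop()
            for cand in order:
                if cand in assigned:
                    continue
                if _hamming1(node, cand) and counts[node] >= 2 * counts[cand] - 1:
                    assigned.add(cand)
                    members.append(cand)
                    queue.append(cand)
        clusters.append((root, sorted(members)))
    clusters.sort(key=lambda c: c[0])
    return clusters


def exact_clusters(counts: dict[str, int]) -> list[tuple[str, list[str]]]:
    """Each distinct UMI is its own cluster (debugging mode)."""
    return [(u, [u]) for u in sorted(counts)]


@dataclass
class DedupGroup:
    """All reads sharing one (barcode, contig, strand, 5' position) key."""

    key: tuple[str, str, str, int]
    records: list[AlignmentRecord] = field(default_factory=list)

    def umi_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for rec in self.records:
            counts[rec.umi] += rec.multiplicity
        return dict(counts)


def deduplicate(
    annotated: Iterable[AlignmentRecord],
    umi_merge: str = "directional",
) -> list[AlignmentRecord]:
    """Collapse duplicate reads sharing barcode + UMI + mapping position.

    Reads are grouped by (barcode, contig, strand, 5' position); within each
    group UMIs are clustered (``directional`` merges sequencing-error UMIs at
    Hamming distance 1, ``exact`` keeps every distinct UMI) and each cluster
    collapses to one representative record — the member with the smallest
    (pos, read_name) — carrying the cluster's total multiplicity.  Output is
    sorted by group key then root UMI, so it is deterministic.

    Read mass is conserved: output multiplicities sum to the number of input
    reads (counting input multiplicities).
    """
    if umi_merge not in ("directional", "exact"):
        raise ValueError(f"unknown umi_merge mode {umi_merge!r}")
    groups: dict[tuple[str, str, str, int], DedupGroup] = {}
    for rec in annotated:
        if rec.barcode is None or rec.umi is None:
            raise ValueError(
                f"read {rec.read_name!r} lacks barcode/UMI annotation; "
                "run attach_barcodes first"
            )
        key = (rec.barcode, rec.contig, rec.strand, rec.five_prime)
        group = groups.get(key)
        if group is None:
            group = groups[key] = DedupGroup(key)
        group.records.append(rec)

    cluster_fn = directional_clusters if umi_merge == "directional" else exact_clusters
    out: list[AlignmentRecord] = []
    for key in sorted(groups):
        group = groups[key]
        counts = group.umi_counts()
        by_umi: dict[str, list[AlignmentRecord]] = defaultdict(list)
        for rec in group.records:
            by_umi[rec.umi].append(rec)
        for root, members in cluster_fn(counts):
            total = sum(counts[u] for u in members)
            candidates = [rec for u in members for rec in by_umi[u]]
            rep = min(candidates, key=lambda r: (r.pos, r.read_name))
            out.append(
                AlignmentRecord(
                    read_name=rep.read_name,
                    contig=rep.contig,
                    pos=rep.pos,
                    strand=rep.strand,
                    aligned_length=rep.aligned_length,
                    mapped=rep.mapped,
                    barcode=rep.barcode,
                    umi=root,
                    multiplicity=total,
                    sequence=rep.sequence,
                    qualities=rep.qualities,
                )
            )
    return out
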