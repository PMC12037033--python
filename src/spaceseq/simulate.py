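"""Fully synthetic fixtures with machine-readable ground truth.

The generator emulates the upstream of this toolkit: a genome with a
controllable GC landscape, a spot layout, barcode-resolved and
genome-aligned SAM streams for the same reads (with PCR duplicates sharing
barcode+UMI, optional one-base UMI errors, and an amplified region sampled
at elevated rate in affected spots), and a small mitochondrial contig with
substitution variants of known heteroplasmy and controllable strand
balance.  Every stochastic choice is recorded in truth tables so downstream
recovery tests close the loop without external data.

Reads are emitted pre-aligned (alignment itself is upstream of this
toolkit), both as in-memory records and, when an output directory is given,
as SAM text plus FASTA/CSV/TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    AlignmentRecord,
    BARCODE_LENGTH,
    Fragment,
    SpotBarcode,
    UMI_LENGTH,
    write_alignments,
    write_spot_layout,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ContigSpec:
    """One simulated contig: length plus a linear GC gradient from
    ``gc_start`` at the left end to ``gc_end`` at the right (equal values
    give flat GC)."""

    name: str
    length: int
    gc_start: float = 0.45
    gc_end: float = 0.45


@dataclass(frozen=True)
class AmpliconSpec:
    """A contiguous amplified region present at ``true_cn`` copies (diploid
    baseline 2) in a fraction of spots."""

    contig: str
    start: int
    end: int
    true_cn: float = 40.0
    affected_spot_fraction: float = 1.0


@dataclass(frozen=True)
class MitoVariantSpec:
    """A substitution at a 1-based position with the given heteroplasmy.

    ``strand_bias`` is the probability that an alt-carrying read lies on the
    forward strand: 0.5 is balanced (a genuine variant), 1.0 puts every alt
    read on the forward strand (a pure strand artifact).  Alt probabilities
    per strand are 2*bias*h and 2*(1-bias)*h (clipped to 1), which keeps the
    pooled allele frequency at h for moderate h.
    """

    position: int
    alt: str
    heteroplasmy: float
    strand_bias: float = 0.5


@dataclass(frozen=True)
class MitoSpec:
    variants: tuple[MitoVariantSpec, ...] = ()
    coverage_per_spot: float = 100.0
    contig: str = "chrM"
    length: int = 1200
    read_length: int = 60
    #: lognormal sigma of the per-spot mtDNA depth factor; per-spot mtDNA
    #: content varies in real tissue, and this variation is what makes
    #: forward/reverse alt counts of genuine variants co-vary across spots.
    depth_sigma: float = 0.35
    #: Beta concentration of per-spot heteroplasmy around the variant mean
    #: (h_spot ~ Beta(h*k, (1-h)*k)).  Heteroplasmy is never uniform across
    #: a tissue; per-spot values are recorded in the truth tables.
    heteroplasmy_concentration: float = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_spots: int = 24
    genome: tuple[ContigSpec, ...] = (ContigSpec("chr1", 2_000_000),)
    reads_per_spot: int = 200
    read_length: int = 75
    duplicate_rate: float = 0.0
    umi_error_rate: float = 0.0
    missing_tag_rate: float = 0.0
    amplicon: AmpliconSpec | None = None
    mito: MitoSpec | None = None

    def __post_init__(self) -> None:
        for name, rate in (
            ("duplicate_rate", self.duplicate_rate),
            ("umi_error_rate", self.umi_error_rate),
            ("missing_tag_rate", self.missing_tag_rate),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.amplicon is not None:
            lengths = {c.name: c.length for c in self.genome}
            amp = self.amplicon
            if amp.true_cn < 2:
                raise ValueError(f"amplicon true_cn must be >= 2, got {amp.true_cn}")
            if (
                amp.contig not in lengths
                or amp.start < 0
                or amp.end > lengths[amp.contig]
                or amp.start >= amp.end
            ):
                raise ValueError(
                    f"amplicon {amp.contig}:{amp.start}-{amp.end} outside genome"
                )


@dataclass
class TruthTables:
    """Ground truth for every downstream recovery test."""

    #: per emitted read: name, barcode, true UMI, emitted UMI, molecule id
    reads: pd.DataFrame
    #: per molecule: id, barcode, contig, start, end, strand
    molecules: pd.DataFrame
    #: per spot: barcode, amplicon_affected flag
    spots: pd.DataFrame
    #: per (variant, spot): position (1-based), alt, barcode, heteroplasmy
    mito_heteroplasmy: pd.DataFrame

    def n_molecules(self) -> int:
        return len(self.molecules)

    def molecule_fragments(self) -> list[Fragment]:
        """Truth fragments (identity Tn5 shift) sorted the standard way."""
        frags = [
            Fragment(m.contig, m.start, m.end, m.barcode, 1)
            for m in self.molecules.itertuples(index=False)
        ]
        frags.sort(key=lambda f: f.sort_key)
        return frags

    def tile_counts(self, contig_lengths: dict[str, int], tile_width: int = 5000,
                    count_mode: str = "both") -> dict[tuple[str, int], int]:
        """Expected per-tile insertion totals from the truth molecules."""
        out: dict[tuple[str, int], int] = {}
        for m in self.molecules.itertuples(index=False):
            ends = (m.start, m.end - 1) if count_mode == "both" else (m.start,)
            for pos in ends:
                key = (m.contig, (pos // tile_width) * tile_width)
                out[key] = out.get(key, 0) + 1
        return out


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: dict[str, str]
    layout: list[SpotBarcode]
    #: barcode-resolved stream: carries CB/UB tags, same alignments
    barcode_records: list[AlignmentRecord]
    #: genome-aligner stream: same reads, no tags
    genome_records: list[AlignmentRecord]
    truth: TruthTables
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}


def _random_sequence(rng: np.random.Generator, length: int, gc_start: float,
                     gc_end: float, block: int = 10_000) -> str:
    """Random sequence whose GC drifts linearly along the contig."""
    out = np.empty(length, dtype=np.uint8)
    n_blocks = (length + block - 1) // block
    for i in range(n_blocks):
        lo = i * block
        hi = min(lo + block, length)
        frac = (lo + hi) / 2 / length
        gc = gc_start + (gc_end - gc_start) * frac
        u = rng.random(hi - lo)
        is_gc = u < gc
        pick = rng.integers(0, 2, hi - lo)
        # GC bases: G or C; AT bases: A or T
        out[lo:hi] = np.where(is_gc, np.where(pick == 0, ord("G"), ord("C")),
                              np.where(pick == 0, ord("A"), ord("T")))
    return out.tobytes().decode("ascii")


def mito_reference_sequence(seed: int, length: int = 1200) -> str:
    """The mitochondrial reference a simulation with this seed will use.

    Generated from a sub-seed derived only from ``seed`` and ``length`` so
    callers can inspect it (e.g. to choose variant alleles that differ from
    the reference) before running :func:`simulate`.
    """
    sub = np.random.default_rng([seed, 0x6D69746F])
    return _random_sequence(sub, length, 0.44, 0.44)


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    arr = _BASES[rng.integers(0, 4, size=(n, k))]
    return [row.tobytes().decode("ascii") for row in arr]


def _make_layout(rng: np.random.Generator, n_spots: int) -> list[SpotBarcode]:
    barcodes: set[str] = set()
    while len(barcodes) < n_spots:
        barcodes.update(_random_kmers(rng, n_spots - len(barcodes), BARCODE_LENGTH))
    ordered = sorted(barcodes)
    ncol = int(np.ceil(np.sqrt(n_spots)))
    spots = []
    for i, bc in enumerate(ordered):
        row, col = divmod(i, ncol)
        spots.append(
            SpotBarcode(bc, True, row, col, pixel_x=100.0 * col, pixel_y=100.0 * row)
        )
    return spots


def _mutate_one_base(rng: np.random.Generator, umi: str) -> str:
    pos = int(rng.integers(0, len(umi)))
    current = umi[pos]
    alt = current
    while alt == current:
        alt = "ACGT"[int(rng.integers(0, 4))]
    return umi[:pos] + alt + umi[pos + 1 :]


def simulate(config: SimulationConfig, out_dir: str | Path | None = None) -> SimulationResult:
    """Generate the full fixture; deterministic for a fixed seed.

    Nuclear molecule positions are uniform over the genome except inside the
    amplicon, which is sampled at rate ``true_cn / 2`` relative to the
    diploid background in affected spots.  Duplicate reads re-emit an
    existing molecule under a fresh read name; UMI errors mutate one base of
    the emitted UMI.  Mitochondrial reads are drawn per strand with the
    configured variant heteroplasmy and strand bias.

    When ``out_dir`` is given, writes genome.fa, barcode.sam, genome.sam,
    layout.csv and truth_*.tsv there.
    """
    rng = np.random.default_rng(config.seed)
    genome: dict[str, str] = {}
    for contig in config.genome:
        genome[contig.name] = _random_sequence(
            rng, contig.length, contig.gc_start, contig.gc_end
        )
    mito = config.mito
    if mito is not None:
        if mito.contig in genome:
            raise ValueError(f"mito contig {mito.contig!r} collides with genome")
        genome[mito.contig] = mito_reference_sequence(config.seed, mito.length)
        for var in mito.variants:
            if not 1 <= var.position <= mito.length:
                raise ValueError(f"mito variant position {var.position} out of range")
            if genome[mito.contig][var.position - 1] == var.alt:
                raise ValueError(
                    f"mito variant alt {var.alt!r} equals reference at {var.position}"
                )

    layout = _make_layout(rng, config.n_spots)
    affected = np.zeros(config.n_spots, dtype=bool)
    if config.amplicon is not None:
        n_aff = int(round(config.amplicon.affected_spot_fraction * config.n_spots))
        affected[rng.permutation(config.n_spots)[:n_aff]] = True

    # --- nuclear reads -----------------------------------------------------
    rl = config.read_length
    segments: list[tuple[str, int, int, float]] = []  # contig, start, end, weight/bp
    for contig in config.genome:
        segments.append((contig.name, 0, contig.length, 1.0))
    amp = config.amplicon

    read_rows = []
    mol_rows = []
    barcode_records: list[AlignmentRecord] = []
    genome_records: list[AlignmentRecord] = []
    mol_id = 0
    read_no = 0

    for spot_i, spot in enumerate(layout):
        segs = []
        for contig, s, e, w in segments:
            if amp is not None and affected[spot_i] and contig == amp.contig:
                boost = amp.true_cn / 2.0
                if s < amp.start:
                    segs.append((contig, s, amp.start, 1.0))
                segs.append((contig, max(s, amp.start), min(e, amp.end), boost))
                if e > amp.end:
                    segs.append((contig, amp.end, e, 1.0))
            else:
                segs.append((contig, s, e, w))
        weights = np.array([(e - s) * w for _, s, e, w in segs])
        probs = weights / weights.sum()

        spot_molecules: list[int] = []  # indices into mol_rows
        for _ in range(config.reads_per_spot):
            dup = (
                config.duplicate_rate > 0
                and spot_molecules
                and rng.random() < config.duplicate_rate
            )
            if dup:
                midx = spot_molecules[int(rng.integers(0, len(spot_molecules)))]
                _, _, contig, start, end, strand, true_umi = mol_rows[midx]
            else:
                seg = segs[int(rng.choice(len(segs), p=probs))]
                contig, s, e, _ = seg
                start = int(rng.integers(s, max(s + 1, e - rl)))
                start = min(start, len(genome[contig]) - rl)
                end = start + rl
                strand = "+" if rng.random() < 0.5 else "-"
                true_umi = _random_kmers(rng, 1, UMI_LENGTH)[0]
                midx = len(mol_rows)
                mol_rows.append(
                    (mol_id, spot.barcode, contig, start, end, strand, true_umi)
                )
                spot_molecules.append(midx)
                mol_id += 1
            mol = mol_rows[midx]
            emitted_umi = mol[6]
            if config.umi_error_rate > 0 and rng.random() < config.umi_error_rate:
                emitted_umi = _mutate_one_base(rng, emitted_umi)
            name = f"read{read_no:08d}"
            read_no += 1
            read_rows.append((name, spot.barcode, mol[6], emitted_umi, mol[0]))
            tagged = rng.random() >= config.missing_tag_rate
            seq = genome[mol[2]][mol[3] : mol[4]]
            genome_records.append(
                AlignmentRecord(name, mol[2], mol[3], mol[5], rl, True,
                                sequence=seq)
            )
            barcode_records.append(
                AlignmentRecord(
                    name, mol[2], mol[3], mol[5], rl, True,
                    barcode=spot.barcode if tagged else None,
                    umi=emitted_umi if tagged else None,
                )
            )

    # --- mitochondrial reads ----------------------------------------------
    het_rows = []
    if mito is not None:
        ref = genome[mito.contig]
        mrl = mito.read_length
        var_positions = np.array([v.position - 1 for v in mito.variants], dtype=int)
        kappa = mito.heteroplasmy_concentration
        for spot in layout:
            depth = float(np.exp(rng.normal(0.0, mito.depth_sigma)))
            n_reads = int(rng.poisson(mito.coverage_per_spot * depth * mito.length / mrl))
            spot_het = {}
            for var in mito.variants:
                h = var.heteroplasmy
                if np.isfinite(kappa) and 0.0 < h < 1.0:
                    h = float(rng.beta(h * kappa, (1.0 - h) * kappa))
                spot_het[(var.position, var.alt)] = h
                het_rows.append((var.position, var.alt, spot.barcode, h))
            for _ in range(n_reads):
                start = int(rng.integers(0, mito.length - mrl + 1))
                end = start + mrl
                strand = "+" if rng.random() < 0.5 else "-"
                seq = list(ref[start:end])
                for vi, var in enumerate(mito.variants):
                    vpos = int(var_positions[vi])
                    if not (start <= vpos < end):
                        continue
                    h_spot = spot_het[(var.position, var.alt)]
                    if strand == "+":
                        p_alt = min(1.0, 2.0 * var.strand_bias * h_spot)
                    else:
                        p_alt = min(1.0, 2.0 * (1.0 - var.strand_bias) * h_spot)
                    if rng.random() < p_alt:
                        seq[vpos - start] = var.alt
                seq = "".join(seq)
                true_umi = _random_kmers(rng, 1, UMI_LENGTH)[0]
                name = f"read{read_no:08d}"
                read_no += 1
                mol_rows.append(
                    (mol_id, spot.barcode, mito.contig, start, end, strand, true_umi)
                )
                read_rows.append((name, spot.barcode, true_umi, true_umi, mol_id))
                mol_id += 1
                genome_records.append(
                    AlignmentRecord(name, mito.contig, start, strand, mrl, True,
                                    sequence=seq)
                )
                barcode_records.append(
                    AlignmentRecord(name, mito.contig, start, strand, mrl, True,
                                    barcode=spot.barcode, umi=true_umi)
                )

    truth = TruthTables(
        reads=pd.DataFrame(
            read_rows, columns=["name", "barcode", "true_umi", "emitted_umi", "molecule_id"]
        ),
        molecules=pd.DataFrame(
            [r[:6] for r in mol_rows],
            columns=["molecule_id", "barcode", "contig", "start", "end", "strand"],
        ),
        spots=pd.DataFrame(
            {
                "barcode": [s.barcode for s in layout],
                "amplicon_affected": affected,
            }
        ),
        mito_heteroplasmy=pd.DataFrame(
            het_rows, columns=["position", "alt", "barcode", "heteroplasmy"]
        ),
    )

    result = SimulationResult(
        config=config,
        genome=genome,
        layout=layout,
        barcode_records=barcode_records,
        genome_records=genome_records,
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: SimulationResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome_fasta": out_dir / "genome.fa",
        "barcode_sam": out_dir / "barcode.sam",
        "genome_sam": out_dir / "genome.sam",
        "layout_csv": out_dir / "layout.csv",
        "truth_reads": out_dir / "truth_reads.tsv",
        "truth_molecules": out_dir / "truth_molecules.tsv",
        "truth_spots": out_dir / "truth_spots.tsv",
        "truth_mito": out_dir / "truth_mito_heteroplasmy.tsv",
    }
    with open(paths["genome_fasta"], "w") as fh:
        for name, seq in result.genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    lengths = result.contig_lengths
    write_alignments(result.barcode_records, paths["barcode_sam"], lengths)
    write_alignments(result.genome_records, paths["genome_sam"], lengths)
    write_spot_layout(result.layout, paths["layout_csv"])
    result.truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    result.truth.molecules.to_csv(paths["truth_molecules"], sep="\t", index=False)
    result.truth.spots.to_csv(paths["truth_spots"], sep="\t", index=False)
    result.truth.mito_heteroplasmy.to_csv(paths["truth_mito"], sep="\t", index=False)
    return paths


def simulate_tss_fragments(
    seed: int,
    n_insertions: int = 10_000,
    enrichment: float = 1.0,
    contig: str = "chr1",
    length: int = 500_000,
    tss_spacing: int = 5_000,
    zone_halfwidth: int = 150,
    barcode: str = "TSS_SPOT_0000_BC1",
) -> tuple[list[Fragment], list[tuple[str, int, str]]]:
    """Insertion events around regularly spaced TSS with a known enrichment.

    Emits one fragment per Tn5 insertion with a 1-bp footprint, so both-end
    insertion counting degenerates to the exact insertion positions — the
    controlled condition a TSS-score calibration needs.  Insertion density
    within ``zone_halfwidth`` of a TSS is ``enrichment`` times the
    background density (``enrichment=1`` is uniform).  Returns (sorted
    fragments, TSS list).
    """
    rng = np.random.default_rng([seed, 0x747373])
    tss_positions = list(range(tss_spacing // 2, length, tss_spacing))
    tss = [
        (contig, p, "+" if i % 2 == 0 else "-") for i, p in enumerate(tss_positions)
    ]
    zone_w = 2 * zone_halfwidth + 1
    z_total = zone_w * len(tss_positions)
    bg_total = length - z_total
    p_zone = enrichment * z_total / (enrichment * z_total + bg_total)
    positions = np.empty(n_insertions, dtype=np.int64)
    in_zone = rng.random(n_insertions) < p_zone
    n_zone = int(in_zone.sum())
    which = rng.integers(0, len(tss_positions), n_zone)
    offs = rng.integers(-zone_halfwidth, zone_halfwidth + 1, n_zone)
    positions[in_zone] = np.array(tss_positions)[which] + offs
    # background: rejection-free draw over the complement is overkill at
    # these densities; draw uniformly and redraw the few zone hits
    n_bg = n_insertions - n_zone
    bg = rng.integers(0, length, n_bg)
    dist = np.abs((bg[:, None] - np.array(tss_positions)[None, :])).min(axis=1)
    while (dist <= zone_halfwidth).any():
        redo = dist <= zone_halfwidth
        bg[redo] = rng.integers(0, length, int(redo.sum()))
        dist = np.abs((bg[:, None] - np.array(tss_positions)[None, :])).min(axis=1)
    positions[~in_zone] = bg
    frags = [Fragment(contig, int(p), int(p) + 1, barcode, 1) for p in positions]
    frags.sort(key=lambda f: f.sort_key)
    return frags, tss


# ---------------------------------------------------------------------------
# Paired gene score / expression matrices for the concordance test


def simulate_concordance_matrices(
    seed: int = 0,
    n_genes: int = 200,
    n_true: int = 50,
    n_clusters: int = 3,
    spots_per_cluster: int = 30,
    base_mean: float = 20.0,
    lfc: float = 2.0,
):
    """Paired accessibility/expression count matrices with cluster structure.

    The first ``n_true`` genes are differentially accessible AND expressed
    (log2 fold change ``lfc`` in one cluster, concordant across modalities);
    the rest are null.  Returns (score GeneMatrix, expression GeneMatrix,
    cluster labels, true gene names).
    """
    import scipy.sparse as sp

    from .matrices import GeneMatrix

    if n_true > n_genes:
        raise ValueError(f"n_true ({n_true}) exceeds n_genes ({n_genes})")
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame(
        {
            "name": [f"gene{i:03d}" for i in range(n_genes)],
            "contig": "chr1",
            "start": np.arange(n_genes) * 10_000,
            "end": np.arange(n_genes) * 10_000 + 5_000,
            "strand": "+",
        }
    )
    n_spots = n_clusters * spots_per_cluster
    barcodes = [f"BC{i:04d}" for i in range(n_spots)]
    labels = {
        bc: f"cluster{i // spots_per_cluster}" for i, bc in enumerate(barcodes)
    }
    up_cluster = rng.integers(0, n_clusters, size=n_genes)
    mats = []
    for _ in range(2):  # the two modalities, independently sampled
        mean = np.full((n_spots, n_genes), base_mean)
        for g in range(n_true):
            rows = slice(
                up_cluster[g] * spots_per_cluster,
                (up_cluster[g] + 1) * spots_per_cluster,
            )
            mean[rows, g] = base_mean * 2.0 ** lfc
        counts = rng.poisson(mean)
        mats.append(
            GeneMatrix(genes.copy(), list(barcodes), sp.csr_matrix(counts.astype(float)))
        )
    true_genes = list(genes["name"][:n_true])
    return mats[0], mats[1], labels, true_genes
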