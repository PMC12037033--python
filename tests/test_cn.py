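"""Copy-number estimation: window tiling, GC matching, diploid baseline,
amplicon recovery, per-gene and per-spot estimates."""

import warnings

import numpy as np
import pytest

import spaceseq as ss
from spaceseq.cn import GenomeWindow, gene_cn, make_windows, spot_cn, window_cn
from spaceseq.io import Fragment, IntervalSet


def uniform_fragments(length, spacing=1000, contig="chr1", barcode="BC", offset=500):
    """One 100-bp fragment per `spacing` bases: exactly equal insertion
    density in every full window whose start is a multiple of spacing."""
    return [
        Fragment(contig, p, p + 100, barcode, 1)
        for p in range(offset, length - 200, spacing)
    ]


@pytest.fixture(scope="module")
def amplified_run():
    """10-contig, 100-Mb genome with a 3-Mb amplicon at true CN 40."""
    contigs = tuple(
        ss.ContigSpec(f"chr{i + 1}", 10_000_000, 0.35 + 0.02 * i, 0.42 + 0.02 * i)
        for i in range(10)
    )
    amp = ss.AmpliconSpec("chr3", 4_000_000, 7_000_000, true_cn=40.0)
    cfg = ss.SimulationConfig(
        seed=61, n_spots=20, genome=contigs, reads_per_spot=800, amplicon=amp
    )
    res = ss.simulate(cfg)
    deduped = ss.deduplicate(res.barcode_records)
    frags, _, _ = ss.build_fragments_file(deduped, res.layout, tn5_shift=(0, 0))
    windows = make_windows(res.genome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n_match lowered to available windows
        windows = window_cn(windows, frags)
    return res, frags, windows


class TestMakeWindows:
    def test_full_window_tiling(self):
        genome = {"chr1": "ACGT" * 2_500_000}  # 10 Mb
        wins = make_windows(genome)
        assert len(wins) == 8
        assert [w.start for w in wins] == [i * 1_000_000 for i in range(8)]
        assert all(w.width == 3_000_000 for w in wins)

    def test_width_must_be_multiple_of_step(self):
        with pytest.raises(ValueError, match="multiple"):
            make_windows({"chr1": "ACGT" * 1000}, width=2500, step=1000)

    def test_all_gc_sequence(self):
        wins = make_windows({"chr1": "GC" * 3000}, width=4000, step=2000)
        assert wins[0].gc_fraction == 1.0

    def test_fully_blacklisted_window_dropped(self):
        genome = {"chr1": "ACGT" * 3000}
        bl = IntervalSet([("chr1", 0, 8000)])
        wins = make_windows(genome, width=4000, step=2000, blacklist=bl)
        assert all(w.start >= 6000 for w in wins)

    def test_blacklist_excluded_from_gc_and_length(self):
        # first half all-GC and blacklisted; second half all-AT
        genome = {"chr1": "G" * 5000 + "A" * 5000}
        bl = IntervalSet([("chr1", 0, 5000)])
        (win,) = make_windows(genome, width=10_000, step=10_000, blacklist=bl)
        assert win.effective_length == 5000
        assert win.gc_fraction == 0.0

    def test_short_contig_yields_single_truncated_window(self):
        wins = make_windows({"chr1": "ACGT" * 250}, width=4000, step=2000)
        assert len(wins) == 1 and wins[0].width == 1000


class TestWindowCN:
    def test_uniform_density_gives_cn_exactly_two(self):
        genome = {"chr1": "ACGT" * 3_000_000}  # 12 Mb
        frags = uniform_fragments(12_000_000)
        windows = make_windows(genome)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows = window_cn(windows, frags)
        for w in windows:
            assert w.log2fc == 0.0
            assert w.cn == 2.0

    def test_doubled_density_gives_cn_four(self):
        # hand-built windows with controlled densities: focal has twice the
        # density of every background window
        windows = [
            GenomeWindow("chr1", i * 1000, i * 1000 + 1000, 0.5, 1000)
            for i in range(0, 20, 2)  # non-overlapping
        ]
        frags = []
        for i, w in enumerate(windows):
            n = 400 if i == 0 else 200
            frags += [
                Fragment("chr1", w.start + j * (1000 // n), w.start + j * (1000 // n) + 1,
                         "BC", 1)
                for j in range(n)
            ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = window_cn(windows, frags, count_mode="start")
        # eps = 1/1000 barely perturbs log2(2): allow the pseudocount's bite
        assert out[0].cn == pytest.approx(4.0, rel=0.01)

    def test_amplicon_cn_recovered(self, amplified_run):
        res, _, windows = amplified_run
        amp = res.config.amplicon
        inside = [
            w.cn for w in windows
            if w.contig == amp.contig and w.start >= amp.start and w.end <= amp.end
        ]
        assert inside, "no window fully inside the amplicon"
        assert np.mean(inside) == pytest.approx(40.0, rel=0.2)

    def test_diploid_background_centered_at_two(self, amplified_run):
        res, _, windows = amplified_run
        amp = res.config.amplicon
        outside = [
            w.cn for w in windows
            if not w.overlaps(amp.contig, amp.start, amp.end)
        ]
        assert 1.8 <= np.median(outside) <= 2.2

    def test_depth_invariance(self):
        genome = {"chr1": "ACGT" * 1_500_000}  # 6 Mb
        rng = np.random.default_rng(63)
        pos = np.sort(rng.integers(0, 5_999_800, 3000))
        frags = [Fragment("chr1", int(p), int(p) + 100, "BC", 1) for p in pos]
        tripled = [Fragment(f.contig, f.start, f.end, f.barcode, 3) for f in frags]
        windows = make_windows(genome)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = window_cn(windows, frags)
            b = window_cn(windows, tripled)
        assert [w.cn for w in a] == pytest.approx([w.cn for w in b])


class TestGeneCN:
    def _win(self, start, cn):
        w = GenomeWindow("chr1", start, start + 3_000_000, 0.4, 3_000_000)
        w.cn = cn
        return w

    def test_gene_inside_single_window(self):
        assert gene_cn(("chr1", 100, 200), [self._win(0, 6.0)]) == 6.0

    def test_gene_spanning_two_windows_averages(self):
        wins = [self._win(0, 4.0), self._win(3_000_000, 8.0)]
        assert gene_cn(("chr1", 2_999_000, 3_001_000), wins) == 6.0

    def test_no_overlap_is_hard_error(self):
        with pytest.raises(ValueError, match="no CN window"):
            gene_cn(("chr2", 0, 100), [self._win(0, 2.0)])

    def test_amplified_gene_recovered(self):
        """Gene CN recovers the truth when the amplicon is wide relative to
        the window width, so every gene-overlapping window is fully
        amplified.  (Genes near amplicon edges are diluted by partially
        overlapping windows — inherent to the overlap-mean definition.)"""
        genome = {f"chr{i + 1}": "ACGT" * 2_500_000 for i in range(5)}  # 5 x 10 Mb
        amp_start, amp_end = 1_500_000, 8_500_000  # 7-Mb amplicon on chr1
        frags = []
        for contig in genome:
            frags += uniform_fragments(10_000_000, spacing=1000, contig=contig)
        # 20x density inside the amplicon: true CN 40 over a diploid baseline
        frags += [
            Fragment("chr1", p, p + 100, "BC", 1)
            for p in range(amp_start + 500, amp_end - 200, 1000)
            for _ in range(19)
        ]
        windows = make_windows(genome)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            windows = window_cn(windows, frags)
        gene = ("chr1", 4_950_000, 5_050_000)
        assert gene_cn(gene, windows) == pytest.approx(40.0, rel=0.2)


class TestSpotCN:
    def test_two_populations_separate(self):
        contigs = (ss.ContigSpec("chr1", 10_000_000), ss.ContigSpec("chr2", 10_000_000))
        amp = ss.AmpliconSpec("chr1", 3_000_000, 6_000_000, true_cn=40.0,
                              affected_spot_fraction=0.5)
        cfg = ss.SimulationConfig(seed=65, n_spots=30, genome=contigs,
                                  reads_per_spot=500, amplicon=amp)
        res = ss.simulate(cfg)
        deduped = ss.deduplicate(res.barcode_records)
        frags, _, _ = ss.build_fragments_file(deduped, res.layout, tn5_shift=(0, 0))
        windows = make_windows(res.genome)
        cn_map = spot_cn(frags, ("chr1", 3_000_000, 6_000_000), windows, res.layout)
        truth = res.truth.spots.set_index("barcode")["amplicon_affected"]
        amp_cns = np.array([cn_map[b] for b in truth.index[truth]])
        dip_cns = np.array([cn_map[b] for b in truth.index[~truth]])
        # AUROC via rank statistic
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(amp_cns, dip_cns, alternative="greater").statistic
        auroc = u / (len(amp_cns) * len(dip_cns))
        assert auroc >= 0.95
        assert np.median(dip_cns) == pytest.approx(2.0, abs=0.5)

    def test_barcode_without_background_is_undefined(self):
        windows = [GenomeWindow("chr1", 0, 6_000_000, 0.4, 6_000_000)]
        frags = [Fragment("chr1", 1_000_500, 1_000_600, "ONLYAMP", 1)]
        cn_map = spot_cn(frags, ("chr1", 1_000_000, 2_000_000), windows)
        assert np.isnan(cn_map["ONLYAMP"])

    def test_no_amplicon_insertions_gives_zero(self):
        windows = [GenomeWindow("chr1", 0, 6_000_000, 0.4, 6_000_000)]
        frags = [Fragment("chr1", 4_000_000, 4_000_100, "BC", 1)]
        cn_map = spot_cn(frags, ("chr1", 1_000_000, 2_000_000), windows)
        assert cn_map["BC"] == 0.0
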