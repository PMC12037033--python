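"""Mitochondrial allele counting, strand-correlation pass filter, and
per-spot heteroplasmy."""

import numpy as np
import pytest

import spaceseq as ss
from spaceseq.io import AlignmentRecord
from spaceseq.mito import (
    AlleleCounts,
    BASES,
    MitoVariant,
    call_variants,
    count_alleles,
    heteroplasmy_per_spot,
)

REF = "ACGTACGTAC"  # 10 bp toy mito reference


def mread(name, pos, seq, strand="+", bc="B" * 16, quals=None):
    return AlignmentRecord(name, "chrM", pos, strand, len(seq), True,
                           barcode=bc, umi="U" * 12, sequence=seq, qualities=quals)


def pick_variants(seed, pos_het_bias, length=1200):
    ref = ss.mito_reference_sequence(seed, length)
    return [
        ss.MitoVariantSpec(p, next(b for b in "ACGT" if b != ref[p - 1]), h, bias)
        for p, h, bias in pos_het_bias
    ]


@pytest.fixture(scope="module")
def mito_run():
    """40 spots at ~100x coverage: 8 strand-balanced variants at
    heteroplasmy {0.1, 0.5, 0.8} and 8 fully strand-biased artifacts at
    matched allele frequencies."""
    seed = 71
    hs = [0.1, 0.5, 0.8, 0.5, 0.1, 0.8, 0.5, 0.5]
    true = pick_variants(seed, [(p, h, 0.5) for p, h in zip(range(101, 902, 100), hs)])
    arts = pick_variants(seed, [(p, h, 1.0) for p, h in zip(range(151, 952, 100), hs)])
    cfg = ss.SimulationConfig(
        seed=seed,
        n_spots=40,
        genome=(ss.ContigSpec("chr1", 100_000),),
        reads_per_spot=20,
        mito=ss.MitoSpec(variants=tuple(true + arts), coverage_per_spot=100.0),
    )
    res = ss.simulate(cfg)
    table, _ = ss.build_read_barcode_table(res.barcode_records)
    annotated, _ = ss.attach_barcodes(res.genome_records, table)
    counts = count_alleles(
        [r for r in annotated if r.contig == "chrM"], res.genome["chrM"]
    )
    return res, true, arts, counts, call_variants(counts)


class TestCountAlleles:
    def test_matching_read_increments_reference_bases(self):
        counts = count_alleles([mread("r1", 0, REF)], REF)
        for pos, base in enumerate(REF):
            assert counts.counts[0, 0, BASES.index(base), pos] == 1
        assert counts.counts[:, 1].sum() == 0  # nothing on the reverse strand

    def test_single_mismatch_counted_as_alt(self):
        seq = REF[:4] + "A" + REF[5:]  # ref A,C,G,T,A... pos 4 is 'A' already
        seq = REF[:5] + "A" + REF[6:]  # pos 5 ref 'C' -> alt 'A'
        counts = count_alleles([mread("r1", 0, seq)], REF)
        assert counts.counts[0, 0, BASES.index("A"), 5] == 1
        assert counts.counts[0, 0, BASES.index("C"), 5] == 0
        assert counts.counts[0, 0, BASES.index(REF[4]), 4] == 1

    def test_low_quality_bases_excluded(self):
        quals = tuple([30] * 5 + [2] + [30] * 4)
        counts = count_alleles([mread("r1", 0, REF, quals=quals)], REF,
                               min_base_quality=10)
        assert counts.counts[0, 0, :, 5].sum() == 0
        assert counts.counts[0, 0, :, 4].sum() == 1

    def test_read_past_reference_end_is_hard_error(self):
        with pytest.raises(ValueError, match="past reference end"):
            count_alleles([mread("r1", 5, REF)], REF)

    def test_strand_assignment(self):
        counts = count_alleles([mread("r1", 0, REF, strand="-")], REF)
        assert counts.counts[0, 1].sum() == 10 and counts.counts[0, 0].sum() == 0

    def test_pileup_matches_simulation_coverage(self, mito_run):
        res, _, _, counts, _ = mito_run
        mito_mols = res.truth.molecules.query("contig == 'chrM'")
        # grand total: every aligned base of every mito read is counted
        assert counts.counts.sum() == (mito_mols.end - mito_mols.start).sum()
        # per-barcode totals match the simulator's read placement
        per_bc = mito_mols.groupby("barcode").apply(
            lambda d: (d.end - d.start).sum(), include_groups=False
        )
        got = counts.counts.sum(axis=(1, 2, 3))
        for bc, expect in per_bc.items():
            assert got[counts.barcodes.index(bc)] == expect


class TestCallVariants:
    def test_perfect_strand_agreement_passes(self):
        rng = np.random.default_rng(73)
        counts = np.zeros((20, 2, 4, 10), dtype=np.int64)
        ref_i = BASES.index(REF[3])
        alt_i = BASES.index("A")  # ref at 3 is 'T'
        per_bc = rng.integers(1, 30, 20)
        for b in range(20):
            counts[b, 0, alt_i, 3] = per_bc[b]
            counts[b, 1, alt_i, 3] = per_bc[b]  # identical on both strands
            counts[b, 0, ref_i, 3] = 5
            counts[b, 1, ref_i, 3] = 5
        ac = AlleleCounts([f"b{i}" for i in range(20)], REF, counts)
        (v,) = [v for v in call_variants(ac) if v.alt == "A" and v.position == 4]
        assert v.strand_correlation == pytest.approx(1.0)
        assert v.passes

    def test_forward_only_variant_fails_as_undefined(self):
        counts = np.zeros((20, 2, 4, 10), dtype=np.int64)
        ref_i = BASES.index(REF[3])
        alt_i = BASES.index("A")
        rng = np.random.default_rng(74)
        for b in range(20):
            counts[b, 0, alt_i, 3] = rng.integers(1, 20)
            counts[b, 0, ref_i, 3] = 5
            counts[b, 1, ref_i, 3] = 5
        ac = AlleleCounts([f"b{i}" for i in range(20)], REF, counts)
        (v,) = [v for v in call_variants(ac) if v.alt == "A" and v.position == 4]
        assert np.isnan(v.strand_correlation)
        assert not v.passes

    def test_true_variants_pass_artifacts_fail(self, mito_run):
        _, true, arts, _, variants = mito_run
        vmap = {(v.position, v.alt): v for v in variants}
        for spec in true:
            v = vmap[(spec.position, spec.alt)]
            assert v.passes, f"true variant at {spec.position} failed"
            assert v.mean_heteroplasmy == pytest.approx(spec.heteroplasmy, abs=0.05)
        n_fail = sum(
            not vmap[(s.position, s.alt)].passes
            for s in arts
            if (s.position, s.alt) in vmap
        ) + sum((s.position, s.alt) not in vmap for s in arts)
        assert n_fail >= 7

    def test_raising_threshold_never_adds_variants(self, mito_run):
        _, _, _, counts, _ = mito_run
        loose = {(v.position, v.alt) for v in call_variants(counts, 0.25) if v.passes}
        tight = {(v.position, v.alt) for v in call_variants(counts, 0.6) if v.passes}
        assert tight <= loose

    def test_barcode_permutation_invariance(self, mito_run):
        _, _, _, counts, variants = mito_run
        rng = np.random.default_rng(75)
        perm = rng.permutation(len(counts.barcodes))
        shuffled = AlleleCounts(
            [counts.barcodes[i] for i in perm], counts.reference, counts.counts[perm]
        )
        vs = call_variants(shuffled)
        key = lambda v: (v.position, v.alt)
        assert sorted(map(key, vs)) == sorted(map(key, variants))
        for a, b in zip(sorted(vs, key=key), sorted(variants, key=key)):
            assert a.strand_correlation == pytest.approx(
                b.strand_correlation, nan_ok=True
            )
            assert a.passes == b.passes


class TestHeteroplasmy:
    def test_simple_ratio(self):
        counts = np.zeros((1, 2, 4, 10), dtype=np.int64)
        counts[0, 0, BASES.index("A"), 3] = 4
        counts[0, 1, BASES.index("A"), 3] = 2
        counts[0, 0, BASES.index("T"), 3] = 4  # the reference allele
        ac = AlleleCounts(["bc"], REF, counts)
        v = MitoVariant(4, "T", "A", 1.0, 0.6, 1, True)
        assert heteroplasmy_per_spot(v, ac) == {"bc": pytest.approx(0.6)}

    def test_zero_coverage_is_undefined(self):
        ac = AlleleCounts(["bc"], REF, np.zeros((1, 2, 4, 10), dtype=np.int64))
        v = MitoVariant(4, "T", "A", 1.0, 0.6, 1, True)
        assert np.isnan(heteroplasmy_per_spot(v, ac)["bc"])

    def test_alleles_sum_to_one_per_covered_barcode(self, mito_run):
        _, _, _, counts, _ = mito_run
        cov = counts.coverage()
        pos = 200  # 1-based 201: a variant site
        ref = counts.reference[pos]
        total = np.zeros(len(counts.barcodes))
        for alt in BASES:
            if alt == ref:
                continue
            v = MitoVariant(pos + 1, ref, alt, 0.0, 0.0, 0, False)
            h = heteroplasmy_per_spot(v, counts)
            total += np.array([h[b] if np.isfinite(h[b]) else 0.0 for b in counts.barcodes])
        ref_counts = counts.counts[:, :, BASES.index(ref), pos].sum(axis=1)
        covered = cov[:, pos] > 0
        ref_frac = np.where(covered, ref_counts / np.maximum(cov[:, pos], 1), 0.0)
        assert np.allclose((total + ref_frac)[covered], 1.0)

    def test_per_spot_recovery_at_100x(self, mito_run):
        res, true, _, counts, variants = mito_run
        vmap = {(v.position, v.alt): v for v in variants}
        truth = res.truth.mito_heteroplasmy.set_index(["position", "alt", "barcode"])
        for spec in true:
            h = heteroplasmy_per_spot(vmap[(spec.position, spec.alt)], counts)
            errors = [
                abs(est - truth.loc[(spec.position, spec.alt, bc), "heteroplasmy"])
                for bc, est in h.items()
                if np.isfinite(est)
            ]
            mae = np.mean(errors)
            assert mae <= 0.05, f"variant at {spec.position}: MAE {mae:.3f}"
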