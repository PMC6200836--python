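"""Kataegis, chromothripsis, and breakage-fusion-bridge detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somascape import catastrophe as cat
from somascape.io_formats import CNSegment, MutationRecord, SVRecord


def snv(sample, chrom, pos, ref="A", alt="T", ctx="CAG"):
    return MutationRecord(sample, chrom, pos, ref, alt, ctx)


def seg(chrom, start, end, cn, sample="s", minor=None):
    return CNSegment(sample, chrom, start, end, cn, minor)


def sv(chrom1, pos1, chrom2, pos2, sample="s", svtype="DEL"):
    return SVRecord(sample, chrom1, pos1, "+", chrom2, pos2, "-", svtype)


class TestIntermutationDistances:
    def test_successive_differences(self):
        recs = [snv("s", "chr1", p) for p in (100, 600, 10_600)]
        d = cat.intermutation_distances(recs)
        assert d["chr1"].tolist() == [500, 10_000]

    def test_single_variant_no_distance(self):
        d = cat.intermutation_distances([snv("s", "chr1", 50)])
        assert d["chr1"].tolist() == []

    def test_count_conservation_across_chromosomes(self):
        rng = np.random.default_rng(0)
        recs = sorted(
            (snv("s", f"chr{c}", int(p)) for c in (1, 2, 3)
             for p in rng.choice(np.arange(10, 10_000), size=17, replace=False)),
            key=lambda r: (r.chrom, r.pos),
        )
        d = cat.intermutation_distances(recs)
        assert sum(len(v) for v in d.values()) == len(recs) - len(d)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cat.intermutation_distances([snv("s", "chr1", 10), snv("s", "chr1", 5)])


class TestKataegis:
    def test_hyperscore_arithmetic(self):
        # 6 SNVs spaced 500 bp in a 3000-SNV sample on a 3-Gb genome
        cluster = [snv("s", "chr1", 10_000 + 500 * i) for i in range(6)]
        background = [snv("s", "chr2", 1_000_000 + 10_000 * i) for i in range(2994)]
        foci = cat.detect_kataegis(cluster + background, genome_length_bp=3e9)
        assert len(foci) == 1
        f = foci[0]
        assert f.n_snvs == 6
        assert f.end - f.start == 2500
        assert f.hyperscore == pytest.approx((6 / 2500) / (3000 / 3e9))

    def test_below_min_snvs_not_reported(self):
        recs = [snv("s", "chr1", 1000 + 100 * i) for i in range(3)]
        assert cat.detect_kataegis(recs, 3e9) == []

    def test_run_broken_by_large_gap(self):
        # 4 tight SNVs, a >2kb gap, then 4 more: two separate maximal runs
        left = [snv("s", "chr1", 1000 + 100 * i) for i in range(4)]
        right = [snv("s", "chr1", 10_000 + 100 * i) for i in range(4)]
        foci = cat.detect_kataegis(left + right, 3e9)
        assert len(foci) == 2
        assert all(f.n_snvs == 4 for f in foci)

    def test_foci_disjoint_and_thresholds_hold(self):
        rng = np.random.default_rng(1)
        recs = sorted((snv("s", "chr1", int(p))
                       for p in rng.choice(np.arange(100, 5_000_000), 600, replace=False)),
                      key=lambda r: r.pos)
        foci = cat.detect_kataegis(recs, 3e9)
        spans = sorted((f.start, f.end) for f in foci)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for f in foci:
            assert f.n_snvs >= 4 and f.hyperscore > 5
            assert max(np.diff(f.positions)) < 2000

    def test_uniform_null_rarely_fires(self):
        # ~1 SNV/Mb over 10 seeded samples: mean false foci < 0.5/sample
        genome = 100_000_000
        total_foci = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = np.sort(rng.integers(100, genome, size=100))
            recs = [snv(f"s{seed}", "chr1", int(p)) for p in pos]
            total_foci += len(cat.detect_kataegis(recs, genome))
        assert total_foci / 10 < 0.5


class TestBreakpoints:
    def test_intra_chromosomal_contributes_two(self):
        bps = cat.breakpoints_of([sv("chr1", 10, "chr1", 99)])
        assert bps["chr1"].tolist() == [10, 99]

    def test_translocation_splits_across_chromosomes(self):
        bps = cat.breakpoints_of([sv("chr1", 10, "chr2", 99, svtype="TRA")])
        assert bps["chr1"].tolist() == [10] and bps["chr2"].tolist() == [99]

    def test_total_conservation(self):
        rng = np.random.default_rng(2)
        svs = [sv(f"chr{rng.integers(1, 4)}", int(rng.integers(1, 1000)),
                  f"chr{rng.integers(4, 6)}", int(rng.integers(1, 1000)), svtype="TRA")
               for _ in range(10)]
        bps = cat.breakpoints_of(svs)
        assert sum(len(v) for v in bps.values()) == 20


class TestKsUniformity:
    def test_evenly_spaced_large_p(self):
        positions = np.linspace(0.05, 0.95, 10) * 1_000_000
        _, p = cat.ks_uniformity(positions, 1_000_000)
        assert p > 0.9

    def test_tight_cluster_small_p(self):
        positions = np.linspace(1, 10_000, 30)
        stat, p = cat.ks_uniformity(positions, 1_000_000)
        assert stat >= 0.95 and p < 1e-10

    def test_closed_form_three_points(self):
        stat, _ = cat.ks_uniformity(np.array([0.25, 0.5, 0.75]) * 1000, 1000)
        assert stat == pytest.approx(0.25)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            cat.ks_uniformity([1, 2], 1000)


class TestCnSwitches:
    def test_alternating_states(self):
        segs = [seg("chr1", i * 100, (i + 1) * 100, cn)
                for i, cn in enumerate([2, 3, 2, 3, 2])]
        assert cat.count_cn_switches(segs) == 4

    def test_single_segment(self):
        assert cat.count_cn_switches([seg("chr1", 0, 100, 2)]) == 0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 8), min_size=1, max_size=30))
    def test_matches_bruteforce_scan(self, cns):
        segs = [seg("chr1", i * 10, (i + 1) * 10, cn) for i, cn in enumerate(cns)]
        states = [int(np.rint(c)) for c in cns]
        brute = sum(states[i] != states[i + 1] for i in range(len(states) - 1))
        assert cat.count_cn_switches(segs) == brute


def chromothripsis_fixture(rng, window=(40_000_000, 60_000_000), n_bp=60,
                           n_osc=30, chrom="chr1"):
    """Planted chromothriptic chr1 (100 Mb) plus uniform background on chr2 (2.9 Gb)."""
    lengths = {"chr1": 100_000_000, "chr2": 2_900_000_000}
    positions = np.sort(rng.integers(window[0], window[1], size=n_bp))
    svs = [sv(chrom, int(positions[i]), chrom, int(positions[i + 1]) + 1)
           for i in range(0, n_bp - 1, 2)]
    bg = np.sort(rng.integers(1, lengths["chr2"], size=40))
    svs += [sv("chr2", int(bg[i]), "chr2", int(bg[i + 1]) + 1) for i in range(0, 39, 2)]
    edges = np.linspace(window[0], window[1], n_osc + 1).astype(int)
    segs = [seg(chrom, int(edges[i]), int(edges[i + 1]), 2 if i % 2 == 0 else 3)
            for i in range(n_osc)]
    segs += [seg(chrom, 0, window[0], 2), seg(chrom, window[1], lengths["chr1"], 2)]
    segs += [seg("chr2", 0, lengths["chr2"], 2)]
    return svs, segs, lengths


class TestChromothripsis:
    def test_planted_chromosome_called(self):
        svs, segs, lengths = chromothripsis_fixture(np.random.default_rng(0))
        calls = {c.chrom: c for c in cat.detect_chromothripsis(svs, segs, lengths)}
        assert calls["chr1"].verdict
        assert calls["chr1"].fold_enrichment >= 3
        assert calls["chr1"].n_cn_switches >= 10
        assert not calls["chr2"].verdict

    def test_sparse_flat_chromosome_not_called(self):
        rng = np.random.default_rng(1)
        lengths = {"chr1": 100_000_000}
        pos = np.sort(rng.integers(1, lengths["chr1"], size=8))
        svs = [sv("chr1", int(pos[i]), "chr1", int(pos[i + 1]) + 1) for i in range(0, 7, 2)]
        segs = [seg("chr1", 0, lengths["chr1"], 2)]
        (call,) = cat.detect_chromothripsis(svs, segs, lengths)
        assert not call.verdict and "fewer than" in call.reason

    def test_nine_switches_fails_single_criterion(self):
        svs, _, lengths = chromothripsis_fixture(np.random.default_rng(2))
        # explicit 10-segment alternating profile covering chr1: 9 switches
        edges = np.linspace(0, lengths["chr1"], 11).astype(int)
        segs = [seg("chr1", int(edges[i]), int(edges[i + 1]), 2 if i % 2 == 0 else 3)
                for i in range(10)]
        segs += [seg("chr2", 0, lengths["chr2"], 2)]
        calls = {c.chrom: c for c in cat.detect_chromothripsis(svs, segs, lengths)}
        assert calls["chr1"].n_cn_switches == 9
        assert calls["chr1"].fold_enrichment >= 3 and calls["chr1"].ks_p < 0.01
        assert not calls["chr1"].verdict

    def test_verdict_invariant_to_relabeling_and_scaling(self):
        svs, segs, lengths = chromothripsis_fixture(np.random.default_rng(3))
        base = {c.chrom: c.verdict for c in cat.detect_chromothripsis(svs, segs, lengths)}

        relabel = {"chr1": "chrA", "chr2": "chrB"}
        svs2 = [sv(relabel[v.chrom1], v.pos1, relabel[v.chrom2], v.pos2) for v in svs]
        segs2 = [seg(relabel[s.chrom], s.start, s.end, s.total_cn) for s in segs]
        lengths2 = {relabel[c]: l for c, l in lengths.items()}
        out2 = {c.chrom: c.verdict for c in cat.detect_chromothripsis(svs2, segs2, lengths2)}
        assert out2 == {relabel[c]: v for c, v in base.items()}

        f = 10
        svs3 = [sv(v.chrom1, v.pos1 * f, v.chrom2, v.pos2 * f) for v in svs]
        segs3 = [seg(s.chrom, s.start * f, s.end * f, s.total_cn) for s in segs]
        lengths3 = {c: l * f for c, l in lengths.items()}
        out3 = {c.chrom: c.verdict for c in cat.detect_chromothripsis(svs3, segs3, lengths3)}
        assert out3 == base

    def test_missing_chrom_length_raises(self):
        svs = [sv("chr9", 10, "chr9", 20)]
        with pytest.raises(ValueError, match="chr9"):
            cat.detect_chromothripsis(svs, [], {"chr1": 1000})


class TestBFB:
    LENGTHS = {"chr1": 100_000_000}

    def _clustered_svs(self, rng, lo, hi, n=26):
        pos = np.sort(rng.integers(lo, hi, size=n))
        return [sv("chr1", int(pos[i]), "chr1", int(pos[i + 1]) + 1)
                for i in range(0, n - 1, 2)]

    def test_planted_arm_called(self):
        rng = np.random.default_rng(0)
        L = self.LENGTHS["chr1"]
        segs = [seg("chr1", 0, L - 8_000_000, 2, minor=1),
                seg("chr1", L - 8_000_000, L - 2_000_000, 8, minor=1),
                seg("chr1", L - 2_000_000, L, 1, minor=0)]
        svs = self._clustered_svs(rng, L - 8_000_000, L - 2_000_000)
        calls = {(c.chrom, c.arm): c for c in cat.detect_bfb(svs, segs, self.LENGTHS)}
        q = calls[("chr1", "q")]
        assert q.telomeric_loss and q.adjacent_amplification and q.breakpoint_cluster
        assert q.verdict
        assert not calls[("chr1", "p")].verdict

    def test_flat_arm_not_called(self):
        rng = np.random.default_rng(1)
        segs = [seg("chr1", 0, self.LENGTHS["chr1"], 2, minor=1)]
        svs = self._clustered_svs(rng, 10_000_000, 20_000_000)
        calls = cat.detect_bfb(svs, segs, self.LENGTHS)
        assert not any(c.verdict for c in calls)

    def test_distant_amplification_rejected_by_window(self):
        rng = np.random.default_rng(2)
        L = self.LENGTHS["chr1"]
        # amplification 20 Mb away from the lost telomeric segment
        segs = [seg("chr1", 0, L - 30_000_000, 2, minor=1),
                seg("chr1", L - 30_000_000, L - 25_000_000, 8, minor=1),
                seg("chr1", L - 25_000_000, L - 2_000_000, 2, minor=1),
                seg("chr1", L - 2_000_000, L, 1, minor=0)]
        svs = self._clustered_svs(rng, L - 5_000_000, L - 1_000_000)
        calls = {(c.chrom, c.arm): c for c in cat.detect_bfb(svs, segs, self.LENGTHS)}
        q = calls[("chr1", "q")]
        assert q.telomeric_loss and not q.adjacent_amplification and not q.verdict

    def test_uncovered_arm_end_flagged(self):
        segs = [seg("chr1", 30_000_000, 70_000_000, 2, minor=1)]
        calls = {(c.chrom, c.arm): c for c in cat.detect_bfb([], segs, self.LENGTHS)}
        assert calls[("chr1", "q")].reason == "uncovered arm end"
        assert not calls[("chr1", "q")].verdict


class TestRecurrentGenes:
    GENES = [("GENE1", "chr1", 100, 200), ("GENE2", "chr2", 0, 50)]

    def test_breakpoint_at_gene_start_counted(self):
        # 1-based position 101 occupies 0-based index 100 = the interval start
        svs = [sv("chr1", 101, "chr1", 5000, sample="a")]
        incidence, rec = cat.recurrent_rearranged_genes(svs, self.GENES)
        assert incidence.at["GENE1", "a"] == 1 and rec["GENE1"] == 1

    def test_two_svs_same_gene_binary_incidence(self):
        svs = [sv("chr1", 150, "chr1", 5000, sample="a"),
               sv("chr1", 160, "chr1", 6000, sample="a")]
        incidence, rec = cat.recurrent_rearranged_genes(svs, self.GENES)
        assert incidence.at["GENE1", "a"] == 1 and rec["GENE1"] == 1

    def test_recurrence_counts_samples(self):
        svs = [sv("chr1", 150, "chr1", 5000, sample="a"),
               sv("chr1", 170, "chr1", 6000, sample="b"),
               sv("chr2", 10_000, "chr2", 20_000, sample="c")]
        _, rec = cat.recurrent_rearranged_genes(svs, self.GENES)
        assert rec["GENE1"] == 2 and rec["GENE2"] == 0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cat.recurrent_rearranged_genes([], [("G", "chr1", 5, 5)])
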