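"""Synthetic cohort generator: determinism, context fidelity, planted margins."""

import numpy as np
import pytest

from somascape import catastrophe as cat
from somascape import io_formats as io
from somascape import synthetic as syn
from somascape.spectrum import collapse_substitution


def small_config(seed, **group_kw):
    genome = {"chr1": 2_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    defaults = dict(
        n_samples=2,
        burden_log_mean=float(np.log(5.0)),
        burden_log_sd=0.2,
        signatures=["S1", "S17"],
        exposure_alpha=[2.0, 2.0],
        kataegis_mean=1.0,
        chromothripsis_prob=0.0,
        bfb_prob=0.0,
        background_sv_mean=5.0,
    )
    defaults.update(group_kw)
    return syn.SimulationConfig(
        seed=seed, genome=genome, groups={"g": syn.GroupConfig(**defaults)},
        chromothripsis_pool=["chr2"], bfb_pool=["chr3"],
    )


@pytest.fixture(scope="module")
def small_cohort():
    """Two samples on the default mini genome with every event type planted.

    The chromothripsis fold-enrichment criterion is relative to the sample's
    genome-wide breakpoint density, so planted margins are only guaranteed at
    the default genome geometry (planted breakpoints must not dominate the
    genome-wide null)."""
    grp = syn.GroupConfig(
        n_samples=2, burden_log_mean=float(np.log(5.0)), burden_log_sd=0.2,
        signatures=["S1", "S17"], exposure_alpha=[2.0, 2.0], kataegis_mean=2.0,
        chromothripsis_prob=1.0, bfb_prob=1.0, background_sv_mean=5.0)
    return syn.simulate_cohort(
        syn.SimulationConfig(seed=7, genome="mini", groups={"g": grp}))


class TestReference:
    def test_mini_preset_shape(self):
        g = syn.genome_spec("mini")
        assert len(g) == 10 and all(v == 10_000_000 for v in g.values())

    def test_gc_zero_gives_at_only(self):
        seqs = syn.generate_reference({"c": 10_000}, seed=0, gc_fraction=0.0)
        assert set(np.unique(seqs["c"])) <= {0, 3}  # A and T codes

    def test_realized_gc_close_to_target(self):
        seqs = syn.generate_reference({"c": 10_000_000}, seed=1, gc_fraction=0.41)
        gc = np.isin(seqs["c"], [1, 2]).mean()
        assert abs(gc - 0.41) < 0.005

    def test_deterministic_per_seed(self):
        a = syn.generate_reference({"c": 1000}, seed=5)
        b = syn.generate_reference({"c": 1000}, seed=5)
        assert (a["c"] == b["c"]).all()


class TestMutationSimulation:
    def test_every_context_matches_genome(self, small_cohort):
        for recs in small_cohort.snvs.values():
            for r in recs:
                tri = syn.decode_seq(small_cohort.seqs[r.chrom][r.pos - 2 : r.pos + 1])
                assert r.context == tri and r.context[1] == r.ref

    def test_single_signature_spectrum_converges(self, reference_native):
        cfg = small_config(3, signatures=["S17"], exposure_alpha=[1.0],
                           burden_log_mean=float(np.log(2000.0)), burden_log_sd=0.01,
                           n_samples=1, kataegis_mean=0.0)
        cohort = syn.simulate_cohort(cfg)
        from somascape.spectrum import build_spectrum
        from somascape.signatures import cosine_similarity

        spec = build_spectrum(cohort.all_snvs())
        assert spec.sum().sum() > 20_000
        sim = cosine_similarity(spec.iloc[0], reference_native.loc["S17"])
        assert sim >= 0.99

    def test_zero_burden_sample_empty(self):
        cfg = small_config(4, burden_log_mean=-30.0, kataegis_mean=0.0)
        cohort = syn.simulate_cohort(cfg)
        assert all(len(r) == 0 for r in cohort.snvs.values())


class TestKataegisPlanting:
    def test_no_foci_leaves_records_unchanged(self, small_cohort):
        recs = list(small_cohort.snvs[small_cohort.manifest.samples[0]])
        out, truth = syn.plant_kataegis(
            "s", recs, small_cohort.seqs, small_cohort.genome, 0,
            np.random.default_rng(0))
        assert truth == [] and out == sorted(recs, key=lambda r: (r.chrom, r.pos))

    def test_three_foci_constructed_within_margins(self, small_cohort):
        recs = list(small_cohort.snvs[small_cohort.manifest.samples[0]])
        out, truth = syn.plant_kataegis(
            "s", recs, small_cohort.seqs, small_cohort.genome, 3,
            np.random.default_rng(1))
        assert len(truth) == 3
        spans = sorted((t["chrom"], t["start"], t["end"]) for t in truth)
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            assert c1 != c2 or e1 < s2
        for t in truth:
            assert t["n_snvs"] >= 6
            assert max(np.diff(t["positions"])) < 1500

    def test_detector_recovers_planted_foci(self, small_cohort):
        from somascape.pipeline import score_kataegis

        score = score_kataegis(small_cohort)
        assert score.tp + score.fn > 0
        assert score.recall >= 0.95


class TestCnSvPlanting:
    def test_planted_events_detected_null_chroms_clean(self, small_cohort):
        from somascape.pipeline import score_bfb, score_chromothripsis

        ct = score_chromothripsis(small_cohort)
        assert ct.tp > 0 and ct.fn == 0 and ct.fp == 0
        bfb = score_bfb(small_cohort)
        assert bfb.tp > 0 and bfb.fn == 0 and bfb.fp == 0

    def test_background_only_sample_all_negative(self):
        cohort = syn.simulate_cohort(small_config(9, kataegis_mean=0.0))
        for s in cohort.manifest.samples:
            calls = cat.detect_chromothripsis(cohort.svs[s], cohort.segments[s],
                                              cohort.genome)
            assert not any(c.verdict for c in calls)

    def test_segments_partition_genome(self, small_cohort):
        for segs in small_cohort.segments.values():
            io.sort_and_check_segments(segs)
            by_chrom = {}
            for s in segs:
                by_chrom.setdefault(s.chrom, []).append(s)
            for chrom, chrom_segs in by_chrom.items():
                chrom_segs.sort(key=lambda s: s.start)
                assert chrom_segs[0].start == 0
                assert chrom_segs[-1].end == small_cohort.genome[chrom]
                for a, b in zip(chrom_segs, chrom_segs[1:]):
                    assert a.end == b.start


class TestBundle:
    def test_seed_determinism_byte_identical_truth(self):
        a = syn.simulate_cohort(small_config(11))
        b = syn.simulate_cohort(small_config(11))
        assert a.truth_json() == b.truth_json()
        sa, sb = a.manifest.samples[0], b.manifest.samples[0]
        assert a.snvs[sa] == b.snvs[sb]

    def test_bundle_round_trips_through_readers(self, tmp_path):
        import pyfaidx

        cfg = small_config(13, bfb_prob=1.0)
        outdir = tmp_path / "bundle"
        cohort = syn.generate_cohort(cfg, outdir)
        genome = pyfaidx.Fasta(str(outdir / "genome.fa"))
        sample = cohort.manifest.samples[0]
        recs = io.read_snvs(outdir / "snvs" / f"{sample}.vcf", genome, sample_id=sample)
        assert recs == cohort.snvs[sample]
        segs = io.read_segments(outdir / "segments.seg.tsv")
        assert sorted(segs, key=lambda s: (s.sample_id, s.chrom, s.start)) == \
            io.sort_and_check_segments([s for ss in cohort.segments.values() for s in ss])
        svs = io.read_bedpe(outdir / "svs.bedpe")
        assert len(svs) == sum(len(v) for v in cohort.svs.values())
        manifest = io.read_manifest(outdir / "manifest.tsv")
        assert manifest.groups == cohort.manifest.groups

    def test_refuses_to_overwrite_without_force(self, tmp_path):
        outdir = tmp_path / "bundle"
        outdir.mkdir()
        (outdir / "stale.txt").write_text("x")
        with pytest.raises(FileExistsError):
            syn.generate_cohort(small_config(1), outdir)


class TestChannelFidelity:
    def test_spectrum_reflects_planted_mixture_channels(self, small_cohort):
        # collapsing any emitted record must land on a channel with nonzero
        # probability under the group's planted mixture
        profiles = syn.load_reference_signatures(convention="native")
        mix = profiles.loc[["S1", "S17"]].mean(axis=0)
        support = set(mix[mix > 0].index)
        for s in small_cohort.manifest.samples:
            truth = small_cohort.truth[s]
            planted_pos = {(f["chrom"], p) for f in truth.kataegis_foci
                           for p in f["positions"]}
            for r in small_cohort.snvs[s]:
                if (r.chrom, r.pos) in planted_pos:
                    continue  # kataegis SNVs draw alt uniformly
                assert collapse_substitution(r.ref, r.alt, r.context) in support
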