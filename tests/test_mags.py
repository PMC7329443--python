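"""MAG refinement: composition statistics, the merge/filter/dereplicate/
gate rules, and the full-workflow invariants on seeded fixtures."""

import numpy as np
import pandas as pd
import pytest

from ventmag import mags, synth
from ventmag.mags import (AAIMatrix, BinRecord, ContigStats,
                          compute_contig_stats, dereplicate_by_aai,
                          filter_outlier_contigs, irep_eligible,
                          mag_relative_abundance, merge_decision,
                          quality_gate, refine_bins,
                          resolve_duplicate_contigs)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestContigStats:
    def test_at_only_sequence(self):
        s = compute_contig_stats("ATATATAT", depth=1.0)
        assert s.gc == 0.0

    def test_gc_homopolymer_tetra_classes(self):
        s = compute_contig_stats("GCGCGCGC", depth=1.0)
        assert s.gc == 1.0
        # GCGC and CGCG are each their own reverse complement: the five
        # 4-mer windows fall into exactly those two palindromic classes
        assert np.count_nonzero(s.tetra) == 2
        assert sorted(s.tetra[s.tetra > 0]) == pytest.approx([0.4, 0.6])

    def test_reverse_complement_invariance(self, rng):
        seq = synth.random_sequence(3000, gc=0.45, rng=rng)
        s1 = compute_contig_stats(seq, 1.0)
        s2 = compute_contig_stats(_revcomp(seq), 1.0)
        np.testing.assert_allclose(s1.tetra, s2.tetra, atol=1e-12)
        assert s1.gc == pytest.approx(s2.gc)

    def test_n_windows_skipped_and_short_rejected(self):
        s = compute_contig_stats("ACGTNACGT", 1.0)
        assert s.tetra.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            compute_contig_stats("ACG", 1.0)

    def test_canonical_class_count(self):
        assert len(mags.CANONICAL_TETRAMERS) == 136


class TestMergeDecision:
    @pytest.mark.parametrize("qa,qb,qm,ta,tb,expect", [
        ((55, 3), (50, 2), (68, 3.8), "T", "T", True),   # both thresholds met
        ((55, 3), (50, 2), (68, 4.5), "T", "T", False),  # contamination
        ((55, 3), (50, 2), (64, 3.5), "T", "T", False),  # completeness gain
        ((55, 3), (50, 2), (68, 3.8), "T", "U", False),  # taxonomy mismatch
        ((55, 3), (50, 2), (65, 4.0), "T", "T", True),   # boundaries inclusive
    ])
    def test_rule(self, qa, qb, qm, ta, tb, expect):
        assert merge_decision(qa, qb, qm, ta, tb) is expect


def _uniform_bin(n=6, gc=0.5, depth=10.0, seed=0):
    rng = np.random.default_rng(seed)
    stats = {}
    for i in range(n):
        tetra = np.full(136, 1 / 136)
        stats[f"c{i}"] = ContigStats(f"c{i}", 10_000, gc, depth, tetra)
    rec = BinRecord(bin_id="b", contigs=set(stats), taxonomy="T",
                    completeness=90.0, contamination=1.0)
    return rec, stats


class TestOutlierFilter:
    def test_homogeneous_bin_untouched(self):
        rec, stats = _uniform_bin()
        kept, removed, reasons = filter_outlier_contigs(rec, stats)
        assert removed == [] and len(kept) == 6

    def test_depth_outlier_removed_with_reason(self):
        rec, stats = _uniform_bin()
        stats["c0"] = ContigStats("c0", 10_000, 0.5, 100.0,
                                  np.full(136, 1 / 136))
        kept, removed, reasons = filter_outlier_contigs(rec, stats,
                                                        depth_fold=3.0)
        assert removed == ["c0"]
        assert reasons["c0"] == ["depth"]

    def test_small_bins_not_filtered(self):
        rec, stats = _uniform_bin(n=2)
        rec = BinRecord("b", {"c0", "c1"}, "T", 90, 1)
        stats["c0"] = ContigStats("c0", 10_000, 0.9, 500.0,
                                  np.full(136, 1 / 136))
        kept, removed, _ = filter_outlier_contigs(rec, stats)
        assert removed == []

    def test_missing_stats_raise(self):
        rec, stats = _uniform_bin()
        del stats["c3"]
        with pytest.raises(KeyError):
            filter_outlier_contigs(rec, stats)

    def test_injected_contaminants_recovered(self, bin_metadata):
        # >= 90% of injected foreign contigs removed, <= 5% of native
        removed = set()
        for b in bin_metadata.bins:
            _, rem, _ = filter_outlier_contigs(b, bin_metadata.contigs)
            removed |= {(b.bin_id, c) for c in rem}
        truth = bin_metadata.truth
        inj = truth[truth.is_contaminant]
        native = truth[(~truth.is_contaminant) & (truth.bin_id != "")]
        recall = np.mean([(r.bin_id, r.contig_id) in removed
                          for r in inj.itertuples()])
        false = np.mean([(r.bin_id, r.contig_id) in removed
                         for r in native.itertuples()])
        assert recall >= 0.90
        assert false <= 0.05


def _bin(bid, contigs, comp, cont=0.0, tax="T", length=1_000_000, count=0):
    return BinRecord(bid, set(contigs), tax, comp, cont, length,
                     count or len(contigs))


def _aai(ids, pairs):
    df = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in ids:
        for j in ids:
            if i != j:
                df.loc[i, j] = 60.0
    for a, b, v in pairs:
        df.loc[a, b] = df.loc[b, a] = v
    return AAIMatrix(df)


class TestDereplication:
    def test_higher_completeness_survives(self):
        bins = [_bin("b1", ["c1"], 85), _bin("b2", ["c2"], 78)]
        aai = _aai(["b1", "b2"], [("b1", "b2", 99.4)])
        assert [b.bin_id for b in dereplicate_by_aai(bins, aai)] == ["b1"]

    def test_no_pairs_above_cutoff_is_identity(self):
        bins = [_bin("b1", ["c1"], 85), _bin("b2", ["c2"], 78)]
        aai = _aai(["b1", "b2"], [("b1", "b2", 98.9)])
        assert len(dereplicate_by_aai(bins, aai)) == 2

    def test_chain_collapses_to_single_survivor(self):
        bins = [_bin("A", ["c1"], 80), _bin("B", ["c2"], 90),
                _bin("C", ["c3"], 70)]
        aai = _aai(["A", "B", "C"], [("A", "B", 99.2), ("B", "C", 99.1),
                                     ("A", "C", 98.5)])
        kept = dereplicate_by_aai(bins, aai)
        assert [b.bin_id for b in kept] == ["B"]  # component rule, best C


class TestDuplicateResolution:
    def test_no_duplicates_identity(self):
        bins = [_bin("b1", ["c1"], 90), _bin("b2", ["c2"], 70)]
        out = resolve_duplicate_contigs(bins)
        assert {b.bin_id: b.contigs for b in out} == {"b1": {"c1"},
                                                      "b2": {"c2"}}

    def test_contig_stays_with_more_complete_bin(self):
        bins = [_bin("b1", ["c1", "dup"], 90), _bin("b2", ["c2", "dup"], 70)]
        out = {b.bin_id: b.contigs for b in resolve_duplicate_contigs(bins)}
        assert "dup" in out["b1"] and "dup" not in out["b2"]

    def test_idempotent(self):
        bins = [_bin("b1", ["c1", "dup"], 90), _bin("b2", ["c2", "dup"], 70)]
        once = resolve_duplicate_contigs(bins)
        twice = resolve_duplicate_contigs(once)
        assert [(b.bin_id, b.contigs) for b in once] == \
               [(b.bin_id, b.contigs) for b in twice]


class TestQualityGate:
    @pytest.mark.parametrize("comp,cont,kept", [
        (70.0, 9.0, True), (69.9, 0.0, False), (100.0, 9.1, False),
        (95.0, 0.0, True),
    ])
    def test_boundaries(self, comp, cont, kept):
        bins = [_bin("b", ["c"], comp, cont)]
        assert (len(quality_gate(bins)) == 1) is kept


class TestRelativeAbundance:
    def test_single_bin_holding_everything(self):
        stats = {"c1": ContigStats("c1", 10_000, 0.5, 10.0)}
        bins = [_bin("b", ["c1"], 90)]
        assert mag_relative_abundance(bins, stats)["b"] == pytest.approx(1.0)

    def test_hand_computed_fraction(self):
        stats = {"c1": ContigStats("c1", 10_000, 0.5, 10.0),
                 "c2": ContigStats("c2", 10_000, 0.5, 30.0),
                 "c3": ContigStats("c3", 20_000, 0.5, 10.0)}
        bins = [_bin("b", ["c1", "c2"], 90)]
        assert mag_relative_abundance(bins, stats)["b"] == pytest.approx(2 / 3)

    def test_short_contigs_excluded_everywhere(self):
        stats = {"c1": ContigStats("c1", 10_000, 0.5, 10.0),
                 "tiny": ContigStats("tiny", 1_000, 0.5, 1000.0)}
        bins = [_bin("b", ["c1", "tiny"], 90)]
        assert mag_relative_abundance(bins, stats,
                                      min_len=3000)["b"] == pytest.approx(1.0)


class TestIrepEligibility:
    @pytest.mark.parametrize("count,length,expect", [
        (100, 1_000_000, True), (200, 1_000_000, False),
        (350, 2_000_000, True),  # exactly 175/Mb, boundary inclusive
    ])
    def test_scaffold_density(self, count, length, expect):
        b = _bin("b", ["c"], 90, length=length, count=count)
        assert irep_eligible(b) is expect

    def test_non_bacterial_ineligible(self):
        b = BinRecord("b", {"c"}, "T", 90, 0, 1_000_000, 10,
                      domain="Archaea")
        assert not irep_eligible(b)


class TestRefineWorkflow:
    def test_invariants_and_truth_on_fixture(self, bin_metadata):
        res = refine_bins(bin_metadata.bins, bin_metadata.contigs,
                          bin_metadata.aai,
                          merged_quality=bin_metadata.merged_quality,
                          quality_update=bin_metadata.quality_of)
        seen = set()
        for b in res.bins:
            assert not (b.contigs & seen)
            seen |= b.contigs
            assert b.completeness >= 70.0 and b.contamination <= 9.0
        ids = [b.bin_id for b in res.bins]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert bin_metadata.aai[a, b] < 99.0
        # truth contamination of retained bins is (near) zero after filtering
        for b in res.bins:
            c_truth, x_truth = bin_metadata.quality_of(b)
            assert c_truth >= 70.0
            assert x_truth <= 9.0

    def test_idempotence(self, bin_metadata):
        res = refine_bins(bin_metadata.bins, bin_metadata.contigs,
                          bin_metadata.aai,
                          merged_quality=bin_metadata.merged_quality,
                          quality_update=bin_metadata.quality_of)
        ids = [b.bin_id for b in res.bins]
        aai2 = AAIMatrix(bin_metadata.aai.values.loc[ids, ids])
        res2 = refine_bins(res.bins, bin_metadata.contigs, aai2,
                           quality_update=bin_metadata.quality_of)
        assert [(b.bin_id, sorted(b.contigs)) for b in res2.bins] == \
               [(b.bin_id, sorted(b.contigs)) for b in res.bins]

    def test_merge_stage_combines_partial_bins(self, two_communities):
        # two half-genomes of one taxon with little overlap should merge
        comm_a, _ = two_communities
        meta = synth.generate_bin_metadata(comm_a, contamination_fraction=0.0,
                                           bins_per_taxon=2,
                                           completeness_range=(0.5, 0.6),
                                           seed=23)
        res = refine_bins(meta.bins, meta.contigs, meta.aai,
                          merged_quality=meta.merged_quality,
                          quality_update=meta.quality_of)
        assert res.merged  # at least one accepted merge
        for b in res.bins:
            assert b.completeness >= 70.0
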