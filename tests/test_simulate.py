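"""Synthetic library generators: distributions, determinism, error model."""

import numpy as np
import pytest
from scipy import stats

from spacerseq import (NAMED_MUTATIONS, SiteDistribution, add_errors,
                       apply_mutation, build_plasmid_locus, draw_spacer_pool,
                       predict_second_site, simulate_expanded_arrays,
                       simulate_linear_library, simulate_plasmid_library)
from spacerseq.references import WT_REPEAT


class TestPlasmidLibrary:
    def test_pure_lr_reads_start_with_prespacer_then_repeat(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        dist = SiteDistribution(lr=1.0, rs=0.0, off_target=0.0)
        batch = simulate_plasmid_library(name, seq, dist, prespacer, 50,
                                         seed=1, annotation=ann)
        repeat_start0 = ann.array_start - 1
        for _, read, _ in batch.records:
            assert read.startswith(prespacer.top_strand)
            assert read[35:] == seq[repeat_start0: repeat_start0 + 65]
        assert all(t["site"] == ann.lr_site and t["strand"] == "+"
                   for t in batch.truth)

    def test_pure_g_off_target_sites_land_on_guanine(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        dist = SiteDistribution(lr=0, rs=0, off_target=1.0,
                                base_weights=(("G", 1.0), ("A", 0), ("C", 0), ("T", 0)))
        batch = simulate_plasmid_library(name, seq, dist, prespacer, 200,
                                         seed=2, annotation=ann)
        comp = dict(zip("ACGT", "TGCA"))
        for t in batch.truth:
            base = seq[t["site"] - 1]
            assert (base if t["strand"] == "+" else comp[base]) == "G"

    def test_off_target_base_frequencies_match_configured_weights(self, pcrispr,
                                                                  prespacer):
        name, seq, ann = pcrispr
        dist = SiteDistribution(lr=0, rs=0, off_target=1.0)
        batch = simulate_plasmid_library(name, seq, dist, prespacer, 10_000,
                                         seed=3, annotation=ann)
        comp = dict(zip("ACGT", "TGCA"))
        counts = {b: 0 for b in "GACT"}
        for t in batch.truth:
            base = seq[t["site"] - 1]
            counts[base if t["strand"] == "+" else comp[base]] += 1
        for base, expected in [("G", 56.5), ("A", 22.1), ("C", 13.7), ("T", 7.7)]:
            assert abs(100 * counts[base] / len(batch) - expected) < 2.0

    def test_empty_batch_for_nonpositive_n(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        batch = simulate_plasmid_library(name, seq, SiteDistribution(1, 0, 0),
                                         prespacer, 0, annotation=ann)
        assert len(batch) == 0 and batch.truth == []

    def test_identical_seed_gives_byte_identical_batches(self, pcrispr, prespacer,
                                                         tmp_path):
        name, seq, ann = pcrispr
        dist = SiteDistribution(0.4, 0.4, 0.2)
        a = simulate_plasmid_library(name, seq, dist, prespacer, 100, seed=9,
                                     annotation=ann)
        b = simulate_plasmid_library(name, seq, dist, prespacer, 100, seed=9,
                                     annotation=ann)
        a.write_fastq(tmp_path / "a.fastq")
        b.write_fastq(tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


class TestLinearLibrary:
    def test_pure_lr_top_strand_junctions_at_repeat_position_1(self, linear_target,
                                                               prespacer):
        batch = simulate_linear_library(linear_target, SiteDistribution(1.0, 0.0),
                                        prespacer, 30, seed=4, strand="top")
        assert all(t["site"] == linear_target.repeat_start() for t in batch.truth)
        for _, read, _ in batch.records:
            assert read == prespacer.top_strand + linear_target.top_strand[
                linear_target.repeat_start() - 1:]

    def test_pure_rs_bottom_strand_junctions_at_repeat_position_36(self,
                                                                   linear_target,
                                                                   prespacer):
        batch = simulate_linear_library(linear_target, SiteDistribution(0.0, 1.0),
                                        prespacer, 30, seed=5, strand="bottom")
        rs_plus = linear_target.repeat_start() + 35
        assert all(t["site"] == rs_plus and t["strand"] == "-" for t in batch.truth)

    def test_mixture_fractions_within_binomial_interval(self, linear_target,
                                                        prespacer):
        n = 4000
        batch = simulate_linear_library(linear_target, SiteDistribution(0.5, 0.5),
                                        prespacer, n, seed=6)
        k = sum(t["strand"] == "+" for t in batch.truth)
        lo, hi = stats.binom.interval(0.9999, n, 0.5)
        assert lo <= k <= hi

    def test_wrong_strand_events_are_skipped_and_tallied(self, linear_target,
                                                         prespacer):
        batch = simulate_linear_library(linear_target, SiteDistribution(0.5, 0.5),
                                        prespacer, 200, seed=7, strand="top")
        assert len(batch) + batch.skipped["strand_mismatch"] == 200
        assert all(t["strand"] == "+" for t in batch.truth)


class TestExpandedArrays:
    @pytest.mark.parametrize("mutant, expected_site", [("WT", 36), ("InsC24", 37)])
    def test_ground_truth_junction_follows_the_ruler_rule(self, genome, mutant,
                                                          expected_site):
        repeat, _ = apply_mutation(WT_REPEAT, NAMED_MUTATIONS[mutant])
        locus = build_plasmid_locus(repeat=repeat)
        pool = draw_spacer_pool(genome[1], 50, seed=8)
        batch = simulate_expanded_arrays(locus, pool, 40, seed=9)
        assert predict_second_site(repeat) == expected_site
        assert all(t["site"] == expected_site for t in batch.truth)
        # read layout: leader tail + duplicated copy + spacer + full repeat
        truth = batch.truth[0]
        read = batch.records[0][1]
        lr = truth["lr_offset"]
        assert read[lr: lr + expected_site] == (
            locus.top_strand[locus.repeat_start() - 1:])[:expected_site]
        spacer_end = lr + expected_site + truth["spacer_len"]
        assert read[spacer_end: spacer_end + len(repeat)] == repeat

    def test_empty_spacer_pool_gives_empty_batch(self):
        locus = build_plasmid_locus()
        assert len(simulate_expanded_arrays(locus, [], 10, seed=1)) == 0

    def test_oversized_junction_window_rejected_and_logged(self, genome):
        locus = build_plasmid_locus()
        pool = draw_spacer_pool(genome[1], 5, seed=2)
        batch = simulate_expanded_arrays(locus, pool, 10, seed=3, read_len=80)
        assert len(batch) == 0
        assert batch.skipped["spacer_window_overflow"] == 10

    def test_forbidden_flank_filter_respected(self, genome):
        pool = draw_spacer_pool(genome[1], 100, seed=4, forbidden_flank="C")
        gseq = genome[1]
        for spacer in pool:
            idx = gseq.find(spacer)
            assert idx > 0 and gseq[idx - 1] != "C"


class TestErrorModel:
    def test_rate_zero_returns_identical_reads(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        batch = simulate_plasmid_library(name, seq, SiteDistribution(1, 0, 0),
                                         prespacer, 20, seed=1, annotation=ann)
        assert add_errors(batch, 0.0, seed=5).records == batch.records

    def test_rate_one_changes_every_base(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        batch = simulate_plasmid_library(name, seq, SiteDistribution(1, 0, 0),
                                         prespacer, 5, seed=1, annotation=ann)
        noisy = add_errors(batch, 1.0, seed=6)
        for (_, clean, _), (_, dirty, _) in zip(batch.records, noisy.records):
            assert all(a != b for a, b in zip(clean, dirty))

    def test_substitution_count_is_binomial(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        batch = simulate_plasmid_library(name, seq, SiteDistribution(1, 0, 0),
                                         prespacer, 1000, seed=1, annotation=ann)
        noisy = add_errors(batch, 0.01, seed=7)
        total = sum(len(r[1]) for r in batch.records)
        assert total == 100_000
        subs = sum(a != b for (_, c, _), (_, d, _) in zip(batch.records, noisy.records)
                   for a, b in zip(c, d))
        assert abs(subs - 1000) < 100  # within 10% of the expectation

    def test_invalid_rate_rejected(self, pcrispr, prespacer):
        name, seq, ann = pcrispr
        batch = simulate_plasmid_library(name, seq, SiteDistribution(1, 0, 0),
                                         prespacer, 5, seed=1, annotation=ann)
        with pytest.raises(ValueError):
            add_errors(batch, -0.1)
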