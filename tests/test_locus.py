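"""Locus model: mutations, ruler predictions, integration products."""

import pytest

from spacerseq import (CrisprLocus, IntegrationEvent, NAMED_MUTATIONS,
                       build_minimal_linear_target, revcomp, simulate_products)
from spacerseq.locus import (BlockedEndError, CoordinateError, PreSpacer,
                             RepeatMutation, RulerDisruptedError, RulerElement,
                             apply_mutation, invert_coord_map, locate_ruler,
                             predict_first_site, predict_second_site)


class TestApplyMutation:
    def test_single_insertion_shifts_downstream_positions(self, wt_repeat):
        mutant, cmap = apply_mutation(wt_repeat, RepeatMutation.insertion(24, "C"))
        assert len(mutant) == 37
        assert cmap[28] == 29
        assert cmap[23] == 23

    def test_empty_substitution_is_identity(self, wt_repeat):
        mutant, cmap = apply_mutation(wt_repeat, RepeatMutation.substitution(1, ""))
        assert mutant == wt_repeat
        assert all(cmap[i] == i for i in cmap)

    def test_deletion_then_reinsertion_round_trips(self, wt_repeat):
        deleted, _ = apply_mutation(wt_repeat, RepeatMutation.deletion(14))
        restored, _ = apply_mutation(deleted,
                                     RepeatMutation.insertion(14, wt_repeat[13]))
        assert restored == wt_repeat

    def test_substitution_preserves_length(self, wt_repeat):
        mutant, cmap = apply_mutation(wt_repeat, RepeatMutation.substitution(5, "AAA"))
        assert len(mutant) == len(wt_repeat)
        assert mutant[4:7] == "AAA"
        assert all(cmap[i] == i for i in cmap)

    @pytest.mark.parametrize("mutation", [
        RepeatMutation.insertion(99, "C"),
        RepeatMutation.deletion(0),
        RepeatMutation.deletion(30, 40),
        RepeatMutation.substitution(35, "AAAA"),
    ])
    def test_out_of_range_positions_raise(self, wt_repeat, mutation):
        with pytest.raises(CoordinateError):
            apply_mutation(wt_repeat, mutation)

    def test_coord_map_is_monotone_and_invertible(self, wt_repeat):
        for mut in NAMED_MUTATIONS.values():
            _, cmap = apply_mutation(wt_repeat, mut)
            mapped = [v for v in (cmap[i] for i in sorted(cmap)) if v is not None]
            assert mapped == sorted(mapped)
            inv = invert_coord_map(cmap)
            for wt_pos, mut_pos in cmap.items():
                if mut_pos is not None:
                    assert inv[mut_pos] == wt_pos


class TestRuler:
    def test_wt_element_found_at_28(self, wt_repeat, ruler):
        assert locate_ruler(wt_repeat, ruler) == 28

    def test_scrambled_element_is_absent(self, wt_repeat, ruler):
        scrambled, _ = apply_mutation(wt_repeat, RepeatMutation.substitution(28, "ACTAG"))
        assert locate_ruler(scrambled, ruler) is None
        with pytest.raises(RulerDisruptedError):
            predict_second_site(scrambled, ruler)

    def test_insertion_mutant_location_matches_coord_map(self, wt_repeat, ruler):
        # oracle: brute-force string search shifted by the coordinate map
        mutant, cmap = apply_mutation(wt_repeat, RepeatMutation.insertion(24, "C"))
        assert locate_ruler(mutant, ruler) == cmap[28] == 29

    @pytest.mark.parametrize("name, expected", [
        ("WT", 36), ("InsC24", 37), ("Del14", 35), ("InsC33", 36),
        ("DelA23", 35), ("Ins36", 36), ("Ins36-37", 36), ("Ins36-38", 36),
        ("Del35", 36), ("Del34-35", 36), ("Del33-35", 36),
        ("InsCG33-34", 36), ("DelC33", 36), ("DelCA33-34", 36),
    ])
    def test_second_site_predictions_for_mutant_panel(self, wt_repeat, ruler,
                                                      name, expected):
        mutant, _ = apply_mutation(wt_repeat, NAMED_MUTATIONS[name])
        assert predict_second_site(mutant, ruler) == expected

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_upstream_insertions_shift_site_by_insert_length(self, wt_repeat,
                                                             ruler, k):
        wt_site = predict_second_site(wt_repeat, ruler)
        for pos in range(2, 28):
            mutant, _ = apply_mutation(wt_repeat,
                                       RepeatMutation.insertion(pos, "C" * k))
            assert predict_second_site(mutant, ruler) == wt_site + k, pos

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_upstream_deletions_shift_site_back_by_deleted_length(self, wt_repeat,
                                                                  ruler, k):
        wt_site = predict_second_site(wt_repeat, ruler)
        for start in range(2, 28 - k + 1):
            mutant, _ = apply_mutation(wt_repeat,
                                       RepeatMutation.deletion(start, start + k - 1))
            assert predict_second_site(mutant, ruler) == wt_site - k, start

    def test_first_site_invariant_under_all_repeat_mutations(self, wt_repeat):
        target = build_minimal_linear_target()
        assert predict_first_site(target) == 1
        for mut in NAMED_MUTATIONS.values():
            mutant, _ = apply_mutation(wt_repeat, mut)
            assert predict_first_site(build_minimal_linear_target(repeat=mutant)) == 1

    def test_first_site_targets_leader_proximal_repeat_of_multi_unit_locus(self):
        locus = CrisprLocus("A" * 20, (("G" * 36, "C" * 30), ("G" * 36, "T" * 30)))
        assert predict_first_site(locus) == 1

    def test_ruler_invariant_ties_wt_start_and_offset(self, ruler):
        assert ruler.wt_start + ruler.offset == 36


class TestProducts:
    def test_dideoxy_both_strands_blocks_everything(self, linear_target, prespacer):
        dd = prespacer.with_chemistry("dd", "dd")
        ev = IntegrationEvent("t", "+", linear_target.repeat_start())
        with pytest.raises(BlockedEndError):
            simulate_products(linear_target, dd, [ev])

    @pytest.mark.parametrize("topology", ["spacer-hairpin", "leader-hairpin"])
    def test_single_dideoxy_allows_only_lr_half_sites(self, prespacer, topology):
        target = build_minimal_linear_target(topology=topology)
        lr = IntegrationEvent("t", "+", target.repeat_start(), event_class="half-LR")
        rs = IntegrationEvent("t", "-", target.repeat_start() + 35,
                              event_class="half-RS")
        one_dd = prespacer.with_chemistry("OH", "dd")
        products = simulate_products(target, one_dd, [lr])
        assert len(products) == 1
        with pytest.raises(BlockedEndError):
            simulate_products(target, one_dd, [rs])

    def test_half_lr_product_length_on_66nt_target(self, linear_target, prespacer):
        # independent check: concatenate the strings by hand
        site = linear_target.repeat_start()  # position 11 of 66
        ev = IntegrationEvent("t", "+", site)
        (product,) = simulate_products(linear_target, prespacer, [ev])
        expected = prespacer.top_strand + linear_target.top_strand[site - 1:]
        assert product.sequence == expected
        assert product.length == 35 + 56 == 91

    def test_half_rs_product_is_prespacer_plus_minus_strand_tail(self,
                                                                 linear_target,
                                                                 prespacer):
        site = linear_target.repeat_start() + 35  # RS site, plus coordinate 46
        ev = IntegrationEvent("t", "-", site, event_class="half-RS")
        (product,) = simulate_products(linear_target, prespacer, [ev])
        assert product.sequence == prespacer.bottom_strand + revcomp(
            linear_target.top_strand[:site])
        assert product.length == 35 + 46

    def test_spacer_hairpin_product_continues_through_the_loop(self, prespacer):
        target = build_minimal_linear_target(topology="spacer-hairpin")
        ev = IntegrationEvent("t", "+", target.repeat_start())
        (product,) = simulate_products(target, prespacer, [ev])
        n = len(target.top_strand)
        assert product.length == 35 + 56 + len(target.hairpin_loop) + n


class TestPreSpacer:
    def test_default_geometry_is_30bp_core_with_5nt_overhangs(self, prespacer):
        assert len(prespacer.top_strand) == len(prespacer.bottom_strand) == 35
        assert revcomp(prespacer.top_strand[:30]) == prespacer.bottom_strand[:30]

    def test_bad_chemistry_string_rejected(self):
        with pytest.raises(ValueError):
            PreSpacer("ACGT", "ACGT", top_3p="PO4")
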