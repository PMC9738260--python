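"""Group allele sets, cluster-exclusive eplets and driver filtering."""

import numpy as np
import pytest

from epletclust.nomination import (
    ExclusionReason,
    GroupAlleleSets,
    NominationError,
    chain_attribution,
    exclusive_eplets,
    group_alleles,
    nominate_drivers,
)
from epletclust.registry import ElliProCategory, EpletRecord, EpletRegistry

from conftest import exclusivity_oracle, random_registry_and_groups

RETAINED_DR = {
    "30C", "30G", "37S", "71A", "96EV", "108T", "142M", "48Q", "96Y", "11STS",
    "31FH", "37L", "57A", "57DE", "70QQ", "74R", "77N", "96HK", "98Q",
}


class TestGroupAlleles:
    def test_dr_reference_group_b_has_eight_alleles(self, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        assert len(gs.groups["B"]) == 8
        assert "DRB4*01:01" in gs.groups["B"]

    def test_alpha_allele_can_sit_in_several_groups(self, dq_panel, dq_groups):
        gs = group_alleles(dq_groups, dq_panel)
        multi = [g for g, alleles in gs.groups.items() if "DQA1*02:01" in alleles]
        assert len(multi) >= 2  # pairs into DQ2, DQ3 and DQ4 heterodimers

    def test_single_group_unions_whole_panel(self, drb_panel):
        gs = group_alleles({b: "all" for b in drb_panel.bead_ids}, drb_panel)
        assert gs.groups["all"] == drb_panel.alleles

    def test_unknown_bead_rejected(self, drb_panel, drb_groups):
        with pytest.raises(NominationError, match="GHOST"):
            group_alleles({**drb_groups, "GHOST": "A"}, drb_panel)

    def test_unassigned_bead_rejected(self, drb_panel, drb_groups):
        partial = dict(drb_groups)
        partial.popitem()
        with pytest.raises(NominationError, match="no group"):
            group_alleles(partial, drb_panel)


class TestExclusiveEplets:
    def test_dr_reference_yields_32_rows(self, drb_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        rows = exclusive_eplets(gs, drb_registry)
        assert len(rows) == 32

    def test_dq_reference_yields_28_rows(self, dq_registry, dq_panel, dq_groups):
        gs = group_alleles(dq_groups, dq_panel)
        rows = exclusive_eplets(gs, dq_registry)
        assert len(rows) == 28

    def test_shared_eplet_across_groups_is_dropped(self):
        registry = EpletRegistry(
            locus_group="DRB",
            expression_map={
                "DRB1*01:01": frozenset({"X"}),
                "DRB1*03:01": frozenset({"X"}),
            },
            eplet_index={"X": EpletRecord("X", "beta", ElliProCategory.HIGH)},
        )
        gs = GroupAlleleSets(
            locus_group="DRB",
            groups={
                "G1": frozenset({"DRB1*01:01"}),
                "G2": frozenset({"DRB1*03:01"}),
            },
        )
        assert exclusive_eplets(gs, registry) == []

    def test_locus_mismatch_rejected(self, dq_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        with pytest.raises(NominationError, match="locus"):
            exclusive_eplets(gs, dq_registry)

    def test_matches_brute_force_oracle(self):
        """Random registries: implementation vs direct enumeration of the rule."""
        rng = np.random.default_rng(97)
        for trial in range(120):
            registry, gs = random_registry_and_groups(
                rng, disjoint=bool(trial % 2)
            )
            rows = exclusive_eplets(gs, registry)
            assert {(r.eplet, r.group) for r in rows} == exclusivity_oracle(gs, registry)

    def test_merging_groups_keeps_their_exclusive_eplets(self):
        """For disjoint (partitioned) groups, merging two never loses eplets."""
        rng = np.random.default_rng(101)
        for _ in range(60):
            registry, gs = random_registry_and_groups(rng, disjoint=True)
            before = len(exclusive_eplets(gs, registry))
            gids = sorted(gs.groups)
            if len(gids) < 2:
                continue
            a, b = gids[0], gids[1]
            merged_groups = {
                g: alleles for g, alleles in gs.groups.items() if g not in (a, b)
            }
            merged_groups[f"{a}+{b}"] = gs.groups[a] | gs.groups[b]
            merged = GroupAlleleSets(locus_group=gs.locus_group, groups=merged_groups)
            assert len(exclusive_eplets(merged, registry)) >= before


class TestNominateDrivers:
    def test_dr_reference_decomposition(self, drb_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        report = nominate_drivers(exclusive_eplets(gs, drb_registry))
        reasons = [f.reason for f in report.rows]
        assert reasons.count(ExclusionReason.SINGLE_ALLELE) == 8
        assert reasons.count(ExclusionReason.LOW_SCORE) == 5
        assert len(report.retained) == 19
        assert set(report.retained) == RETAINED_DR

    def test_unknown_score_is_retained(self, drb_registry, drb_panel, drb_groups):
        # 96HK has a blank ElliPro cell; a missing category is not evidence
        # against the eplet, so it stays on the driver list
        gs = group_alleles(drb_groups, drb_panel)
        report = nominate_drivers(exclusive_eplets(gs, drb_registry))
        assert "96HK" in report.retained

    def test_empty_input(self):
        report = nominate_drivers([])
        assert report.rows == [] and report.retained == []

    def test_disabled_filters_retain_everything(self, drb_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        rows = exclusive_eplets(gs, drb_registry)
        report = nominate_drivers(
            rows, min_allele_count=1, allowed_scores=frozenset(ElliProCategory)
        )
        assert len(report.retained) == len(rows)

    def test_single_allele_precedes_low_score(self):
        registry = EpletRegistry(
            locus_group="DRB",
            expression_map={"DRB1*01:01": frozenset({"X"})},
            eplet_index={"X": EpletRecord("X", "beta", ElliProCategory.LOW)},
        )
        gs = GroupAlleleSets(
            locus_group="DRB", groups={"G1": frozenset({"DRB1*01:01"})}
        )
        report = nominate_drivers(exclusive_eplets(gs, registry))
        assert report.rows[0].reason is ExclusionReason.SINGLE_ALLELE

    def test_order_preserving_and_idempotent(self, drb_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        rows = exclusive_eplets(gs, drb_registry)
        report = nominate_drivers(rows)
        assert [f.row for f in report.rows] == rows
        again = nominate_drivers([f.row for f in report.rows])
        assert again.retained == report.retained


class TestChainAttribution:
    def test_dq_alpha_drivers(self, dq_registry, dq_panel, dq_groups):
        gs = group_alleles(dq_groups, dq_panel)
        report = nominate_drivers(exclusive_eplets(gs, dq_registry))
        alpha_retained = {
            f.row.eplet
            for f in report.rows
            if f.reason is ExclusionReason.NONE and f.row.chain_class == "alpha"
        }
        assert alpha_retained == {"52SK", "129QS"}
        assert chain_attribution(report)["alpha"] == 2

    def test_dr_drivers_all_beta(self, drb_registry, drb_panel, drb_groups):
        gs = group_alleles(drb_groups, drb_panel)
        report = nominate_drivers(exclusive_eplets(gs, drb_registry))
        counts = chain_attribution(report)
        assert counts == {"alpha": 0, "beta": 19}

    def test_empty_report(self):
        assert chain_attribution(nominate_drivers([])) == {"alpha": 0, "beta": 0}
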