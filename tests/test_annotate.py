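"""Positional classification, isomiR clustering and normalization."""

import pytest

from xenomir.align import HairpinAlignment, align_and_resolve
from xenomir.annotate import (
    ARM_VARIANT,
    KNOWN_MATURE,
    LOOP,
    LOOP_NO_MATURE,
    PUTATIVE_STAR,
    AnnotatedGroup,
    AnnotationResult,
    annotate_tags,
    classify_alignment,
    cluster_isomirs,
    infer_loop_interval,
    normalize_counts,
    star_ratio_report,
)
from xenomir.config import METASTATIC, NON_METASTATIC
from xenomir.io import FIVE_PRIME, HairpinReference, MatureAnnotation
from xenomir.preprocess import TagRecord

from conftest import counts


def aln(hid: str, start: int, end: int, tag: str = "") -> HairpinAlignment:
    return HairpinAlignment(tag or "N" * (end - start), hid, start, end, 0)


class TestLoopInterval:
    def test_two_matures_forced_interval(self, two_mature_hairpin):
        ms = two_mature_hairpin.matures_of("hp-1")
        assert infer_loop_interval(80, ms) == (32, 48)

    def test_single_mature_mirror_reflection(self, single_mature_hairpin):
        ms = single_mature_hairpin.matures_of("hp-2")
        assert infer_loop_interval(80, ms) == (32, 48)

    def test_no_matures_central_third(self):
        assert infer_loop_interval(90, []) == (30, 60)

    def test_degenerate_interval_collapses_to_midpoint(self):
        ms = [
            MatureAnnotation("a", "h", 0, 45, FIVE_PRIME),
            MatureAnnotation("b", "h", 40, 80, "three_prime"),
        ]
        assert infer_loop_interval(80, ms) == (40, 40)


class TestClassify:
    def test_isomir_within_two_nt_both_ends(self, two_mature_hairpin):
        c = classify_alignment(aln("hp-1", 11, 33), two_mature_hairpin, 2)
        assert (c.category, c.feature, c.start_shift) == (KNOWN_MATURE, "miR-A", 1)

    def test_opposite_arm_of_single_mature_is_putative_star(self, single_mature_hairpin):
        c = classify_alignment(aln("hp-2", 50, 72), single_mature_hairpin, 2)
        assert (c.category, c.feature) == (PUTATIVE_STAR, "miR-B*")

    def test_read_between_arms_is_loop(self, two_mature_hairpin):
        c = classify_alignment(aln("hp-1", 36, 44), two_mature_hairpin, 2)
        assert c.category == LOOP

    def test_loop_without_matures(self):
        ref = HairpinReference(records={"hp": "ACGT" * 25})
        c = classify_alignment(aln("hp", 40, 55), ref, 2)
        assert c.category == LOOP_NO_MATURE

    def test_arm_overlap_beyond_tolerance_is_variant(self, two_mature_hairpin):
        c = classify_alignment(aln("hp-1", 15, 37), two_mature_hairpin, 2)
        assert c.category == ARM_VARIANT

    def test_no_star_call_on_two_mature_hairpin(self, two_mature_hairpin):
        # the 3' arm of a fully annotated hairpin is a known mature, never a
        # putative star
        c = classify_alignment(aln("hp-1", 48, 70), two_mature_hairpin, 2)
        assert (c.category, c.feature) == (KNOWN_MATURE, "miR-A*")


def group(start, shift, met, nonmet) -> AnnotatedGroup:
    g = AnnotatedGroup(
        feature="miR-A", category=KNOWN_MATURE, hairpin_id="hp-1",
        group_start=start, start_shift=shift, counts=counts(met, nonmet))
    g.seq_counts["N" * 22] = met + nonmet
    return g


class TestClusterIsomirs:
    def test_most_abundant_start_wins_and_zero_shift_kept(self):
        groups = [group(10, 0, 40, 60), group(11, 1, 70, 80), group(9, -1, 10, 10)]
        out = cluster_isomirs(groups)
        rep = [g for g in out if g.is_representative]
        assert len(rep) == 1 and rep[0].group_start == 11
        # the annotated-start group rides along as its own row
        assert {g.group_start for g in out} == {11, 10}

    def test_single_start_single_row(self):
        out = cluster_isomirs([group(10, 0, 5, 5)])
        assert len(out) == 1 and out[0].is_representative

    def test_combined_tie_breaks_upstream(self):
        out = cluster_isomirs([group(9, -1, 25, 25), group(11, 1, 30, 20)])
        rep = [g for g in out if g.is_representative][0]
        assert rep.group_start == 9


class TestNormalize:
    def test_zero_raw(self):
        assert normalize_counts(0, 100, 1e6) == 0.0

    def test_full_library(self):
        assert normalize_counts(7, 7, 1e6) == 1e6

    def test_two_reads_in_2173913(self):
        # 2 / 2,173,913 * 1e6 = 0.9200 -> prints as 0.92
        assert f"{normalize_counts(2, 2_173_913, 1e6):.2f}" == "0.92"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(1, 0, 1e6)


class TestAnnotateTags:
    def _run(self, reference, tags, config):
        resolved = align_and_resolve(
            [t.sequence for t in tags], reference, config.max_mismatches)
        return annotate_tags(tags, resolved, reference, config)

    def test_counts_conserved_and_normalized_sum_to_scale(
            self, two_mature_hairpin, config):
        seq = two_mature_hairpin.records["hp-1"]
        tags = [
            TagRecord(seq[10:32], counts(5, 3)),      # mature
            TagRecord(seq[11:33], counts(2, 0)),      # isomiR, +1
            TagRecord(seq[48:70], counts(4, 6)),      # star arm
            TagRecord(seq[32:48], counts(2, 2)),      # loop
            TagRecord(seq[15:37], counts(3, 1)),      # arm variant
        ]
        result = self._run(two_mature_hairpin, tags, config)
        assert result.table.library_totals == {METASTATIC: 16, NON_METASTATIC: 12}
        for lib in (METASTATIC, NON_METASTATIC):
            assert sum(r[f"norm_{lib}"] for r in result.table.rows) == pytest.approx(
                config.norm_scale)
        categories = {r["category"] for r in result.table.rows}
        assert categories == {KNOWN_MATURE, LOOP, ARM_VARIANT}

    def test_every_tag_in_exactly_one_group(self, two_mature_hairpin, config):
        seq = two_mature_hairpin.records["hp-1"]
        tags = [TagRecord(seq[s:s + 20], counts(2, 2)) for s in range(0, 55, 5)]
        result = self._run(two_mature_hairpin, tags, config)
        total = sum(r[f"raw_{METASTATIC}"] for r in result.table.rows)
        assert total == sum(t.count(METASTATIC) for t in tags)

    def test_zero_mapped_counts_rejected(self, two_mature_hairpin, config):
        tags = [TagRecord("A" * 20, counts(3, 3))]  # aligns nowhere
        with pytest.raises(ValueError):
            self._run(two_mature_hairpin, tags, config)


class TestStarRatioReport:
    def _result(self, rows):
        return AnnotationResult(
            groups=[], table=None, de_rows=rows, ambiguous_tags=0, unaligned_tags=0)

    def _row(self, feature, met, nonmet):
        return {
            "feature": feature, "hairpin_id": "hp-1", "category": KNOWN_MATURE,
            "group_start": 0, "start_shift": 0, "is_representative": True,
            "sequence": "N" * 22,
            f"raw_{METASTATIC}": 0, f"raw_{NON_METASTATIC}": 0,
            f"norm_{METASTATIC}": met, f"norm_{NON_METASTATIC}": nonmet,
        }

    def test_dominance_switch_flagged(self, two_mature_hairpin):
        # miR-126-style: 5' arm dominates in one library, 3' arm in the other
        rows = [self._row("miR-A", 26005.24, 1799.70),
                self._row("miR-A*", 1099.03, 3798.06)]
        report = star_ratio_report(self._result(rows), two_mature_hairpin)
        assert report[0]["dominance_switch"] is True

    def test_missing_arm_counts_zero_no_flag(self, two_mature_hairpin):
        rows = [self._row("miR-A", 10.0, 20.0)]
        report = star_ratio_report(self._result(rows), two_mature_hairpin)
        assert report[0]["metastatic_3p"] == 0.0
        assert report[0]["dominance_switch"] is False

    def test_equal_arms_noted_as_tie(self, two_mature_hairpin):
        rows = [self._row("miR-A", 5.0, 7.0), self._row("miR-A*", 5.0, 2.0)]
        report = star_ratio_report(self._result(rows), two_mature_hairpin)
        assert report[0]["note"] == "tie"
        assert report[0]["dominance_switch"] is False
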