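"""Deletion-interval inference and direct-repeat footprint detection."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fractionato.repeat_signature import (
    FOOTPRINT,
    NO_FOOTPRINT,
    DeletionEvent,
    NotSingleDeletionError,
    classify_footprint,
    infer_deletion_interval,
    split_by_anchors,
    summarize_footprints,
)
from fractionato.synthetic_data import generate_sequence_pair


class TestInferDeletionInterval:
    def test_worked_example(self):
        ev = infer_deletion_interval("AACGATGGGGCGATTT", "AACGATTT")
        assert ev.gap_size == 8
        assert (ev.placement_min, ev.placement_max) == (2, 6)
        assert ev.repeat == "CGAT" and ev.repeat_length == 4

    def test_worked_example_exhaustive_placements(self):
        pre, prod = "AACGATGGGGCGATTT", "AACGATTT"
        gap = len(pre) - len(prod)
        valid = [
            s for s in range(len(prod) + 1) if pre[:s] + pre[s + gap :] == prod
        ]
        ev = infer_deletion_interval(pre, prod)
        assert valid == list(range(ev.placement_min, ev.placement_max + 1))

    def test_homopolymer_edge_case(self):
        ev = infer_deletion_interval("AAAATTTT", "AAATTTT")
        assert ev.gap_size == 1
        assert (ev.placement_min, ev.placement_max) == (0, 3)
        assert ev.repeat == "AAA"

    def test_equal_sequences_rejected(self):
        with pytest.raises(NotSingleDeletionError):
            infer_deletion_interval("ACGT", "ACGT")

    def test_incompatible_pair_rejected(self):
        with pytest.raises(NotSingleDeletionError):
            infer_deletion_interval("AAAAAA", "CCCC")

    def test_n_in_deleted_segment_is_harmless(self):
        # unknown bases inside the excised segment never touch the matching
        ev = infer_deletion_interval("GGCCTNTACCGG", "GGCCCCGG")
        assert ev.gap_size == 4 and ev.repeat_length == 0

    def test_n_in_product_blocks_inference(self):
        # N never matches, so a placement cannot be verified across it
        with pytest.raises(NotSingleDeletionError):
            infer_deletion_interval("AANCGGGGTT", "AANCTT")

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            infer_deletion_interval("ACXT", "AC")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=150, deadline=None)
    def test_planted_repeat_recovered_exactly(self, seed):
        rng_len = seed % 25  # repeat lengths 0..24, the published range
        pre, prod, truth = generate_sequence_pair(
            flank_len=40, insert_len=10, repeat_len=rng_len, seed=seed
        )
        ev = infer_deletion_interval(pre, prod)
        assert ev.repeat_length == rng_len
        assert ev.repeat == truth.repeat
        assert ev.gap_size == truth.gap_size

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_reconstruction_and_reversal_symmetry(self, seed):
        pre, prod, _ = generate_sequence_pair(
            flank_len=30, insert_len=8, repeat_len=seed % 10, seed=seed
        )
        ev = infer_deletion_interval(pre, prod)
        for s in range(ev.placement_min, ev.placement_max + 1):
            assert pre[:s] + pre[s + ev.gap_size :] == prod
        rev = infer_deletion_interval(pre[::-1], prod[::-1])
        assert (rev.gap_size, rev.repeat_length) == (ev.gap_size, ev.repeat_length)


class TestClassifyAndSummarize:
    @staticmethod
    def _event(repeat_length, gap=20):
        return DeletionEvent(
            precursor_id="p", product_id="q", gap_size=gap,
            placement_min=0, placement_max=repeat_length, repeat="A" * repeat_length,
        )

    @pytest.mark.parametrize(
        "repeat_length,label",
        [(0, NO_FOOTPRINT), (2, NO_FOOTPRINT), (3, FOOTPRINT), (4, FOOTPRINT), (24, FOOTPRINT)],
    )
    def test_threshold(self, repeat_length, label):
        assert classify_footprint(self._event(repeat_length)) == label

    def test_summary_counts_and_gaps(self):
        events = [self._event(r, gap=g) for r, g in [(0, 5), (2, 30), (3, 178), (10, 9)]]
        report = summarize_footprints(events, min_repeat_len=3)
        assert report.footprint_positive == 2 and report.n_events == 4
        assert (report.gap_min, report.gap_max) == (5, 178)
        assert report.gap_mean == pytest.approx((5 + 30 + 178 + 9) / 4)

    def test_single_event_without_repeat(self):
        report = summarize_footprints([self._event(0)])
        assert report.footprint_positive == 0 and report.n_events == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_footprints([])


def test_split_by_anchors_isolates_gaps():
    # two gaps in one gene: split into windows, then infer each separately
    p1, q1, t1 = generate_sequence_pair(flank_len=25, insert_len=6, repeat_len=4, seed=10)
    p2, q2, t2 = generate_sequence_pair(flank_len=25, insert_len=9, repeat_len=0, seed=11)
    pre, prod = p1 + p2, q1 + q2
    pairs = split_by_anchors(
        pre, prod,
        [((0, len(p1)), (0, len(q1))), ((len(p1), len(pre)), (len(q1), len(prod)))],
    )
    ev1 = infer_deletion_interval(*pairs[0])
    ev2 = infer_deletion_interval(*pairs[1])
    assert ev1.repeat_length == 4 and ev1.gap_size == t1.gap_size
    assert ev2.repeat_length == 0 and ev2.gap_size == t2.gap_size
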