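"""Gap typing, tag pairing, N-padding arithmetic, and edit application."""

import hashlib
from fractions import Fraction

import numpy as np
import pytest
from conftest import random_dna

from tilegap import (
    Gap,
    LongRead,
    Scaffold,
    TagAlignmentRecord,
    apply_closures,
    close_type1,
    close_type2,
    close_type3,
    collect_boundary_support,
    pair_tags,
    select_spanning_read,
    total_n_count,
)
from tilegap.align_filter import TagAnchor
from tilegap.closure import SENTINEL_N, BoundarySupport, TagPair
from tilegap.tiling import Tag


def make_anchor(read_id, index, start, tag_len=300, orientation="+"):
    tag = Tag(read_id, index, index * tag_len, tag_len, "A" * tag_len)
    rec = TagAlignmentRecord(
        tag.id, "s1", start, orientation, tag_len, 0, tag_len
    )
    return TagAnchor(tag, rec)


def make_left_support(gap, read, *, slack, tag_len=300, orientation="+"):
    """Support whose nearest anchor ends ``slack`` bases before the gap.

    The anchor is placed so the read's canonical tail past the anchor is
    whatever the read length implies; extension follows from both.
    """
    # nearest anchor: last full tag of the read prefix that aligns
    pc = 0  # canonical tag offset; choose tag 0 for simplicity
    rec_end = gap.start - slack
    anchor = make_anchor(read.id, 0, rec_end - tag_len, tag_len, orientation)
    tail = read.length - pc - tag_len
    ext = max(0, tail - slack)
    return BoundarySupport(gap, "left", read.id, orientation, [anchor], anchor, slack, ext)


def make_right_support(gap, read, *, slack, pc, tag_len=300, orientation="+"):
    """Support whose nearest anchor starts ``slack`` bases after the gap and
    sits at canonical read offset ``pc``."""
    tag = Tag(read.id, 0, pc, tag_len, "A" * tag_len)
    rec = TagAlignmentRecord(tag.id, "s1", gap.end + slack, orientation, tag_len, 0, tag_len)
    anchor = TagAnchor(tag, rec)
    ext = max(0, pc - slack)
    return BoundarySupport(gap, "right", read.id, orientation, [anchor], anchor, slack, ext)


class TestPairTags:
    def _supports(self, gap, read, pa, ob_minus_oa, pb, tag_len=100):
        a = TagAnchor(
            Tag(read.id, pa // tag_len, pa, tag_len, "A" * tag_len),
            TagAlignmentRecord(f"{read.id}#a", "s1", 10_000, "+", tag_len, 0, tag_len),
        )
        b = TagAnchor(
            Tag(read.id, pb // tag_len, pb, tag_len, "A" * tag_len),
            TagAlignmentRecord(
                f"{read.id}#b", "s1", 10_000 + ob_minus_oa, "+", tag_len, 0, tag_len
            ),
        )
        left = BoundarySupport(gap, "left", read.id, "+", [a], a, 0, 0)
        right = BoundarySupport(gap, "right", read.id, "+", [b], b, 0, 0)
        return left, right

    def test_equal_distances_retained(self):
        gap = Gap("s1", 10_200, 11_000)
        read = LongRead("A", "A" * 5_000)
        left, right = self._supports(gap, read, pa=500, ob_minus_oa=2_400, pb=2_900)
        (pair,) = pair_tags(left, right, read)
        assert pair.ratio == 1 and pair.retained

    @pytest.mark.parametrize("dp,do,c,retained", [
        (1_250, 1_000, 0.2, False),  # ratio 1.25 outside the interval
        (1_200, 1_000, 0.2, False),  # ratio exactly 1 + c: strict, rejected
        (1_199, 1_000, 0.2, True),
        (801, 1_000, 0.2, True),
        (800, 1_000, 0.2, False),  # ratio exactly 1 - c: strict, rejected
    ])
    def test_strict_ratio_bounds(self, dp, do, c, retained):
        gap = Gap("s1", 10_100, 10_500)
        read = LongRead("A", "A" * 5_000)
        left, right = self._supports(gap, read, pa=0, ob_minus_oa=do, pb=dp)
        (pair,) = pair_tags(left, right, read, c)
        assert pair.retained is retained


class TestSelectSpanningRead:
    reads = {
        "A": LongRead("A", "A" * 9_000),
        "B": LongRead("B", "A" * 8_000),
        "C": LongRead("C", "A" * 9_000),
    }

    def test_argmax_by_pair_count(self):
        assert select_spanning_read({"A": 7, "B": 5}, self.reads) == "A"

    def test_tie_broken_by_read_length_then_id(self):
        assert select_spanning_read({"A": 5, "B": 5}, self.reads) == "A"
        assert select_spanning_read({"A": 5, "C": 5}, self.reads) == "A"

    def test_no_candidates(self):
        assert select_spanning_read({}, self.reads) is None
        assert select_spanning_read({"A": 0}, self.reads) is None


class TestCloseType1:
    def test_error_free_fill_restores_truth(self, rng):
        truth = random_dna(rng, 6_000)
        gap_start, gap_end = 2_500, 3_300
        gapped = truth[:gap_start] + "N" * 800 + truth[gap_end:]
        gap = Gap("s1", gap_start, gap_end)
        read = LongRead("A", truth[1_000:5_000])
        # anchors: tag 4 covers truth[2200:2500), tag 9 covers truth[3700:4000)
        a = TagAnchor(
            Tag("A", 4, 1_200, 300, read.sequence[1_200:1_500]),
            TagAlignmentRecord("A#4", "s1", 2_200, "+", 300, 0, 300),
        )
        b = TagAnchor(
            Tag("A", 9, 2_700, 300, read.sequence[2_700:3_000]),
            TagAlignmentRecord("A#9", "s1", 3_700, "+", 300, 0, 300),
        )
        pair = TagPair(a, b, Fraction(1), True)
        result = close_type1(gap, read, [pair])
        assert result.gap_type == 1 and result.inserted_n == 0
        assert result.status == "closed"
        new = apply_closures([Scaffold("s1", gapped)], [result])[0]
        assert new.sequence == truth

    def test_reverse_orientation_fill_is_reverse_complemented(self, rng):
        from tilegap._util import revcomp

        truth = random_dna(rng, 6_000)
        gap_start, gap_end = 2_500, 3_300
        gapped = truth[:gap_start] + "N" * 800 + truth[gap_end:]
        gap = Gap("s1", gap_start, gap_end)
        read = LongRead("A", revcomp(truth[1_000:5_000]))
        L = read.length
        # same loci as the forward test, seen from the reverse-strand read
        pa_canon, pb_canon = 1_200, 2_700
        a = TagAnchor(
            Tag("A", 0, L - pa_canon - 300, 300, ""),
            TagAlignmentRecord("A#a", "s1", 2_200, "-", 300, 0, 300),
        )
        b = TagAnchor(
            Tag("A", 0, L - pb_canon - 300, 300, ""),
            TagAlignmentRecord("A#b", "s1", 3_700, "-", 300, 0, 300),
        )
        result = close_type1(gap, read, [TagPair(a, b, Fraction(1), True)])
        new = apply_closures([Scaffold("s1", gapped)], [result])[0]
        assert new.sequence == truth

    def test_requires_retained_pair(self):
        gap = Gap("s1", 100, 200)
        with pytest.raises(ValueError):
            close_type1(gap, LongRead("A", "A" * 1_000), [])


class TestCloseType2:
    def _gap(self, L_C=1_000):
        return Gap("s1", 10_000, 10_000 + L_C)

    def _run(self, ext_left, ext_right, L_C=1_000, slack_l=0, slack_r=0):
        gap = self._gap(L_C)
        read_a = LongRead("A", "A" * (300 + slack_l + ext_left))
        pc_b = slack_r + ext_right
        read_b = LongRead("B", "C" * (pc_b + 300))
        left = make_left_support(gap, read_a, slack=slack_l)
        right = make_right_support(gap, read_b, slack=slack_r, pc=pc_b)
        assert (left.extension, right.extension) == (ext_left, ext_right)
        reads = {"A": read_a, "B": read_b}
        return close_type2(gap, left, right, reads)

    def test_spacer_formula_when_reads_do_not_meet(self):
        result = self._run(600, 300)
        assert result.inserted_n == 100
        assert len(result.fill) == 600 + 100 + 300
        assert result.status == "partial"

    def test_sentinel_when_reads_jointly_overspan(self):
        result = self._run(600, 500)  # 1,100 >= 1,000
        assert result.inserted_n == SENTINEL_N == 100

    def test_degenerate_left_contributes_nothing(self):
        result = self._run(0, 300)
        assert result.inserted_n == 700

    def test_zero_total_extension_emits_nothing(self):
        assert self._run(0, 0) is None

    def test_interval_length_preserved_when_not_met(self):
        result = self._run(400, 200, slack_l=50, slack_r=30)
        assert len(result.fill) == (result.end - result.start)


class TestCloseType3:
    def _run(self, ext, L_C=1_000, slack=0, side="left"):
        gap = Gap("s1", 10_000, 10_000 + L_C)
        if side == "left":
            read = LongRead("A", "A" * (300 + slack + ext))
            sup = make_left_support(gap, read, slack=slack)
        else:
            read = LongRead("A", "A" * (slack + ext + 300))
            sup = make_right_support(gap, read, slack=slack, pc=slack + ext)
        assert sup.extension == ext
        return close_type3(gap, sup, {"A": read})

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_partial_fill_pads_remaining_gap(self, side):
        result = self._run(400, side=side)
        assert result.gap_type == 3
        assert result.inserted_n == 600
        assert len(result.fill) == 1_000

    @pytest.mark.parametrize("side", ["left", "right"])
    def test_overspan_truncated_to_sentinel(self, side):
        result = self._run(1_200, side=side)
        assert result.inserted_n == SENTINEL_N
        assert len(result.fill) == 1_000  # 900 bases + 100 N

    def test_zero_extension_no_edit(self):
        assert self._run(0) is None


class TestApplyClosures:
    def test_zero_results_identity(self):
        sc = Scaffold("s1", "ACGTNNNNACGT")
        assert apply_closures([sc], []) == [sc]

    def test_type1_closure_removes_gap_n(self, rng):
        truth = random_dna(rng, 2_000)
        sc = Scaffold("s1", truth[:800] + "N" * 200 + truth[1_000:])
        gap = Gap("s1", 800, 1_000)
        from tilegap.closure import ClosureResult

        res = ClosureResult(gap, 1, 800, 1_000, truth[800:1_000], ("A",))
        new = apply_closures([sc], [res])[0]
        assert total_n_count([sc]) - total_n_count([new]) == 200

    def test_flanks_outside_intervals_untouched(self, rng):
        from tilegap.closure import ClosureResult

        seq = random_dna(rng, 5_000)
        seq = seq[:1_000] + "N" * 300 + seq[1_300:4_000] + "N" * 300 + seq[4_300:]
        sc = Scaffold("s1", seq)
        r1 = ClosureResult(Gap("s1", 1_000, 1_300), 1, 950, 1_350, "G" * 420, ("A",))
        r2 = ClosureResult(Gap("s1", 4_000, 4_300), 1, 3_990, 4_310, "T" * 300, ("B",))
        new = apply_closures([sc], [r1, r2])[0]
        checksum = lambda s: hashlib.sha256(s.encode()).hexdigest()
        assert checksum(new.sequence[:950]) == checksum(seq[:950])
        assert checksum(new.sequence[-(len(seq) - 4_310) :]) == checksum(seq[4_310:])
        # the slice between the two edits is shifted by the first fill's size
        shift = 420 - (1_350 - 950)
        assert new.sequence[1_350 + shift : 3_990 + shift] == seq[1_350:3_990]

    def test_overlapping_intervals_rejected(self):
        from tilegap.closure import ClosureResult

        sc = Scaffold("s1", "A" * 1_000)
        r1 = ClosureResult(Gap("s1", 100, 200), 1, 100, 300, "G" * 200, ())
        r2 = ClosureResult(Gap("s1", 250, 350), 1, 250, 350, "T" * 100, ())
        with pytest.raises(ValueError):
            apply_closures([sc], [r1, r2])


class TestBoundarySupport:
    def _anchors(self, read_id, ends, tag_len=300):
        """Anchors whose alignments end at the given scaffold positions."""
        return [
            make_anchor(read_id, i, end - tag_len)
            for i, end in enumerate(sorted(ends))
        ]

    def test_min_tag_count_inclusive(self):
        gap = Gap("s1", 10_000, 11_000)
        reads = {"A": LongRead("A", "A" * 12_000)}
        anchors = self._anchors("A", [10_000 - 300 * k for k in range(6)])
        left, right = collect_boundary_support(gap, anchors, reads, 5_000, 5)
        assert len(left) == 1 and left[0].tag_count == 6
        assert right == []

    def test_four_anchors_insufficient(self):
        gap = Gap("s1", 10_000, 11_000)
        reads = {"A": LongRead("A", "A" * 12_000)}
        anchors = self._anchors("A", [10_000 - 300 * k for k in range(4)])
        left, _ = collect_boundary_support(gap, anchors, reads, 5_000, 5)
        assert left == []

    def test_window_excludes_distant_anchors(self):
        gap = Gap("s1", 50_000, 51_000)
        reads = {"A": LongRead("A", "A" * 60_000)}
        anchors = self._anchors("A", [30_000 - 300 * k for k in range(8)])
        left, right = collect_boundary_support(gap, anchors, reads, 5_000, 5)
        assert left == [] and right == []

    def test_terminal_gap_single_sided(self):
        gap = Gap("s1", 0, 500, terminal=True)
        reads = {"A": LongRead("A", "A" * 10_000)}
        anchors = [make_anchor("A", i, 500 + 300 * i) for i in range(6)]
        left, right = collect_boundary_support(gap, anchors, reads, 5_000, 5)
        assert left == [] and len(right) == 1


class TestNSpacerFormulaRandomized:
    def test_formula_equivalence_on_random_configurations(self):
        """The spacer N count always equals L_C - (L_A - p_a + p_b) with
        orientation-adjusted boundary-entry positions, over 1,000 random
        type-2 configurations that do not meet in the middle."""
        rng = np.random.default_rng(7)
        for _ in range(1_000):
            L_C = int(rng.integers(200, 3_000))
            ext_a = int(rng.integers(0, L_C))
            ext_b = int(rng.integers(0, L_C - ext_a))
            if ext_a + ext_b == 0:
                continue
            slack_l = int(rng.integers(0, 200))
            slack_r = int(rng.integers(0, 200))
            gap = Gap("s1", 10_000, 10_000 + L_C)
            read_a = LongRead("A", "A" * (300 + slack_l + ext_a))
            pc_b = slack_r + ext_b
            read_b = LongRead("B", "C" * (pc_b + 300))
            left = make_left_support(gap, read_a, slack=slack_l)
            right = make_right_support(gap, read_b, slack=slack_r, pc=pc_b)
            result = close_type2(gap, left, right, {"A": read_a, "B": read_b})
            # boundary-entry positions: read base landing on each gap edge
            p_a_eff = left.nearest.tag.p + 300 + slack_l
            p_b_eff = pc_b - slack_r
            expected = L_C - (read_a.length - p_a_eff + p_b_eff)
            assert result.inserted_n == expected == L_C - ext_a - ext_b
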