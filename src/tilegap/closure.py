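"""Gap classification and closure.

Each gap (length L_C) falls into one of three types:

1. one read anchors both flanks with enough tags and at least one retained
   tag pair — the read sequence between the two anchors nearest the gap
   replaces the gap completely (no N left);
2. both flanks are anchored, but by different reads — each read contributes
   the sequence from its anchor toward the gap, joined by an N spacer:
   N = L_C - (extension_left + extension_right) when the reads do not meet,
   or a sentinel of exactly 100 N when they jointly over-span the gap,
   flagging a junction later iterations may confirm;
3. only one flank is anchored — the supporting read extends into the gap
   and the rest is padded with N (truncated to leave a 100-N sentinel when
   the read over-spans).

Tag pairs across a gap are retained when the read-distance to
scaffold-distance ratio lies strictly within 1 +/- c. Reverse-orientation
reads are canonicalized by reverse complement (p' = L - p - tag_len) so all
extension and fill arithmetic runs in a forward frame.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

from ._util import revcomp
from .align_filter import TagAnchor
from .assembly_io import Gap, Scaffold
from .tiling import LongRead

SENTINEL_N = 100  # N run flagging an unverified junction


def canonical_p(anchor: TagAnchor, read_len: int) -> int:
    """Read offset of the anchor tag in the forward (canonicalized) frame."""
    if anchor.record.orientation == "+":
        return anchor.tag.p
    return read_len - anchor.tag.p - anchor.tag.tag_len


def canonical_seq(read: LongRead, orientation: str) -> str:
    return read.sequence if orientation == "+" else revcomp(read.sequence)


@dataclass
class BoundarySupport:
    """One read's anchoring evidence at one side of a gap."""

    gap: Gap
    side: str  # "left" | "right"
    read_id: str
    orientation: str
    anchors: list[TagAnchor]
    nearest: TagAnchor
    slack: int  # scaffold bases between the nearest anchor and the gap edge
    extension: int  # read bases protruding past the nearest anchor into the gap

    @property
    def tag_count(self) -> int:
        return len(self.anchors)

    @property
    def proportion(self) -> float:
        return min(self.extension / self.gap.length, 1.0)


@dataclass
class TagPair:
    """Two tags of one read anchored on opposite sides of a gap."""

    a: TagAnchor
    b: TagAnchor
    ratio: Fraction
    retained: bool


@dataclass
class ClosureResult:
    """A single gap edit: scaffold interval [start, end) replaced by ``fill``."""

    gap: Gap
    gap_type: int  # 1 | 2 | 3
    start: int
    end: int
    fill: str
    source_reads: tuple[str, ...] = field(default_factory=tuple)

    @property
    def inserted_n(self) -> int:
        return self.fill.count("N")

    @property
    def status(self) -> str:
        return "closed" if self.inserted_n == 0 else "partial"


def collect_boundary_support(
    gap: Gap,
    anchors: Sequence[TagAnchor],
    reads_by_id: Mapping[str, LongRead],
    window: int,
    min_tag_count: int,
) -> tuple[list[BoundarySupport], list[BoundarySupport]]:
    """Per-read support at each side of ``gap``.

    A read supports the left side when at least ``min_tag_count`` of its
    retained anchors have alignments ending within ``window`` bases of the
    gap start (symmetrically, starting within ``window`` of the gap end for
    the right side). Extension is measured from the anchor nearest the gap
    in the read's canonical frame.
    """
    left_by_read: dict[str, list[TagAnchor]] = defaultdict(list)
    right_by_read: dict[str, list[TagAnchor]] = defaultdict(list)
    for a in anchors:
        rec = a.record
        if gap.start - window <= rec.end <= gap.start:
            left_by_read[a.tag.read_id].append(a)
        if gap.end <= rec.start <= gap.end + window:
            right_by_read[a.tag.read_id].append(a)

    def build(side: str, by_read: dict[str, list[TagAnchor]]) -> list[BoundarySupport]:
        out = []
        for read_id in sorted(by_read):
            group = by_read[read_id]
            if len(group) < min_tag_count:
                continue
            read = reads_by_id[read_id]
            if side == "left":
                nearest = max(group, key=lambda a: (a.record.end, a.record.start))
                slack = gap.start - nearest.record.end
                pc = canonical_p(nearest, read.length)
                tail = read.length - pc - nearest.tag.tag_len
                ext = max(0, tail - slack)
            else:
                nearest = min(group, key=lambda a: (a.record.start, a.record.end))
                slack = nearest.record.start - gap.end
                pc = canonical_p(nearest, read.length)
                ext = max(0, pc - slack)
            out.append(
                BoundarySupport(
                    gap, side, read_id, nearest.record.orientation, group, nearest, slack, ext
                )
            )
        return out

    return build("left", left_by_read), build("right", right_by_read)


def pair_tags(
    left: BoundarySupport,
    right: BoundarySupport,
    read: LongRead,
    c: float = 0.2,
) -> list[TagPair]:
    """Enumerate cross-boundary tag pairs of one read and apply the ratio test.

    A pair (a, b) is retained iff 1 - c < (p_b - p_a)/(O_b - O_a) < 1 + c
    with strict inequalities, distances taken in the canonical frame.
    """
    lo, hi = 1 - Fraction(str(c)), 1 + Fraction(str(c))
    pairs = []
    for a in left.anchors:
        for b in right.anchors:
            dp = canonical_p(b, read.length) - canonical_p(a, read.length)
            do = b.record.start - a.record.start
            if do <= 0 or dp <= 0:
                continue
            ratio = Fraction(dp, do)
            pairs.append(TagPair(a, b, ratio, lo < ratio < hi))
    return pairs


def select_spanning_read(
    pair_counts: Mapping[str, int],
    reads_by_id: Mapping[str, LongRead],
) -> str | None:
    """Read with the most retained tag pairs; ties go to the longer read,
    then the lexicographically smaller id."""
    candidates = [rid for rid, n in pair_counts.items() if n > 0]
    if not candidates:
        return None
    return min(
        candidates,
        key=lambda rid: (-pair_counts[rid], -reads_by_id[rid].length, rid),
    )


def close_type1(
    gap: Gap,
    read: LongRead,
    pairs: Sequence[TagPair],
) -> ClosureResult:
    """Fill the gap with one read's sequence between its two anchors nearest
    the boundaries; no N remains."""
    retained = [p for p in pairs if p.retained]
    if not retained:
        raise ValueError("type-1 closure requires at least one retained pair")
    left_tags = {id(p.a): p.a for p in retained}
    right_tags = {id(p.b): p.b for p in retained}
    left = max(left_tags.values(), key=lambda a: (a.record.end, a.record.start))
    right = min(right_tags.values(), key=lambda a: (a.record.start, a.record.end))
    if left.record.end > gap.start or right.record.start < gap.end:
        raise ValueError("anchor overlaps the gap N run")
    orientation = left.record.orientation
    canon = canonical_seq(read, orientation)
    pa = canonical_p(left, read.length)
    pb = canonical_p(right, read.length)
    fill = canon[pa + left.tag.tag_len : pb]
    return ClosureResult(
        gap, 1, left.record.end, right.record.start, fill, (read.id,)
    )


def close_type2(
    gap: Gap,
    left: BoundarySupport,
    right: BoundarySupport,
    reads_by_id: Mapping[str, LongRead],
) -> ClosureResult | None:
    """Join two reads' flank extensions across the gap with an N spacer.

    Spacer = L_C - (ext_left + ext_right) when the reads do not meet, else
    exactly the 100-N sentinel. Returns None when neither read actually
    protrudes into the gap.
    """
    ext_a, ext_b = left.extension, right.extension
    if ext_a + ext_b == 0:
        return None
    read_a = reads_by_id[left.read_id]
    read_b = reads_by_id[right.read_id]
    canon_a = canonical_seq(read_a, left.orientation)
    canon_b = canonical_seq(read_b, right.orientation)
    pa = canonical_p(left.nearest, read_a.length)
    pb = canonical_p(right.nearest, read_b.length)
    fill_a = canon_a[pa + left.nearest.tag.tag_len :]
    fill_b = canon_b[:pb]
    if ext_a + ext_b < gap.length:
        spacer = gap.length - ext_a - ext_b
    else:
        spacer = SENTINEL_N
    fill = fill_a + "N" * spacer + fill_b
    return ClosureResult(
        gap, 2, left.nearest.record.end, right.nearest.record.start, fill,
        (read_a.id, read_b.id),
    )


def close_type3(
    gap: Gap,
    support: BoundarySupport,
    reads_by_id: Mapping[str, LongRead],
) -> ClosureResult | None:
    """Extend one read from its anchor into the gap; pad the rest with N.

    When the read over-spans the gap the fill is truncated so that a 100-N
    sentinel remains: a one-sided extension never fabricates a verified
    junction. Zero extension emits no edit.
    """
    ext = support.extension
    if ext == 0:
        return None
    read = reads_by_id[support.read_id]
    canon = canonical_seq(read, support.orientation)
    pc = canonical_p(support.nearest, read.length)
    slack = support.slack
    if support.side == "left":
        tail = canon[pc + support.nearest.tag.tag_len :]
        if ext < gap.length:
            fill = tail + "N" * (gap.length - ext)
        else:
            fill = tail[: slack + gap.length - SENTINEL_N] + "N" * SENTINEL_N
        start, end = support.nearest.record.end, gap.end
    else:
        head = canon[:pc]
        if ext < gap.length:
            fill = "N" * (gap.length - ext) + head
        else:
            fill = "N" * SENTINEL_N + head[-(slack + gap.length - SENTINEL_N) :]
        start, end = gap.start, support.nearest.record.start
    return ClosureResult(gap, 3, start, end, fill, (read.id,))


def _best_support(supports: Sequence[BoundarySupport]) -> BoundarySupport:
    # largest gap proportion covered; ties to more tags, then read id
    return min(supports, key=lambda s: (-s.extension, -s.tag_count, s.read_id))


def classify_and_close(
    gap: Gap,
    left_supports: Sequence[BoundarySupport],
    right_supports: Sequence[BoundarySupport],
    reads_by_id: Mapping[str, LongRead],
    c: float = 0.2,
) -> ClosureResult | None:
    """Apply the type precedence (1, then 2, then 3) to one gap."""
    left_by_read = {s.read_id: s for s in left_supports}
    right_by_read = {s.read_id: s for s in right_supports}

    # type 1: a single read anchored at both boundaries with retained pairs
    spanning = sorted(set(left_by_read) & set(right_by_read))
    pair_counts: dict[str, int] = {}
    pairs_by_read: dict[str, list[TagPair]] = {}
    for rid in spanning:
        pairs = pair_tags(left_by_read[rid], right_by_read[rid], reads_by_id[rid], c)
        pairs_by_read[rid] = pairs
        pair_counts[rid] = sum(1 for p in pairs if p.retained)
    chosen = select_spanning_read(pair_counts, reads_by_id)
    if chosen is not None:
        return close_type1(gap, reads_by_id[chosen], pairs_by_read[chosen])

    # type 2: both boundaries anchored, by different reads
    if left_supports and right_supports:
        best_left = _best_support(left_supports)
        best_right = _best_support(right_supports)
        if best_left.read_id == best_right.read_id:
            alt_left = [s for s in left_supports if s.read_id != best_right.read_id]
            alt_right = [s for s in right_supports if s.read_id != best_left.read_id]
            options = []
            if alt_right:
                options.append((best_left, _best_support(alt_right)))
            if alt_left:
                options.append((_best_support(alt_left), best_right))
            if options:
                # first option wins ties (replace the right-side read first)
                best_left, best_right = max(
                    options, key=lambda lr: lr[0].extension + lr[1].extension
                )
            else:
                # one read only: demote to a one-sided (type 3) closure
                side = best_left if best_left.extension >= best_right.extension else best_right
                return close_type3(gap, side, reads_by_id)
        result = close_type2(gap, best_left, best_right, reads_by_id)
        if result is not None:
            return result

    # type 3: one boundary anchored
    one_sided = list(left_supports) + list(right_supports)
    if one_sided:
        return close_type3(gap, _best_support(one_sided), reads_by_id)
    return None


def apply_closures(
    scaffolds: Sequence[Scaffold],
    results: Sequence[ClosureResult],
) -> list[Scaffold]:
    """Apply gap edits, right-to-left per scaffold so coordinates stay valid.

    Replaced intervals within one scaffold must be pairwise disjoint; bases
    outside them are untouched and scaffold count/order is preserved.
    """
    by_scaffold: dict[str, list[ClosureResult]] = defaultdict(list)
    for res in results:
        by_scaffold[res.gap.scaffold_id].append(res)
    out = []
    for sc in scaffolds:
        edits = sorted(by_scaffold.get(sc.id, []), key=lambda r: r.start)
        for prev, nxt in zip(edits, edits[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping replacement intervals on {sc.id}")
        seq = sc.sequence
        for res in reversed(edits):
            if not (0 <= res.start <= res.end <= len(seq)):
                raise ValueError(f"replacement interval out of bounds on {sc.id}")
            seq = seq[: res.start] + res.fill + seq[res.end :]
        out.append(Scaffold(sc.id, seq))
    return out


def total_n_count(scaffolds: Sequence[Scaffold]) -> int:
    return sum(sc.sequence.count("N") for sc in scaffolds)
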