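"""Alignment coverage scoring and the three anchor-refinement filters.

Tag alignments are scored by coverage = (match bases + inserted bases) /
tag length and thresholded. Surviving tags are classified by multiplicity:
type 1 (a single candidate locus) and type 2 (two or more loci). Type-1
anchors of each read are refined per scaffold by an orientation majority
vote and an order-consistency check against the median tag; type-2 tags are
then rescued by their neighbouring type-1 anchors when scaffold,
orientation, relative order and read-vs-scaffold distance all agree.

Scaffold order for reverse-orientation anchor groups is compared on negated
positions, so "consistent" means anti-collinear on the reverse strand.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .assembly_io import TagAlignmentRecord
from .tiling import Tag

TYPE1 = "type1"
TYPE2 = "type2"


@dataclass
class CoverageScore:
    """Fraction of a tag explained by the alignment; may exceed 1 for long
    insertions (one-sided filter, never clamped)."""

    value: Fraction

    def __float__(self) -> float:
        return float(self.value)


@dataclass
class TagAnchor:
    """A tag together with its (chosen) alignment locus."""

    tag: Tag
    record: TagAlignmentRecord
    multiplicity: str = TYPE1


def compute_coverage(record: TagAlignmentRecord, tag_len: int) -> CoverageScore:
    if tag_len <= 0:
        raise ValueError("tag_len must be positive")
    return CoverageScore(Fraction(record.match_len + record.insert_len, tag_len))


def filter_by_coverage(
    records: Iterable[TagAlignmentRecord],
    tag_len: int,
    threshold: float = 0.8,
) -> list[TagAlignmentRecord]:
    """Keep records with coverage >= ``threshold`` (inclusive), order preserved.

    The comparison is exact: the coverage fraction is rational and the
    threshold is interpreted via its decimal representation.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cut = Fraction(str(threshold))
    return [r for r in records if compute_coverage(r, tag_len).value >= cut]


def classify_by_multiplicity(
    records: Iterable[TagAlignmentRecord],
    tags_by_id: Mapping[str, Tag],
) -> tuple[list[TagAnchor], dict[str, list[TagAlignmentRecord]]]:
    """Split coverage-filtered records into unique anchors and multi-mappers.

    Returns ``(type1_anchors, type2_candidates)`` where the latter maps
    tag id to its >=2 candidate loci. Tags with zero surviving loci are
    simply absent.
    """
    by_tag: dict[str, list[TagAlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_tag[rec.tag_id].append(rec)
    anchors: list[TagAnchor] = []
    multi: dict[str, list[TagAlignmentRecord]] = {}
    for tag_id, recs in by_tag.items():
        if len(recs) == 1:
            anchors.append(TagAnchor(tags_by_id[tag_id], recs[0], TYPE1))
        else:
            multi[tag_id] = recs
    return anchors, multi


def orientation_filter(anchors: Sequence[TagAnchor]) -> list[TagAnchor]:
    """Majority vote on alignment orientation within one (read, scaffold) group.

    A tie means the whole group is unreliable and is removed; otherwise only
    the majority orientation survives.
    """
    fwd = sum(1 for a in anchors if a.record.orientation == "+")
    rev = len(anchors) - fwd
    if fwd == rev:
        return []
    keep = "+" if fwd > rev else "-"
    return [a for a in anchors if a.record.orientation == keep]


def _scaffold_key(anchor: TagAnchor) -> int:
    # negate reverse-strand positions so collinearity is one comparison
    return anchor.record.start if anchor.record.orientation == "+" else -anchor.record.start


def order_filter(anchors: Sequence[TagAnchor]) -> list[TagAnchor]:
    """Order-consistency filter for a single-orientation anchor group.

    With two anchors, both are kept iff their read order matches their
    (orientation-adjusted) scaffold order. With three or more, the tag at
    the median read position is the reference (lower median on ties) and is
    always kept; every other anchor is kept iff it lies on the same side of
    the reference on the read and on the scaffold.
    """
    if len(anchors) <= 1:
        return list(anchors)
    ordered = sorted(anchors, key=lambda a: a.tag.p)
    if len(ordered) == 2:
        a, b = ordered
        if _scaffold_key(a) < _scaffold_key(b):
            return ordered
        return []
    ref = ordered[(len(ordered) - 1) // 2]
    ref_key = _scaffold_key(ref)
    kept = []
    for a in ordered:
        if a is ref:
            kept.append(a)
            continue
        if a.tag.p < ref.tag.p and _scaffold_key(a) < ref_key:
            kept.append(a)
        elif a.tag.p > ref.tag.p and _scaffold_key(a) > ref_key:
            kept.append(a)
    return kept


def rescue_multimapped(
    tag: Tag,
    candidates: Sequence[TagAlignmentRecord],
    read_anchors: Sequence[TagAnchor],
    c: float = 0.2,
) -> TagAnchor | None:
    """Resolve a multi-mapping (type 2) tag via its neighbouring type-1 anchors.

    The nearest retained type-1 anchors on each side of the tag (by read
    offset) define the expected scaffold and orientation; a candidate locus
    survives only if it matches both, lies on the correct side of each
    neighbour, and its read-vs-scaffold distance ratio to each neighbour is
    strictly within 1 +/- ``c``. Exactly one survivor is required; ties or
    disagreeing neighbours yield no rescue.
    """
    left = max(
        (a for a in read_anchors if a.tag.p < tag.p),
        key=lambda a: a.tag.p,
        default=None,
    )
    right = min(
        (a for a in read_anchors if a.tag.p > tag.p),
        key=lambda a: a.tag.p,
        default=None,
    )
    neighbors = [a for a in (left, right) if a is not None]
    if not neighbors:
        return None
    scaffold = neighbors[0].record.scaffold_id
    orientation = neighbors[0].record.orientation
    if any(
        a.record.scaffold_id != scaffold or a.record.orientation != orientation
        for a in neighbors
    ):
        return None

    survivors = []
    for cand in candidates:
        if cand.scaffold_id != scaffold or cand.orientation != orientation:
            continue
        ok = True
        for nb in neighbors:
            dp = tag.p - nb.tag.p
            dk = (cand.start if orientation == "+" else -cand.start) - _scaffold_key(nb)
            if dk == 0 or (dp > 0) != (dk > 0):
                ok = False
                break
            ratio = Fraction(abs(dp), abs(dk))
            if not (1 - Fraction(str(c)) < ratio < 1 + Fraction(str(c))):
                ok = False
                break
        if ok:
            survivors.append(cand)
    if len(survivors) != 1:
        return None
    return TagAnchor(tag, survivors[0], TYPE2)


def refine_anchors(
    records: Sequence[TagAlignmentRecord],
    tags_by_id: Mapping[str, Tag],
    c: float = 0.2,
) -> list[TagAnchor]:
    """Full refinement: multiplicity split, orientation vote, order check,
    then multi-mapper rescue. Returns all retained anchors.

    The orientation vote and order check run per (read, scaffold) group;
    only type-1 anchors serve as rescue neighbours.
    """
    type1, multi = classify_by_multiplicity(records, tags_by_id)

    groups: dict[tuple[str, str], list[TagAnchor]] = defaultdict(list)
    for a in type1:
        groups[(a.tag.read_id, a.record.scaffold_id)].append(a)

    retained: list[TagAnchor] = []
    by_read: dict[str, list[TagAnchor]] = defaultdict(list)
    for key in sorted(groups):
        kept = order_filter(orientation_filter(groups[key]))
        retained.extend(kept)
        by_read[key[0]].extend(kept)

    for tag_id in sorted(multi):
        tag = tags_by_id[tag_id]
        rescued = rescue_multimapped(tag, multi[tag_id], by_read[tag.read_id], c)
        if rescued is not None:
            retained.append(rescued)
    return retained
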