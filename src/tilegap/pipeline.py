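"""Orchestration of the iterate-align-filter-close loop.

One iteration fragments the reads into tags, aligns them to the current
assembly, applies the coverage / orientation / order / rescue filters,
classifies every gap and applies the resulting edits. The loop repeats up
to ``Config.iterations`` times, stopping early when an iteration fills no
bases; partially closed gaps (types 2 and 3) leave residual N runs that are
rediscovered and may be completed as type 1 in a later pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .align_filter import filter_by_coverage, refine_anchors
from .aligner import Aligner
from .assembly_io import Gap, GapReportRow, Scaffold, find_gaps
from .closure import (
    ClosureResult,
    apply_closures,
    classify_and_close,
    collect_boundary_support,
    total_n_count,
)
from .tiling import LongRead, fragment_reads

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """Tunable parameters of the closure pipeline.

    ``tag_len`` (bases) is the tag size of the tiling path; ``min_coverage``
    the alignment-retention score threshold; ``min_tag_count`` the minimum
    anchored tags per gap boundary; ``max_deviation`` the c of the tag-pair
    ratio test; ``boundary_window`` (bases) how far from a gap edge an
    anchor still counts as boundary support.
    """

    tag_len: int = 300
    min_coverage: float = 0.8
    min_tag_count: int = 5
    max_deviation: float = 0.2
    boundary_window: int = 5_000
    min_gap_len: int = 1
    iterations: int = 3
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tag_len <= 0 or self.min_tag_count <= 0 or self.boundary_window <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.max_deviation < 1:
            raise ValueError("max_deviation must lie in (0, 1)")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.boundary_window < self.tag_len:
            raise ValueError("boundary_window must be at least tag_len")


@dataclass
class IterationResult:
    scaffolds: list[Scaffold]
    closures: list[ClosureResult]
    rows: list[GapReportRow]
    bases_filled: int


@dataclass
class PipelineResult:
    scaffolds: list[Scaffold]
    rows: list[GapReportRow]
    iterations_run: int
    bases_filled: int
    gaps_before: int
    gaps_after: int

    def summary(self) -> dict[str, object]:
        return {
            "iterations_run": self.iterations_run,
            "gaps_before": self.gaps_before,
            "gaps_after": self.gaps_after,
            "gaps_closed": self.gaps_before - self.gaps_after,
            "bases_filled": self.bases_filled,
        }


def _resolve_overlaps(
    results: Sequence[ClosureResult],
) -> tuple[list[ClosureResult], list[ClosureResult]]:
    """Greedily keep non-overlapping edits per scaffold (left to right);
    overlapped edits are deferred to the next iteration."""
    kept: list[ClosureResult] = []
    deferred: list[ClosureResult] = []
    by_scaffold: dict[str, list[ClosureResult]] = {}
    for res in results:
        by_scaffold.setdefault(res.gap.scaffold_id, []).append(res)
    for sid in sorted(by_scaffold):
        last_end = -1
        for res in sorted(by_scaffold[sid], key=lambda r: r.start):
            if res.start >= last_end:
                kept.append(res)
                last_end = res.end
            else:
                deferred.append(res)
    return kept, deferred


def run_iteration(
    scaffolds: Sequence[Scaffold],
    reads: Sequence[LongRead],
    config: Config,
    aligner: Aligner,
    iteration: int = 1,
) -> IterationResult:
    """One full align-filter-close pass over the current assembly."""
    gaps_by_scaffold: dict[str, list[Gap]] = {
        sc.id: find_gaps(sc, config.min_gap_len) for sc in scaffolds
    }
    n_gaps = sum(len(g) for g in gaps_by_scaffold.values())
    if n_gaps == 0:
        return IterationResult(list(scaffolds), [], [], 0)

    tags = fragment_reads(reads, config.tag_len)
    tags_by_id = {t.id: t for t in tags}
    reads_by_id = {r.id: r for r in reads}

    records = aligner.align(tags, scaffolds) if tags else []
    records = filter_by_coverage(records, config.tag_len, config.min_coverage)
    anchors = refine_anchors(records, tags_by_id, config.max_deviation)
    anchors_by_scaffold: dict[str, list] = {}
    for a in anchors:
        anchors_by_scaffold.setdefault(a.record.scaffold_id, []).append(a)

    candidates: list[ClosureResult] = []
    typed: dict[tuple[str, int, int], int] = {}
    for sc in scaffolds:
        for gap in gaps_by_scaffold[sc.id]:
            left, right = collect_boundary_support(
                gap,
                anchors_by_scaffold.get(sc.id, []),
                reads_by_id,
                config.boundary_window,
                config.min_tag_count,
            )
            result = classify_and_close(
                gap, left, right, reads_by_id, config.max_deviation
            )
            if result is not None:
                typed[(sc.id, gap.start, gap.end)] = result.gap_type
                candidates.append(result)

    kept, deferred = _resolve_overlaps(candidates)
    for res in deferred:
        logger.info(
            "deferring overlapping closure of %s:%d-%d to the next iteration",
            res.gap.scaffold_id, res.gap.start, res.gap.end,
        )
    n_before = total_n_count(scaffolds)
    new_scaffolds = apply_closures(scaffolds, kept)
    bases_filled = n_before - total_n_count(new_scaffolds)

    applied = {(r.gap.scaffold_id, r.gap.start, r.gap.end): r for r in kept}
    rows = []
    for sc in scaffolds:
        for gap in gaps_by_scaffold[sc.id]:
            key = (sc.id, gap.start, gap.end)
            res = applied.get(key)
            if res is not None:
                rows.append(
                    GapReportRow(
                        sc.id, gap.start, gap.end, gap.length, iteration,
                        str(res.gap_type), res.status, len(res.fill),
                        res.inserted_n, res.source_reads,
                    )
                )
                logger.info(
                    "iter %d %s:%d-%d type %d -> %s (fill %d, N %d, reads %s)",
                    iteration, sc.id, gap.start, gap.end, res.gap_type,
                    res.status, len(res.fill), res.inserted_n,
                    ",".join(res.source_reads),
                )
            else:
                gap_type = typed.get(key)
                rows.append(
                    GapReportRow(
                        sc.id, gap.start, gap.end, gap.length, iteration,
                        str(gap_type) if gap_type else "none", "open",
                    )
                )
    return IterationResult(new_scaffolds, kept, rows, bases_filled)


def run_pipeline(
    scaffolds: Sequence[Scaffold],
    reads: Sequence[LongRead],
    config: Config,
    aligner: Aligner,
) -> PipelineResult:
    """Iterate gap closure until done, no progress, or the iteration budget.

    A non-iterative aligner (precomputed SAM) supports a single pass, since
    its coordinates refer to the input assembly only.
    """
    current = list(scaffolds)
    all_rows: list[GapReportRow] = []
    gaps_before = sum(len(find_gaps(sc, config.min_gap_len)) for sc in current)
    filled_total = 0
    iterations_run = 0
    max_iter = config.iterations if aligner.iterative else 1
    for it in range(1, max_iter + 1):
        result = run_iteration(current, reads, config, aligner, iteration=it)
        iterations_run = it
        all_rows.extend(result.rows)
        filled_total += result.bases_filled
        current = result.scaffolds
        logger.info(
            "iteration %d: %d closures applied, %d bases filled",
            it, len(result.closures), result.bases_filled,
        )
        if result.bases_filled == 0 and not result.closures:
            break
    gaps_after = sum(len(find_gaps(sc, config.min_gap_len)) for sc in current)
    return PipelineResult(
        current, all_rows, iterations_run, filled_total, gaps_before, gaps_after
    )
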