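"""Synthetic genomes, gapped assemblies, long reads, and truth-based scoring.

The generator emulates the study conditions the closure pipeline targets:
a random genome, optionally with planted exact repeat copies; a gapped
derivative in which either random intervals or the planted repeats are
replaced by equal-length N runs (so every gap has a known truth sequence);
and long reads drawn uniformly from the genome with configurable
substitution / insertion / deletion error rates, both strands equiprobable,
lengths log-normal around a 10 kb mean. Everything is deterministic per
seed.

``evaluate_closure`` scores a closed assembly against the truth: each gap
locus is re-located via its flanking sequence (approximate infix alignment,
robust to small boundary rewrites), and the recovered sequence is compared
to the removed truth by global pairwise alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import edlib
import numpy as np

from ._util import revcomp
from .assembly_io import Scaffold
from .tiling import LongRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthRecord:
    """The sequence removed to create one gap, with its coordinates in the
    gapped assembly (which equal its coordinates in the truth genome)."""

    scaffold_id: str
    start: int
    end: int
    sequence: str
    origin: str = "random"  # random | repeat

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadErrorModel:
    """Per-base error probabilities and read-length distribution.

    ``mean_len`` is the target mean read length; lengths are log-normal
    with shape ``sigma`` and clamped to [min_len, genome length].
    """

    substitution: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    mean_len: int = 10_000
    sigma: float = 0.55
    min_len: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.substitution, self.insertion, self.deletion)
        if any(not 0 <= r < 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must lie in [0, 1) and sum below 1")

    @property
    def total_error(self) -> float:
        return self.substitution + self.insertion + self.deletion


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_genome(
    length: int,
    repeat_unit_len: int = 0,
    repeat_copies: int = 0,
    seed: int = 0,
    min_separation: int = 100,
) -> tuple[str, list[tuple[int, int]]]:
    """Random genome with ``repeat_copies`` planted exact copies of one unit.

    Copies are non-overlapping, separated by at least ``min_separation``
    bases and kept away from the sequence ends. Returns the genome and the
    repeat coordinate list (0-based, half-open).
    """
    rng = np.random.default_rng(seed)
    genome = _random_seq(rng, length)
    if repeat_copies == 0 or repeat_unit_len == 0:
        return genome, []
    slots = repeat_copies * repeat_unit_len + (repeat_copies + 1) * min_separation
    if slots > length:
        raise ValueError("repeat copies do not fit into the genome")
    unit = _random_seq(rng, repeat_unit_len)
    spare = length - slots
    cuts = np.sort(rng.integers(0, spare + 1, repeat_copies))
    coords = []
    out = list(genome)
    for i in range(repeat_copies):
        start = min_separation + int(cuts[i]) + i * (repeat_unit_len + min_separation)
        out[start : start + repeat_unit_len] = unit
        coords.append((start, start + repeat_unit_len))
    return "".join(out), coords


def introduce_gaps(
    genome: str,
    strategy: str = "random",
    *,
    n_gaps: int = 20,
    gap_len_range: tuple[int, int] = (200, 2_000),
    repeat_coords: Sequence[tuple[int, int]] | None = None,
    min_repeat_len: int = 200,
    seed: int = 0,
    scaffold_id: str = "scaffold1",
) -> tuple[Scaffold, list[TruthRecord]]:
    """Derive a gapped assembly by replacing intervals with equal-length N runs.

    ``random`` places ``n_gaps`` non-overlapping gaps with lengths uniform in
    ``gap_len_range``, keeping at least one non-N base between gaps and at
    the ends. ``repeat`` replaces every planted repeat of length >=
    ``min_repeat_len`` with an N run of the same length.
    """
    if strategy == "repeat":
        if repeat_coords is None:
            raise ValueError("repeat strategy requires repeat_coords")
        intervals = [(s, e) for s, e in repeat_coords if e - s >= min_repeat_len]
        origin = "repeat"
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        lo, hi = gap_len_range
        lengths = rng.integers(lo, hi + 1, n_gaps)
        spare = len(genome) - int(lengths.sum()) - (n_gaps + 1)
        if spare < 0:
            raise ValueError("requested gaps do not fit into the genome")
        cuts = np.sort(rng.integers(0, spare + 1, n_gaps))
        intervals = []
        pos = 0
        for i in range(n_gaps):
            start = pos + 1 + int(cuts[i]) - (int(cuts[i - 1]) if i else 0)
            intervals.append((start, start + int(lengths[i])))
            pos = start + int(lengths[i])
        origin = "random"
    else:
        raise ValueError(f"unknown gap strategy {strategy!r}")

    out = list(genome)
    records = []
    for start, end in intervals:
        records.append(TruthRecord(scaffold_id, start, end, genome[start:end], origin))
        out[start:end] = "N" * (end - start)
    return Scaffold(scaffold_id, "".join(out)), records


def restore_truth(scaffold: Scaffold, records: Sequence[TruthRecord]) -> Scaffold:
    """Put the removed sequences back; inverse of ``introduce_gaps``."""
    seq = list(scaffold.sequence)
    for r in records:
        if r.scaffold_id == scaffold.id:
            seq[r.start : r.end] = r.sequence
    return Scaffold(scaffold.id, "".join(seq))


def _apply_errors(seq: str, model: ReadErrorModel, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = len(arr)
    r = rng.random(n)
    sub_mask = r < model.substitution
    if sub_mask.any():
        # shift by 1..3 in base space so the substituted base always differs
        idx = {65: 0, 67: 1, 71: 2, 84: 3}
        codes = np.vectorize(idx.get)(arr[sub_mask])
        shift = rng.integers(1, 4, sub_mask.sum())
        arr[sub_mask] = _BASES[(codes + shift) % 4]
    del_mask = (r >= model.substitution) & (r < model.substitution + model.deletion)
    arr = arr[~del_mask]
    if model.insertion > 0 and len(arr) > 0:
        ins_mask = rng.random(len(arr)) < model.insertion
        pos = np.nonzero(ins_mask)[0]
        arr = np.insert(arr, pos + 1, _BASES[rng.integers(0, 4, len(pos))])
    return arr.tobytes().decode()


def simulate_long_reads(
    genome: str,
    coverage: float,
    model: ReadErrorModel | None = None,
) -> list[LongRead]:
    """Draw reads until total bases reach ``coverage`` times the genome length.

    Start positions are uniform, strands equiprobable, and errors applied
    per base according to the model.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    model = model or ReadErrorModel()
    rng = np.random.default_rng(model.seed)
    mu = np.log(model.mean_len) - model.sigma**2 / 2
    target = coverage * len(genome)
    reads: list[LongRead] = []
    total = 0
    i = 0
    while total < target:
        length = int(rng.lognormal(mu, model.sigma))
        length = max(model.min_len, min(length, len(genome)))
        start = int(rng.integers(0, len(genome) - length + 1))
        seq = genome[start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if model.total_error > 0:
            seq = _apply_errors(seq, model, rng)
        reads.append(LongRead(f"read{i:05d}", seq))
        total += len(seq)
        i += 1
    return reads


def write_reads(reads: Sequence[LongRead], path: str | Path, fmt: str = "fasta") -> None:
    """Write reads as FASTA or FASTQ (constant placeholder qualities)."""
    with open(path, "w") as out:
        for read in reads:
            if fmt == "fasta":
                out.write(f">{read.id}\n{read.sequence}\n")
            elif fmt == "fastq":
                out.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * read.length}\n")
            else:
                raise ValueError(f"unknown read format {fmt!r}")


def write_truth_records(records: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as out:
        w = csv.writer(out, delimiter="\t")
        w.writerow(["scaffold_id", "start", "end", "origin", "sequence"])
        for r in records:
            w.writerow([r.scaffold_id, r.start, r.end, r.origin, r.sequence])


def load_truth_records(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            records.append(
                TruthRecord(
                    row["scaffold_id"], int(row["start"]), int(row["end"]),
                    row["sequence"], row["origin"],
                )
            )
    return records


def contig_lengths(seq: str, min_len: int = 1) -> list[int]:
    """Lengths of maximal N-free runs of at least ``min_len`` bases."""
    return [len(run) for run in seq.split("N") if len(run) >= min_len]


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L hold half the total."""
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    return ordered[-1]


@dataclass
class GapEvaluation:
    record: TruthRecord
    status: str  # closed-exact | closed-with-differences | partial | open | unscored
    identity: float | None = None  # percent, for closed gaps


@dataclass
class ClosureEvaluation:
    per_gap: list[GapEvaluation]
    gaps_total: int
    gaps_closed: int
    bases_filled: int
    n50_before: int
    n50_after: int

    @property
    def closed_fraction(self) -> float:
        return self.gaps_closed / self.gaps_total if self.gaps_total else 0.0

    def summary(self) -> dict[str, object]:
        return {
            "gaps_total": self.gaps_total,
            "gaps_closed": self.gaps_closed,
            "bases_filled": self.bases_filled,
            "contig_N50_before": self.n50_before,
            "contig_N50_after": self.n50_after,
        }


def _locate(query: str, target: str) -> tuple[int, int] | None:
    res = edlib.align(query, target, mode="HW", task="locations")
    locs = res.get("locations") or []
    if not locs:
        return None
    start, end = locs[0]
    return start, end + 1  # half-open


def evaluate_closure(
    closed: Sequence[Scaffold],
    truth: Mapping[str, str],
    records: Sequence[TruthRecord],
    flank: int = 300,
    min_contig_len: int = 1,
) -> ClosureEvaluation:
    """Score a closed assembly against the truth genome.

    Each gap locus is found in the closed scaffold by approximate infix
    alignment of its truth flanks, then compared to the removed sequence by
    global pairwise alignment (identity in percent). A locus that is still
    an equal-length all-N run is open; any remaining N means partial.
    """
    closed_by_id = {sc.id: sc for sc in closed}
    per_gap = []
    for rec in sorted(records, key=lambda r: (r.scaffold_id, r.start)):
        truth_seq = truth[rec.scaffold_id]
        target = closed_by_id[rec.scaffold_id].sequence
        if rec.start < flank or rec.end + flank > len(truth_seq):
            per_gap.append(GapEvaluation(rec, "unscored"))
            continue
        left_q = truth_seq[rec.start - flank : rec.start]
        right_q = truth_seq[rec.end : rec.end + flank]
        left = _locate(left_q, target)
        if left is None:
            per_gap.append(GapEvaluation(rec, "unscored"))
            continue
        right = _locate(right_q, target[left[1] :])
        if right is None:
            per_gap.append(GapEvaluation(rec, "unscored"))
            continue
        region = target[left[1] : left[1] + right[0]]
        n_in_region = region.count("N")
        if n_in_region == len(region) == rec.length and rec.length > 0:
            per_gap.append(GapEvaluation(rec, "open"))
        elif n_in_region > 0:
            per_gap.append(GapEvaluation(rec, "partial"))
        else:
            if region == rec.sequence:
                per_gap.append(GapEvaluation(rec, "closed-exact", 100.0))
            else:
                dist = edlib.align(region, rec.sequence, mode="NW", task="distance")[
                    "editDistance"
                ]
                span = max(len(region), rec.length, 1)
                per_gap.append(
                    GapEvaluation(
                        rec, "closed-with-differences", 100.0 * (1 - dist / span)
                    )
                )

    gapped_n = sum(r.length for r in records)
    closed_n = sum(sc.sequence.count("N") for sc in closed)
    before_lengths: list[int] = []
    for sid in sorted({r.scaffold_id for r in records} | set(closed_by_id)):
        seq = list(truth[sid])
        for r in records:
            if r.scaffold_id == sid:
                seq[r.start : r.end] = "N" * r.length
        before_lengths.extend(contig_lengths("".join(seq), min_contig_len))
    after_lengths = []
    for sc in closed:
        after_lengths.extend(contig_lengths(sc.sequence, min_contig_len))
    closed_count = sum(1 for g in per_gap if g.status.startswith("closed"))
    return ClosureEvaluation(
        per_gap=per_gap,
        gaps_total=len(records),
        gaps_closed=closed_count,
        bases_filled=gapped_n - closed_n,
        n50_before=n50(before_lengths),
        n50_after=n50(after_lengths),
    )
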