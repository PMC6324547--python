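"""Assembly and alignment I/O.

Reads and writes scaffold FASTA, discovers gaps as maximal runs of 'N',
parses tag-to-scaffold alignments from SAM, and emits per-gap TSV reports.

All coordinates are 0-based, half-open. SAM input (1-based) is converted at
the parser boundary and never leaks into the rest of the package.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

_VALID_CHARS = frozenset("ACGTN")
_N_RUN = re.compile(r"N+")

# CIGAR operation codes (pysam numeric encoding)
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S = 0, 1, 2, 3, 4
_CIG_EQ, _CIG_X = 7, 8
_ALIGNED_OPS = (_CIG_M, _CIG_EQ, _CIG_X)
_REF_OPS = (_CIG_M, _CIG_EQ, _CIG_X, _CIG_D, _CIG_N)


@dataclass
class Scaffold:
    """A named assembly sequence over {A,C,G,T,N}, upper case."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Gap:
    """A maximal run of 'N' inside a scaffold (0-based, half-open)."""

    scaffold_id: str
    start: int
    end: int
    terminal: bool = False
    status: str = "open"  # open | partial | closed

    @property
    def length(self) -> int:
        """Gap length L_C in bases."""
        return self.end - self.start


@dataclass
class TagAlignmentRecord:
    """One alignment of a fixed-length tag to a scaffold.

    ``match_len`` counts identical bases between tag and scaffold;
    ``insert_len`` counts tag bases inserted relative to the scaffold;
    ``ref_span`` is the scaffold span consumed by the alignment.
    """

    tag_id: str
    scaffold_id: str
    start: int  # 0-based scaffold start, O(.)
    orientation: str  # "+" | "-"
    match_len: int
    insert_len: int
    ref_span: int
    mapq: int = 0
    secondary: bool = False

    @property
    def end(self) -> int:
        return self.start + self.ref_span

    @property
    def read_id(self) -> str:
        return self.tag_id.rsplit("#", 1)[0]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_assembly(path: str | Path) -> list[Scaffold]:
    """Load scaffolds from a (optionally gzipped) FASTA file.

    Sequences are upper-cased; order of the file is preserved. Raises
    ``ValueError`` on an empty file, duplicate record ids, or characters
    outside {A,C,G,T,N}.
    """
    from Bio import SeqIO

    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate scaffold id {record.id!r} in {path}")
            seen.add(record.id)
            seq = str(record.seq).upper()
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(
                    f"scaffold {record.id!r} contains invalid characters {sorted(bad)}"
                )
            if not seq:
                raise ValueError(f"scaffold {record.id!r} has an empty sequence")
            scaffolds.append(Scaffold(record.id, seq))
    if not scaffolds:
        raise ValueError(f"no FASTA records found in {path}")
    return scaffolds


def find_gaps(scaffold: Scaffold, min_gap_len: int = 1) -> list[Gap]:
    """All maximal N runs of length >= ``min_gap_len``, sorted by start.

    Terminal runs (touching either scaffold end) are flagged; they can only
    ever be extended from one side.
    """
    if min_gap_len < 1:
        raise ValueError("min_gap_len must be >= 1")
    gaps = []
    for m in _N_RUN.finditer(scaffold.sequence):
        if m.end() - m.start() >= min_gap_len:
            terminal = m.start() == 0 or m.end() == scaffold.length
            gaps.append(Gap(scaffold.id, m.start(), m.end(), terminal=terminal))
    return gaps


def _mismatches_from_md(md: str) -> int:
    # substitution letters in an MD string, excluding deletion runs (^...)
    return sum(1 for m in re.finditer(r"(\^[A-Z]+)|([A-Z])", md) if m.group(2))


def parse_tag_alignments(
    source: str | Path | IO[str],
    tag_lengths: Mapping[str, int] | None = None,
    scaffold_ids: Iterable[str] | None = None,
) -> list[TagAlignmentRecord]:
    """Parse tag alignments from a SAM stream or path.

    Unmapped records are dropped; secondary/supplementary records are kept
    as extra candidate loci for multiplicity classification. Mismatches are
    derived from the NM tag (NM minus inserted minus deleted bases) or, if
    only MD is present, by counting its substitution letters; records with
    neither tag are skipped with a warning.
    """
    known = set(scaffold_ids) if scaffold_ids is not None else None
    records: list[TagAlignmentRecord] = []
    tmp_path: str | None = None
    if hasattr(source, "read"):  # buffer text streams for htslib
        import tempfile

        with tempfile.NamedTemporaryFile(
            "w", suffix=".sam", delete=False
        ) as tmp:
            tmp.write(source.read())
            source = tmp_path = tmp.name
    save = pysam.set_verbosity(0)
    try:
        sam = pysam.AlignmentFile(source, "r", check_sq=False)
    finally:
        pysam.set_verbosity(save)
    try:
        with sam:
            for aln in sam:
                rec = _record_from_alignment(aln, known, tag_lengths)
                if rec is not None:
                    records.append(rec)
    finally:
        if tmp_path is not None:
            Path(tmp_path).unlink(missing_ok=True)
    return records


def _record_from_alignment(aln, known, tag_lengths) -> TagAlignmentRecord | None:
    if aln.is_unmapped:
        return None
    ref = aln.reference_name
    if known is not None and ref not in known:
        raise ValueError(f"alignment references unknown scaffold {ref!r}")
    cig = aln.cigartuples or []
    aligned = sum(n for op, n in cig if op in _ALIGNED_OPS)
    ins = sum(n for op, n in cig if op == _CIG_I)
    dele = sum(n for op, n in cig if op == _CIG_D)
    ref_span = sum(n for op, n in cig if op in _REF_OPS)
    if aln.has_tag("NM"):
        mismatches = max(0, aln.get_tag("NM") - ins - dele)
    elif aln.has_tag("MD"):
        mismatches = _mismatches_from_md(str(aln.get_tag("MD")))
    else:
        logger.warning(
            "skipping %s: no NM or MD tag to derive match length", aln.query_name
        )
        return None
    if tag_lengths is not None and aln.query_name not in tag_lengths:
        raise ValueError(f"alignment for unknown tag {aln.query_name!r}")
    return TagAlignmentRecord(
        tag_id=aln.query_name,
        scaffold_id=ref,
        start=aln.reference_start,
        orientation="-" if aln.is_reverse else "+",
        match_len=aligned - mismatches,
        insert_len=ins,
        ref_span=ref_span,
        mapq=aln.mapping_quality,
        secondary=aln.is_secondary or aln.is_supplementary,
    )


def write_assembly(scaffolds: Sequence[Scaffold], path: str | Path, width: int = 80) -> None:
    """Write scaffolds as FASTA, 80-column wrapped, in input order."""
    if not scaffolds:
        raise ValueError("refusing to write an empty assembly")
    with open(path, "w") as out:
        for sc in scaffolds:
            out.write(f">{sc.id}\n")
            for i in range(0, sc.length, width):
                out.write(sc.sequence[i : i + width] + "\n")


@dataclass
class GapReportRow:
    """One gap in one iteration of the closure loop."""

    scaffold_id: str
    gap_start: int
    gap_end: int
    gap_len: int
    iteration: int
    gap_type: str  # "1" | "2" | "3" | "none"
    status: str  # open | partial | closed
    fill_len: int = 0
    inserted_n: int = 0
    source_read_ids: tuple[str, ...] = field(default_factory=tuple)


_REPORT_COLUMNS = (
    "scaffold_id",
    "gap_start",
    "gap_end",
    "L_C",
    "iteration",
    "gap_type",
    "status",
    "fill_len",
    "inserted_N",
    "source_read_ids",
)


def write_report(
    rows: Sequence[GapReportRow],
    summary: Mapping[str, object],
    path: str | Path,
) -> None:
    """Write the per-gap TSV report plus a '#'-prefixed summary block."""
    with open(path, "w") as out:
        out.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in rows:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        r.scaffold_id,
                        r.gap_start,
                        r.gap_end,
                        r.gap_len,
                        r.iteration,
                        r.gap_type,
                        r.status,
                        r.fill_len,
                        r.inserted_n,
                        ",".join(r.source_read_ids) or "-",
                    )
                )
                + "\n"
            )
        for key, value in summary.items():
            out.write(f"# {key}\t{value}\n")
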