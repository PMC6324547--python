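"""Fragmentation of long reads into tiling paths of fixed-length tags.

Each read is cut into consecutive, non-overlapping tags of identical length
starting at offset 0; the sub-tag-length remainder at the 3' end is dropped
so that every tag shares the same length (the denominator of the alignment
coverage score). Reads shorter than one tag yield no tags and are ignored
downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

DEFAULT_TAG_LEN = 300


@dataclass
class LongRead:
    """A long sequencing read (PacBio/Nanopore-like), upper case DNA."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Tag:
    """A fixed-length fragment of a long read.

    ``p`` is the 0-based offset of the tag start on the read; tag ids are
    ``"<read_id>#<index>"`` which is also the FASTA id handed to aligners.
    """

    read_id: str
    index: int
    p: int
    tag_len: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.read_id}#{self.index}"


def fragment_read(read: LongRead, tag_len: int = DEFAULT_TAG_LEN) -> list[Tag]:
    """Cut ``read`` into floor(L/tag_len) consecutive tags of length ``tag_len``."""
    if tag_len <= 0:
        raise ValueError("tag_len must be positive")
    n = read.length // tag_len
    return [
        Tag(read.id, i, i * tag_len, tag_len, read.sequence[i * tag_len : (i + 1) * tag_len])
        for i in range(n)
    ]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_long_reads(path: str | Path) -> list[LongRead]:
    """Load reads from FASTA or FASTQ (optionally gzipped); format is sniffed.

    Duplicate read ids are rejected. Sequences are upper-cased.
    """
    from Bio import SeqIO

    with _open_text(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"cannot determine read format of {path}")
        reads: list[LongRead] = []
        seen: set[str] = set()
        for record in SeqIO.parse(handle, fmt):
            if record.id in seen:
                raise ValueError(f"duplicate read id {record.id!r} in {path}")
            seen.add(record.id)
            reads.append(LongRead(record.id, str(record.seq).upper()))
    return reads


def fragment_reads(
    reads: Iterable[LongRead], tag_len: int = DEFAULT_TAG_LEN
) -> list[Tag]:
    """Fragment every read; reads shorter than ``tag_len`` contribute nothing."""
    tags: list[Tag] = []
    for read in reads:
        tags.extend(fragment_read(read, tag_len))
    return tags


def write_tags_fasta(tags: Sequence[Tag], path: str | Path) -> None:
    """Emit tags as FASTA with ids ``read_id#index`` for an external aligner."""
    with open(path, "w") as out:
        for tag in tags:
            out.write(f">{tag.id}\n{tag.sequence}\n")
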