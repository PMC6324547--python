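"""Pluggable tag-to-scaffold alignment backends.

The closure logic only needs `TagAlignmentRecord`s; where they come from is
a contract with three implementations:

* ``SamAligner`` — a user-supplied SAM of tag alignments (single pass);
* ``CommandAligner`` — shell out to an external aligner command template
  with ``{tags.fasta}`` and ``{assembly.fasta}`` placeholders, expecting
  SAM on stdout (e.g. a BWA-MEM or minimap2 pipeline);
* ``BuiltinExactAligner`` — an exact-match seed-and-verify aligner that
  reports every full-length perfect hit on either strand. It is adequate
  for error-free sequence only and exists so the pipeline can run
  hermetically.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from collections import defaultdict
from pathlib import Path
from typing import Protocol, Sequence

from ._util import revcomp
from .assembly_io import Scaffold, TagAlignmentRecord, parse_tag_alignments, write_assembly
from .tiling import Tag, write_tags_fasta

logger = logging.getLogger(__name__)

#: external-command template using the BWA-MEM short-read algorithm;
#: -a reports all candidate loci so multiplicity classification works.
BWA_TEMPLATE = (
    "bwa index {assembly.fasta} >/dev/null 2>&1 && "
    "bwa mem -a -v 1 {assembly.fasta} {tags.fasta} 2>/dev/null"
)

#: minimap2 equivalent (short-read preset, secondary hits kept).
MINIMAP2_TEMPLATE = (
    "minimap2 -ax sr --secondary=yes -N 10 {assembly.fasta} {tags.fasta} 2>/dev/null"
)


class Aligner(Protocol):
    #: whether alignments track the current assembly across iterations
    iterative: bool

    def align(
        self, tags: Sequence[Tag], scaffolds: Sequence[Scaffold]
    ) -> list[TagAlignmentRecord]: ...


class SamAligner:
    """Replays a precomputed SAM file; valid for one iteration only."""

    iterative = False

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def align(self, tags, scaffolds):
        tag_lengths = {t.id: t.tag_len for t in tags}
        return parse_tag_alignments(
            self.path, tag_lengths, [sc.id for sc in scaffolds]
        )


class CommandAligner:
    """Runs an external aligner command template producing SAM on stdout."""

    iterative = True

    def __init__(self, template: str):
        self.template = template

    def align(self, tags, scaffolds):
        with tempfile.TemporaryDirectory(prefix="tilegap_aln_") as tmp:
            tmp = Path(tmp)
            tags_path = tmp / "tags.fasta"
            asm_path = tmp / "assembly.fasta"
            sam_path = tmp / "alignments.sam"
            write_tags_fasta(tags, tags_path)
            write_assembly(scaffolds, asm_path)
            cmd = (
                self.template.replace("{tags.fasta}", str(tags_path))
                .replace("{assembly.fasta}", str(asm_path))
                .replace("{tags}", str(tags_path))
                .replace("{assembly}", str(asm_path))
            )
            with open(sam_path, "w") as out:
                proc = subprocess.run(
                    cmd, shell=True, stdout=out, stderr=subprocess.PIPE, text=True
                )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"aligner command failed (exit {proc.returncode}): "
                    f"{cmd}\n{proc.stderr[-2000:]}"
                )
            tag_lengths = {t.id: t.tag_len for t in tags}
            return parse_tag_alignments(
                sam_path, tag_lengths, [sc.id for sc in scaffolds]
            )


class BuiltinExactAligner:
    """Exact full-length matcher: seed lookup plus verification, both strands.

    Every perfect hit is reported as a candidate locus (match_len equal to
    the tag length, no insertions), so repeats produce multi-mapping tags
    exactly as a real aligner would — but any sequencing error makes a tag
    invisible, hence error-free fixtures only.
    """

    iterative = True

    def __init__(self, seed_len: int = 21):
        self.seed_len = seed_len

    def align(self, tags, scaffolds):
        k = self.seed_len
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, sc in enumerate(scaffolds):
            seq = sc.sequence
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    index[kmer].append((si, pos))
        records = []
        for tag in tags:
            if "N" in tag.sequence or tag.tag_len < k:
                continue
            hits = []
            for orient, seq in (("+", tag.sequence), ("-", revcomp(tag.sequence))):
                for si, pos in index.get(seq[:k], ()):
                    target = scaffolds[si].sequence
                    if target[pos : pos + tag.tag_len] == seq:
                        hits.append((si, pos, orient))
            for n, (si, pos, orient) in enumerate(hits):
                records.append(
                    TagAlignmentRecord(
                        tag_id=tag.id,
                        scaffold_id=scaffolds[si].id,
                        start=pos,
                        orientation=orient,
                        match_len=tag.tag_len,
                        insert_len=0,
                        ref_span=tag.tag_len,
                        mapq=60 if len(hits) == 1 else 0,
                        secondary=n > 0,
                    )
                )
        return records
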