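"""Small sequence helpers shared across modules."""

from __future__ import annotations

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_RC)[::-1]
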