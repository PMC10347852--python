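"""Minimal DNA string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    With odd k no k-mer is its own reverse complement, so the canonical
    form is strand-unambiguous.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc
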