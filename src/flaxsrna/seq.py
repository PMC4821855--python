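"""Shared sequence helpers: alphabet normalization and reverse complement."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGTN")


def normalize(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA (U) to DNA (T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, allow_n: bool = True) -> str:
    """Normalize and validate; raises ValueError on foreign characters."""
    s = normalize(seq)
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s
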