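"""Small shared helpers: rounding, sequence alphabet handling, checksums."""

from __future__ import annotations

import hashlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes collapsed to N on the genome track
_IUPAC_AMBIG = set("RYSWKMBDHVryswkmbdhv")

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used by all printed percentages).

    Python's builtin round() is banker's rounding; percentages here follow the
    half-up convention so 93.25 -> 93.3.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_genome_seq(seq: str) -> str:
    """Uppercase and collapse IUPAC ambiguity codes to N; reject anything else."""
    out = []
    for ch in seq:
        up = ch.upper()
        if up in "ACGTN":
            out.append(up)
        elif ch in _IUPAC_AMBIG:
            out.append("N")
        else:
            raise ValueError(f"invalid sequence character {ch!r}")
    return "".join(out)


def encode_seq(seq: str) -> np.ndarray:
    """Byte-encode a sequence (A,C,G,T,N as uint8 ASCII) for vectorized scans."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def gc_fraction(seq: str) -> float:
    """(#G + #C) / #unambiguous bases; ambiguity characters excluded from both counts."""
    if not seq:
        raise ValueError("empty sequence")
    gc = sum(1 for c in seq.upper() if c in "GC")
    at = sum(1 for c in seq.upper() if c in "AT")
    total = gc + at
    return gc / total if total else 0.0
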