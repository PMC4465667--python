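"""Candidate primer enumeration and best-pair selection inside anchor regions.

Melting temperatures come from the unified nearest-neighbor thermodynamic model
(SantaLucia 1998 duplex ΔH/ΔS parameters) with the entropy salt correction
0.368·(N−1)·ln[Na+] and Tm = ΔH / (ΔS + R·ln(CT/4)) for non-self-complementary
duplexes. The implementation is deliberately self-contained so primer calls are
reproducible from this package alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .conservation import AnchorPair, ConservedAnchor, PipelineConfig
from .seqio import GenomicInterval
from .util import gc_fraction, reverse_complement

R_GAS = 1.987  # cal / (K·mol)

# unified NN duplex parameters: dinucleotide (5'->3' top strand) -> (dH kcal/mol, dS cal/mol/K)
NN_PARAMS = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# initiation terms per terminal base pair
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _nn_lookup(dinuc: str) -> tuple[float, float]:
    if dinuc in NN_PARAMS:
        return NN_PARAMS[dinuc]
    # a duplex step equals its reverse complement read on the other strand
    rc = _COMP[dinuc[1]] + _COMP[dinuc[0]]
    return NN_PARAMS[rc]


def melting_temperature(
    seq: str, monovalent_mM: float = 50.0, primer_nM: float = 50.0
) -> float:
    """Duplex melting temperature in degC for an unambiguous oligo (>= 8 nt).

    fsum makes the result independent of summation order, so
    Tm(seq) == Tm(reverse complement) holds exactly.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"ambiguous base in {seq!r}")
    dh_terms = [_nn_lookup(seq[i:i + 2])[0] for i in range(len(seq) - 1)]
    ds_terms = [_nn_lookup(seq[i:i + 2])[1] for i in range(len(seq) - 1)]
    for end in (seq[0], seq[-1]):
        init = INIT_GC if end in "GC" else INIT_AT
        dh_terms.append(init[0])
        ds_terms.append(init[1])
    dh = math.fsum(dh_terms) * 1000.0  # cal/mol
    ds = math.fsum(ds_terms)
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    ct = primer_nM * 1e-9
    return dh / (ds + R_GAS * math.log(ct / 4.0)) - 273.15


def gc_content(seq: str) -> float:
    return gc_fraction(seq)


@dataclass(frozen=True)
class Primer:
    sequence: str  # 5'->3'
    ref_interval: GenomicInterval
    strand: str  # '+' forward, '-' reverse
    tm: float
    gc: float

    def __post_init__(self):
        if len(self.sequence) != self.ref_interval.length:
            raise ValueError("primer length != interval length")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DesignedPair:
    """A forward/reverse primer pair seated in a left/right anchor pair."""

    pair_id: str
    forward: Primer
    reverse: Primer
    penalty: float

    @property
    def product_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.forward.ref_interval.contig_id,
            self.forward.ref_interval.start,
            self.reverse.ref_interval.end,
        )


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _three_prime_palindrome(seq: str, limit: int) -> bool:
    """True when a 3'-terminal stretch of >= limit bases is its own reverse
    complement (a self-annealing 3' end, the minimal dimer guard)."""
    for k in range(limit, len(seq) + 1):
        suffix = seq[-k:]
        if suffix == reverse_complement(suffix):
            return True
    return False


def enumerate_candidates(
    anchor: ConservedAnchor,
    role: str,
    config: PipelineConfig,
) -> list[Primer]:
    """All primer candidates inside an anchor for a role.

    A candidate is a consensus substring with length in [len_min, len_max] and
    Tm in [tm_min, tm_max], no N, homopolymer runs capped, and no 3'-terminal
    palindrome. Forward candidates sit on the + strand (3' end at the right,
    pointing toward the partner); reverse candidates are reported 5'->3' as the
    − strand reverse complement (3' end at the left).
    """
    if role not in ("forward", "reverse"):
        raise ValueError("role must be 'forward' or 'reverse'")
    seq = anchor.consensus
    iv = anchor.interval
    out: list[Primer] = []
    for length in range(config.primer_len_min, config.primer_len_max + 1):
        if length > len(seq):
            break
        for off in range(len(seq) - length + 1):
            sub = seq[off:off + length]
            if "N" in sub:
                continue
            oriented = sub if role == "forward" else reverse_complement(sub)
            if _max_homopolymer(oriented) > config.max_homopolymer:
                continue
            tm = melting_temperature(
                oriented, config.monovalent_mM, config.primer_nM
            )
            if not (config.tm_min <= tm <= config.tm_max):
                continue
            if _three_prime_palindrome(oriented, config.self_comp_limit):
                continue
            out.append(
                Primer(
                    sequence=oriented,
                    ref_interval=GenomicInterval(
                        iv.contig_id, iv.start + off, iv.start + off + length
                    ),
                    strand="+" if role == "forward" else "-",
                    tm=tm,
                    gc=gc_content(oriented),
                )
            )
    return out


def _individual_penalty(p: Primer, config: PipelineConfig) -> float:
    return config.w_tm * abs(p.tm - config.tm_opt) + config.w_len * abs(
        p.length - config.primer_len_opt
    )


def pair_penalty(f: Primer, r: Primer, config: PipelineConfig) -> float:
    """w_tm·(|Tf−opt| + |Tr−opt|) + w_tm_diff·|Tf−Tr| + w_len·(|Lf−opt| + |Lr−opt|).

    Lower is better; 20-mers at exactly the optimum Tm score 0.
    """
    return (
        config.w_tm * (abs(f.tm - config.tm_opt) + abs(r.tm - config.tm_opt))
        + config.w_tm_diff * abs(f.tm - r.tm)
        + config.w_len
        * (abs(f.length - config.primer_len_opt) + abs(r.length - config.primer_len_opt))
    )


def select_primer_pair(
    pair: AnchorPair,
    config: PipelineConfig,
    pair_id: str = "pair",
) -> Optional[DesignedPair]:
    """Minimal-penalty forward×reverse combination, or None when either side
    has no feasible candidate.

    Ties break by smaller product length, then leftmost forward start, then
    lexicographic forward sequence. The search is an exact branch-and-bound
    over candidates ordered by individual penalty (the pair penalty is bounded
    below by the sum of individual penalties).
    """
    fwd = enumerate_candidates(pair.left, "forward", config)
    rev = enumerate_candidates(pair.right, "reverse", config)
    if not fwd or not rev:
        return None
    fwd.sort(key=lambda p: _individual_penalty(p, config))
    rev.sort(key=lambda p: _individual_penalty(p, config))
    best: tuple | None = None
    best_pair: tuple[Primer, Primer] | None = None
    r0 = _individual_penalty(rev[0], config)
    for f in fwd:
        if best is not None and _individual_penalty(f, config) + r0 > best[0]:
            break
        for r in rev:
            if (
                best is not None
                and _individual_penalty(f, config) + _individual_penalty(r, config)
                > best[0]
            ):
                break
            pen = pair_penalty(f, r, config)
            key = (
                pen,
                r.ref_interval.end - f.ref_interval.start,
                f.ref_interval.start,
                f.sequence,
            )
            if best is None or key < best:
                best = key
                best_pair = (f, r)
    assert best_pair is not None
    return DesignedPair(
        pair_id=pair_id,
        forward=best_pair[0],
        reverse=best_pair[1],
        penalty=best[0],
    )
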