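"""Genome-wide mismatch-tolerant primer-site search and in-silico PCR.

A primer site is any genome position (either strand) whose strand-adjusted
substring lies within a Hamming distance budget of the primer (substitutions
only). Convergent +/− site combinations under a product-size cap are predicted
amplicons; a pair predicted to yield more than one product is non-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import PipelineConfig
from .primer_design import DesignedPair
from .seqio import GenomeSequence, GenomicInterval
from .util import encode_seq, reverse_complement


@dataclass(frozen=True)
class PrimerSite:
    primer_id: str
    interval: GenomicInterval
    strand: str
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    interval: GenomicInterval
    fwd_site: PrimerSite
    rev_site: PrimerSite

    @property
    def length(self) -> int:
        return self.interval.length


class GenomeIndex:
    """Byte-encoded contigs for vectorized Hamming scans."""

    def __init__(self, genome: Sequence[GenomeSequence]):
        self.arrays = {g.contig_id: encode_seq(g.sequence) for g in genome}
        self.sequences = {g.contig_id: g.sequence for g in genome}


def _scan_pattern(arr: np.ndarray, pattern: str, max_mismatches: int) -> np.ndarray:
    """Start offsets where the window Hamming distance <= budget.

    Accumulates per-column mismatch counts over all windows at once; N in the
    genome never matches.
    """
    m = len(pattern)
    n = len(arr) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mism = np.zeros(n, dtype=np.int16)
    pat = encode_seq(pattern)
    for j in range(m):
        mism += arr[j:j + n] != pat[j]
        # early exit is not needed at desk scale; the scan stays exhaustive
    return np.flatnonzero(mism <= max_mismatches)


def find_primer_sites(
    primer_seq: str,
    genome: GenomeIndex | Sequence[GenomeSequence],
    max_mismatches: int = 2,
    primer_id: str = "primer",
    strict_three_prime: bool = False,
) -> list[PrimerSite]:
    """All sites on both strands within the mismatch budget (substitutions only).

    A − strand site at [i, i+m) means the reverse complement of the genome
    window matches the primer; with strict_three_prime the primer's 3'-terminal
    base must match exactly.
    """
    if any(c not in "ACGT" for c in primer_seq.upper()):
        raise ValueError("primer must be unambiguous A/C/G/T")
    idx = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    primer_seq = primer_seq.upper()
    m = len(primer_seq)
    rc = reverse_complement(primer_seq)
    sites: list[PrimerSite] = []
    for cid in sorted(idx.arrays):
        arr = idx.arrays[cid]
        seq = idx.sequences[cid]
        for strand, pattern in (("+", primer_seq), ("-", rc)):
            for i in _scan_pattern(arr, pattern, max_mismatches):
                window = seq[i:i + m]
                mism = sum(a != b for a, b in zip(window, pattern))
                if strict_three_prime:
                    # 3' base: last window column on +, first on −
                    if strand == "+" and window[-1] != pattern[-1]:
                        continue
                    if strand == "-" and window[0] != pattern[0]:
                        continue
                sites.append(
                    PrimerSite(
                        primer_id=primer_id,
                        interval=GenomicInterval(cid, int(i), int(i) + m),
                        strand=strand,
                        mismatches=int(mism),
                    )
                )
    return sites


def enumerate_amplicons(
    sites_f: Sequence[PrimerSite],
    sites_r: Sequence[PrimerSite],
    max_product: int = 3500,
    include_self_pairs: bool = True,
) -> list[Amplicon]:
    """All convergent (+, −) site combinations with 0 < length <= max_product.

    Combinations are drawn from forward×reverse and, when include_self_pairs,
    also forward×forward and reverse×reverse (a real PCR amplifies those too).
    Deduplicated by (contig, start, end).
    """
    groups = [(sites_f, sites_r)]
    if include_self_pairs:
        groups += [(sites_f, sites_f), (sites_r, sites_r)]
    seen: set[tuple[str, int, int]] = set()
    out: list[Amplicon] = []
    for plus_pool, minus_pool in groups:
        plus = [s for s in plus_pool if s.strand == "+"]
        minus = [s for s in minus_pool if s.strand == "-"]
        for p in plus:
            for q in minus:
                if p.interval.contig_id != q.interval.contig_id:
                    continue
                length = q.interval.end - p.interval.start
                if 0 < length <= max_product:
                    key = (p.interval.contig_id, p.interval.start, q.interval.end)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        Amplicon(
                            interval=GenomicInterval(
                                p.interval.contig_id,
                                p.interval.start,
                                q.interval.end,
                            ),
                            fwd_site=p,
                            rev_site=q,
                        )
                    )
    out.sort(key=lambda a: (a.interval.contig_id, a.interval.start, a.interval.end))
    return out


@dataclass(frozen=True)
class Verdict:
    status: str  # 'unique' | 'multiple' | 'none'
    n_products: int
    amplicons: tuple[Amplicon, ...]


def specificity_verdict(
    pair: DesignedPair,
    genome: GenomeIndex | Sequence[GenomeSequence],
    config: PipelineConfig,
) -> Verdict:
    """unique / multiple(n) / none for a designed pair against the genome."""
    idx = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    sites_f = find_primer_sites(
        pair.forward.sequence,
        idx,
        config.max_mismatches,
        primer_id=f"{pair.pair_id}/F",
        strict_three_prime=config.strict_three_prime,
    )
    sites_r = find_primer_sites(
        pair.reverse.sequence,
        idx,
        config.max_mismatches,
        primer_id=f"{pair.pair_id}/R",
        strict_three_prime=config.strict_three_prime,
    )
    amps = enumerate_amplicons(
        sites_f, sites_r, config.max_product, config.include_self_pairs
    )
    if not amps:
        return Verdict("none", 0, ())
    if len(amps) == 1:
        return Verdict("unique", 1, tuple(amps))
    return Verdict("multiple", len(amps), tuple(amps))
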