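"""Coverage tracks, mapped-region calling, cross-species intersection into
conserved anchors, and distance-window pairing.

An *anchor* is a reference span covered (>= min_cov) by reads of every query
species whose per-position majority base agrees with the reference at high
identity. Anchors live in reference coordinates and their consensus is the
reference sequence: species divergence informs the identity screen, primers are
designed on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .seqio import GenomeSequence, GenomicInterval, ReadAlignmentRecord
from .util import encode_seq


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable thresholds of the discovery pipeline.

    Defaults are the published workflow's settings: regions >= 20 bp at >= 2x
    coverage per species, anchor pairs 300-700 bp apart, primers 18-27 bp at
    58-62 degC (optimum 20 bp / 60 degC), uniqueness screened with <= 2
    mismatches and a 3,500 bp product cap.
    """

    min_anchor_len: int = 20
    min_cov: int = 2
    min_aligned_fraction: float = 0.80
    min_identity: float = 0.95
    min_anchor_identity: float = 0.95
    min_gap: int = 300
    max_gap: int = 700
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    tm_min: float = 58.0
    tm_opt: float = 60.0
    tm_max: float = 62.0
    max_mismatches: int = 2
    max_product: int = 3500
    mapq_threshold: int = 30
    monovalent_mM: float = 50.0
    primer_nM: float = 50.0
    max_homopolymer: int = 4
    self_comp_limit: int = 5
    include_self_pairs: bool = True
    strict_three_prime: bool = False
    trim_anchors: bool = True
    primary_only: bool = True
    w_tm: float = 1.0
    w_tm_diff: float = 1.0
    w_len: float = 0.1
    rng_seed: int = 0

    # config-file keys use primer3 option names where one exists, so the
    # published settings read straight onto the file
    _ALIASES = {
        "PRIMER_MIN_SIZE": "primer_len_min",
        "PRIMER_OPT_SIZE": "primer_len_opt",
        "PRIMER_MAX_SIZE": "primer_len_max",
        "PRIMER_MIN_TM": "tm_min",
        "PRIMER_OPT_TM": "tm_opt",
        "PRIMER_MAX_TM": "tm_max",
    }

    def __post_init__(self):
        if not (self.primer_len_min <= self.primer_len_opt <= self.primer_len_max):
            raise ValueError("primer length min <= opt <= max violated")
        if not (self.tm_min <= self.tm_opt <= self.tm_max):
            raise ValueError("Tm min <= opt <= max violated")
        if self.min_gap > self.max_gap:
            raise ValueError("min_gap > max_gap")
        for name in ("min_anchor_len", "min_cov", "max_mismatches", "max_product"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat key=value config (``#`` comments, blank lines allowed)."""
        known = {f.name: f.type for f in fields(cls) if not f.name.startswith("_")}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            key = cls._ALIASES.get(key, key.lower())
            if key not in known:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if not f.name.startswith("_")}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    contig_id: str
    depth: np.ndarray  # one integer cell per reference base

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class MappedRegion:
    species_id: str
    interval: GenomicInterval
    mean_depth: float


@dataclass
class ConservedAnchor:
    interval: GenomicInterval
    consensus: str  # reference sequence over the interval
    per_species_identity: dict[str, float]
    support: dict[str, MappedRegion] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.consensus) != self.interval.length:
            raise ValueError("consensus length != interval length")


@dataclass(frozen=True)
class AnchorPair:
    left: ConservedAnchor
    right: ConservedAnchor

    def __post_init__(self):
        if self.left.interval.contig_id != self.right.interval.contig_id:
            raise ValueError("anchor pair spans two contigs")
        if self.left.interval.end > self.right.interval.start:
            raise ValueError("anchors out of order or overlapping")

    @property
    def gap(self) -> int:
        return self.right.interval.start - self.left.interval.end

    @property
    def target_span(self) -> GenomicInterval:
        return GenomicInterval(
            self.left.interval.contig_id,
            self.left.interval.start,
            self.right.interval.end,
        )


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def coverage_tracks(
    records: Iterable[ReadAlignmentRecord],
    genome: Sequence[GenomeSequence],
) -> dict[str, CoverageTrack]:
    """Per-contig depth where depth[i] = number of record blocks containing i.

    Span-based: internal deletions count as covered, N-skipped (intron) gaps do
    not (records carry their blocks). A record beyond contig bounds is a hard
    error.
    """
    lengths = {g.contig_id: len(g.sequence) for g in genome}
    diffs = {cid: np.zeros(n + 1, dtype=np.int32) for cid, n in lengths.items()}
    for rec in records:
        for blk in rec.blocks:
            if blk.contig_id not in lengths:
                raise ValueError(f"record {rec.read_id}: unknown contig {blk.contig_id}")
            if blk.end > lengths[blk.contig_id]:
                raise ValueError(
                    f"record {rec.read_id} beyond contig bounds "
                    f"({blk.end} > {lengths[blk.contig_id]})"
                )
            diffs[blk.contig_id][blk.start] += 1
            diffs[blk.contig_id][blk.end] -= 1
    return {
        cid: CoverageTrack(cid, np.cumsum(d[:-1])) for cid, d in diffs.items()
    }


def build_coverage(
    records_by_species: Mapping[str, Iterable[ReadAlignmentRecord]],
    genome: Sequence[GenomeSequence],
) -> dict[str, dict[str, CoverageTrack]]:
    """species_id -> contig_id -> CoverageTrack."""
    return {
        sp: coverage_tracks(recs, genome)
        for sp, recs in records_by_species.items()
    }


def call_mapped_regions(
    track: CoverageTrack,
    min_len: int = 20,
    min_cov: int = 2,
    species_id: str = "",
) -> list[MappedRegion]:
    """Maximal runs with depth >= min_cov, kept when run length >= min_len."""
    ok = track.depth >= min_cov
    if not ok.any():
        return []
    padded = np.concatenate(([False], ok, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = edges[::2], edges[1::2]
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            iv = GenomicInterval(track.contig_id, int(s), int(e))
            out.append(
                MappedRegion(species_id, iv, float(track.depth[s:e].mean()))
            )
    return out


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

def _intersect_two(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i].contig_id != b[j].contig_id:
            if a[i].contig_id < b[j].contig_id:
                i += 1
            else:
                j += 1
            continue
        lo = max(a[i].start, b[j].start)
        hi = min(a[i].end, b[j].end)
        if lo < hi:
            out.append(GenomicInterval(a[i].contig_id, lo, hi))
        if a[i].end < b[j].end:
            i += 1
        else:
            j += 1
    return out


def intersect_species(
    regions: Mapping[str, Sequence[MappedRegion]],
) -> list[GenomicInterval]:
    """Maximal intervals contained in at least one region of every species."""
    if not regions:
        raise ValueError("at least one species required")
    per_species = []
    for regs in regions.values():
        ivs = sorted(
            (r.interval for r in regs), key=lambda iv: (iv.contig_id, iv.start)
        )
        per_species.append(list(ivs))
    current = per_species[0]
    for other in per_species[1:]:
        current = _intersect_two(current, other)
    return current


# ---------------------------------------------------------------------------
# pileups and anchor calling
# ---------------------------------------------------------------------------

def build_majority_pileup(
    sam_path,
    genome: Sequence[GenomeSequence],
    keep_ids: set[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-contig majority base (uint8 ASCII) among covering reads.

    Ties go to the reference base when it is among the leaders, else to the
    alphabetically first leader; uncovered positions are ``N``.
    """
    ref = {g.contig_id: encode_seq(g.sequence) for g in genome}
    counts = {
        cid: np.zeros((4, len(arr)), dtype=np.int32) for cid, arr in ref.items()
    }
    base_codes = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        base_codes[b] = i
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if keep_ids is not None and aln.query_name not in keep_ids:
                continue
            cid = aln.reference_name
            if cid not in counts:
                continue
            seq = aln.query_sequence
            if seq is None:
                continue
            qarr = encode_seq(seq)
            qpos = 0
            rpos = aln.reference_start
            for op, ln in aln.cigartuples:
                if op in (0, 7, 8):  # aligned columns
                    codes = base_codes[qarr[qpos:qpos + ln]]
                    valid = codes >= 0
                    np.add.at(
                        counts[cid],
                        (codes[valid], np.arange(rpos, rpos + ln)[valid]),
                    1)
                    qpos += ln
                    rpos += ln
                elif op in (1, 4):  # insertion / soft clip consume query
                    qpos += ln
                elif op in (2, 3):  # deletion / skip consume reference
                    rpos += ln
    pileups = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for cid, cnt in counts.items():
        maj_idx = cnt.argmax(axis=0)
        maj = bases[maj_idx]
        top = cnt.max(axis=0)
        covered = top > 0
        # tie toward the reference base where the reference is a leader
        ref_codes = base_codes[ref[cid]]
        has_ref = ref_codes >= 0
        ref_count = np.zeros(len(maj), dtype=np.int32)
        idx = np.flatnonzero(has_ref)
        ref_count[idx] = cnt[ref_codes[idx], idx]
        tie_to_ref = covered & has_ref & (ref_count == top)
        maj = np.where(tie_to_ref, ref[cid], maj)
        maj = np.where(covered, maj, ord("N"))
        pileups[cid] = maj.astype(np.uint8)
    return pileups


def call_conserved_anchors(
    intervals: Sequence[GenomicInterval],
    pileups: Mapping[str, Mapping[str, np.ndarray]],
    genome: Sequence[GenomeSequence],
    config: PipelineConfig,
    regions_by_species: Mapping[str, Sequence[MappedRegion]] | None = None,
    trim: bool | None = None,
) -> list[ConservedAnchor]:
    """Turn intersected intervals into conserved anchors.

    Per-species identity over a span is the fraction of positions whose
    species-majority base equals the reference base (uncovered positions count
    as disagreement). With trimming (default) each interval is decomposed into
    its maximal sub-runs where every species' majority base agrees with the
    reference; runs shorter than min_anchor_len are dropped. Without trimming
    the whole interval is kept iff every species identity >= the threshold.
    """
    if trim is None:
        trim = config.trim_anchors
    ref = {g.contig_id: encode_seq(g.sequence) for g in genome}
    seqs = {g.contig_id: g.sequence for g in genome}
    species = sorted(pileups)
    anchors: list[ConservedAnchor] = []

    def identity(sp: str, iv: GenomicInterval) -> float:
        pile = pileups[sp].get(iv.contig_id)
        if pile is None or len(pile) != len(ref[iv.contig_id]):
            raise ValueError(f"pileup/interval mismatch for {sp}/{iv.contig_id}")
        seg = pile[iv.start:iv.end]
        return float((seg == ref[iv.contig_id][iv.start:iv.end]).mean())

    def make_anchor(iv: GenomicInterval) -> ConservedAnchor:
        idents = {sp: identity(sp, iv) for sp in species}
        support = {}
        if regions_by_species:
            for sp, regs in regions_by_species.items():
                for reg in regs:
                    if reg.interval.contains(iv):
                        support[sp] = reg
                        break
        return ConservedAnchor(
            interval=iv,
            consensus=seqs[iv.contig_id][iv.start:iv.end],
            per_species_identity=idents,
            support=support,
        )

    for iv in intervals:
        if iv.contig_id not in ref:
            raise ValueError(f"interval on unknown contig {iv.contig_id}")
        if trim:
            agree = np.ones(iv.length, dtype=bool)
            for sp in species:
                pile = pileups[sp].get(iv.contig_id)
                if pile is None or len(pile) != len(ref[iv.contig_id]):
                    raise ValueError(
                        f"pileup/interval mismatch for {sp}/{iv.contig_id}"
                    )
                agree &= (
                    pile[iv.start:iv.end] == ref[iv.contig_id][iv.start:iv.end]
                )
            padded = np.concatenate(([False], agree, [False]))
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in zip(edges[::2], edges[1::2]):
                if e - s >= config.min_anchor_len:
                    sub = GenomicInterval(
                        iv.contig_id, iv.start + int(s), iv.start + int(e)
                    )
                    anchors.append(make_anchor(sub))
        else:
            if iv.length < config.min_anchor_len:
                continue
            anchor = make_anchor(iv)
            if all(
                v >= config.min_anchor_identity
                for v in anchor.per_species_identity.values()
            ):
                anchors.append(anchor)
    anchors.sort(key=lambda a: (a.interval.contig_id, a.interval.start))
    return anchors


def pair_anchors(
    anchors: Sequence[ConservedAnchor],
    min_gap: int = 300,
    max_gap: int = 700,
) -> list[AnchorPair]:
    """All ordered same-contig anchor pairs whose inner gap
    (right.start - left.end) lies in [min_gap, max_gap]; an anchor may appear
    in several pairs."""
    srt = sorted(anchors, key=lambda a: (a.interval.contig_id, a.interval.start))
    pairs: list[AnchorPair] = []
    for i, left in enumerate(srt):
        for right in srt[i + 1:]:
            if right.interval.contig_id != left.interval.contig_id:
                break
            gap = right.interval.start - left.interval.end
            if gap > max_gap:
                break
            if gap >= min_gap:
                pairs.append(AnchorPair(left, right))
    return pairs
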