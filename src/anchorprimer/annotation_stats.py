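"""Marker classification against gene models and alignment variability
statistics (parsimony-informative sites, mean pairwise nucleotide diversity,
GC content, repeat pruning, and the marker report table).

Heterozygous sites written as IUPAC ambiguity codes, and gaps, are treated as
missing data with pairwise deletion throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seqio import GeneModel
from .specificity import Amplicon
from .util import round_half_up

_UNAMBIG = b"ACGT"


# ---------------------------------------------------------------------------
# marker classification
# ---------------------------------------------------------------------------

@dataclass
class MarkerAnnotation:
    pair_id: str
    gene_ids: list[str]
    marker_class: str  # NPCL | EPIC | UTR_anchored | intergenic
    intron_count: int
    structure_code: str


def _structure_code(marker_class: str, intron_count: int) -> str:
    if marker_class == "intergenic":
        return "-"
    return "e" if intron_count == 0 else "i" * intron_count


def classify_marker(
    amplicon: Amplicon,
    gene_models: Sequence[GeneModel],
    pair_id: str = "pair",
) -> MarkerAnnotation:
    """Classify a predicted product against gene models.

    intergenic when no gene overlaps; UTR_anchored when either primer site
    lies wholly inside a UTR of the classifying gene; otherwise EPIC when the
    product intersects >= 1 intron of that gene, else NPCL. With several
    overlapping genes all ids are reported and the gene with maximal overlap
    classifies. Structure codes follow the e / i / ii convention (one letter
    i per intron in the fragment).
    """
    iv = amplicon.interval
    hits = [
        (gm.span.overlap_len(iv), gm)
        for gm in gene_models
        if gm.span.overlaps(iv)
    ]
    if not hits:
        return MarkerAnnotation(pair_id, [], "intergenic", 0, "-")
    hits.sort(key=lambda t: (-t[0], t[1].gene_id))
    gene = hits[0][1]
    gene_ids = [gm.gene_id for _, gm in hits]
    intron_count = sum(1 for intr in gene.introns if intr.overlaps(iv))
    utrs = gene.utr5 + gene.utr3
    primer_in_utr = any(
        utr.contains(site.interval)
        for utr in utrs
        for site in (amplicon.fwd_site, amplicon.rev_site)
    )
    if primer_in_utr:
        cls = "UTR_anchored"
    elif intron_count >= 1:
        cls = "EPIC"
    else:
        cls = "NPCL"
    return MarkerAnnotation(
        pair_id, gene_ids, cls, intron_count, _structure_code(cls, intron_count)
    )


# ---------------------------------------------------------------------------
# alignment container
# ---------------------------------------------------------------------------

@dataclass
class AlignmentMatrix:
    """n×L multiple alignment over {A,C,G,T, IUPAC ambiguity, '-'}."""

    names: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise ValueError("names/rows length mismatch")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("ragged alignment")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.array(
            [np.frombuffer(r.encode("ascii"), dtype=np.uint8) for r in self.rows]
        )

    @classmethod
    def from_fasta(cls, path) -> "AlignmentMatrix":
        names, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            names.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(names, rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def count_pic(aln: AlignmentMatrix) -> int:
    """Parsimony-informative columns: >= 2 distinct unambiguous states each in
    >= 2 sequences; gaps and ambiguity codes are missing data."""
    if aln.n < 2:
        return 0
    mat = aln.to_array()
    counts = np.stack([(mat == b).sum(axis=0) for b in _UNAMBIG])  # 4 x L
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def nucleotide_diversity(aln: AlignmentMatrix) -> float:
    """Mean pairwise p-distance with pairwise deletion of gaps/ambiguities.

    A pair with zero comparable sites is excluded with a warning.
    """
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    mat = aln.to_array()
    unambig = np.isin(mat, np.frombuffer(_UNAMBIG, dtype=np.uint8))
    dists = []
    n_excluded = 0
    for i, j in combinations(range(aln.n), 2):
        comparable = unambig[i] & unambig[j]
        n_comp = int(comparable.sum())
        if n_comp == 0:
            n_excluded += 1
            continue
        diff = int((mat[i][comparable] != mat[j][comparable]).sum())
        dists.append(diff / n_comp)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} sequence pair(s) with no comparable sites excluded",
            stacklevel=2,
        )
    if not dists:
        raise ValueError("no sequence pair with comparable sites")
    return float(np.mean(dists))


def pic_percent(pic_count: int, alignment_length: int) -> float:
    """100·pic/L, rounded half-up to 1 decimal (printed with a trailing zero)."""
    if alignment_length <= 0:
        raise ValueError("alignment length must be positive")
    if not (0 <= pic_count <= alignment_length):
        raise ValueError("pic_count outside [0, alignment_length]")
    return round_half_up(100.0 * pic_count / alignment_length, 1)


def alignment_gc_percent(aln: AlignmentMatrix) -> float:
    """GC percentage over all rows, ambiguity/gap characters excluded."""
    mat = aln.to_array()
    gc = int(np.isin(mat, np.frombuffer(b"GC", dtype=np.uint8)).sum())
    at = int(np.isin(mat, np.frombuffer(b"AT", dtype=np.uint8)).sum())
    if gc + at == 0:
        raise ValueError("no unambiguous bases in alignment")
    return round_half_up(100.0 * gc / (gc + at), 1)


# ---------------------------------------------------------------------------
# repeat pruning
# ---------------------------------------------------------------------------

@dataclass
class PruneRules:
    max_monomer_run: int = 8  # monomer runs LONGER than this are removed
    motif_len_max: int = 6
    min_motif_repeats: int = 5


def _column_consensus(aln: AlignmentMatrix) -> str:
    """Majority character per column among unambiguous bases; '-' when a column
    has no unambiguous base. Ties go to the alphabetically first base."""
    mat = aln.to_array()
    counts = np.stack([(mat == b).sum(axis=0) for b in _UNAMBIG])  # 4 x L
    top = counts.max(axis=0)
    maj = np.frombuffer(_UNAMBIG, dtype=np.uint8)[counts.argmax(axis=0)]
    cons = np.where(top > 0, maj, ord("-")).astype(np.uint8)
    return cons.tobytes().decode("ascii")


def repeat_mask(consensus: str, rules: PruneRules) -> np.ndarray:
    """Boolean mask of consensus columns inside a monomer run longer than
    max_monomer_run or a microsatellite run (motif length 1..motif_len_max
    repeated >= min_motif_repeats times)."""
    L = len(consensus)
    mask = np.zeros(L, dtype=bool)
    # monomer runs
    i = 0
    while i < L:
        j = i
        while j < L and consensus[j] == consensus[i]:
            j += 1
        if consensus[i] in "ACGT" and j - i > rules.max_monomer_run:
            mask[i:j] = True
        i = j
    # microsatellite motif runs (perfect tandem repeats)
    for k in range(1, rules.motif_len_max + 1):
        i = 0
        while i + k <= L:
            motif = consensus[i:i + k]
            if "-" in motif:
                i += 1
                continue
            j = i + k
            while j + k <= L and consensus[j:j + k] == motif:
                j += k
            n_rep = (j - i) // k
            if n_rep >= rules.min_motif_repeats:
                mask[i:i + n_rep * k] = True
            # advance by one, not to j: phase-shifted overlapping runs
            # (e.g. the TA-frame inside an AT-repeat) must be caught too
            i += 1
    return mask


def alignment_prune(
    aln: AlignmentMatrix, rules: PruneRules | None = None
) -> tuple[AlignmentMatrix, np.ndarray]:
    """Remove repeat columns (consensus monomer runs > 8 bp, microsatellite
    motif runs); returns the pruned alignment and the removal mask."""
    rules = rules or PruneRules()
    if aln.length == 0:
        return aln, np.zeros(0, dtype=bool)
    mask = repeat_mask(_column_consensus(aln), rules)
    keep = ~mask
    rows = ["".join(np.array(list(r))[keep]) for r in aln.rows]
    return AlignmentMatrix(list(aln.names), rows), mask


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def sequencing_success_pct(n_obtained: int, n_attempted: int) -> float:
    if n_attempted <= 0:
        raise ValueError("n_attempted must be positive")
    return round_half_up(100.0 * n_obtained / n_attempted, 1)


def marker_report(
    alignments: Mapping[str, AlignmentMatrix],
    annotations: Mapping[str, MarkerAnnotation] | None = None,
    n_attempted: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """One row per marker with structure code, sequence counts, alignment
    length, PIC count/percent, nucleotide diversity and GC percent. Markers
    without an alignment get missing statistics."""
    annotations = annotations or {}
    n_attempted = n_attempted or {}
    marker_ids = sorted(set(alignments) | set(annotations))
    rows = []
    for mid in marker_ids:
        ann = annotations.get(mid)
        row: dict = {
            "marker_id": mid,
            "structure_code": ann.structure_code if ann else "",
        }
        aln = alignments.get(mid)
        if aln is None or aln.n == 0:
            row.update(
                n_sequences=np.nan,
                sequencing_success=np.nan,
                alignment_length=np.nan,
                pic_count=np.nan,
                pic_percent=np.nan,
                nucleotide_diversity=np.nan,
                gc_percent=np.nan,
            )
        else:
            pic = count_pic(aln)
            row["n_sequences"] = aln.n
            attempted = n_attempted.get(mid)
            row["sequencing_success"] = (
                sequencing_success_pct(aln.n, attempted) if attempted else np.nan
            )
            row["alignment_length"] = aln.length
            row["pic_count"] = pic
            row["pic_percent"] = pic_percent(pic, aln.length)
            row["nucleotide_diversity"] = (
                nucleotide_diversity(aln) if aln.n >= 2 else np.nan
            )
            row["gc_percent"] = alignment_gc_percent(aln)
        rows.append(row)
    cols = [
        "marker_id",
        "structure_code",
        "n_sequences",
        "sequencing_success",
        "alignment_length",
        "pic_count",
        "pic_percent",
        "nucleotide_diversity",
        "gc_percent",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_marker_report(report: pd.DataFrame, path) -> None:
    """Report TSV with the display convention: percentages printed with two
    digits after the point (e.g. 19.60%), diversity with three decimals."""
    disp = report.copy()
    for col in ("sequencing_success", "pic_percent", "gc_percent"):
        disp[col] = disp[col].map(
            lambda v: "" if pd.isna(v) else f"{v:.2f}%"
        )
    disp["nucleotide_diversity"] = disp["nucleotide_diversity"].map(
        lambda v: "" if pd.isna(v) else f"{v:.3f}"
    )
    for col in ("n_sequences", "alignment_length", "pic_count"):
        disp[col] = disp[col].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    disp.to_csv(path, sep="\t", index=False)
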