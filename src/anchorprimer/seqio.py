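"""Readers/writers for the standard formats the pipeline touches, plus read QC
and mapping-summary utilities.

Coordinate convention: everything in memory is 0-based half-open. GFF3 (1-based,
closed) and the displayed primer-table coordinates (1-based, closed) are converted
at the I/O boundary only.
"""

from __future__ import annotations

import re
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import normalize_genome_seq, round_half_up


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A reference-anchored span, 0-based half-open; the unit of region arithmetic."""

    contig_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GenomeSequence:
    contig_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """One aligned read against the reference.

    ``blocks`` are the reference-consuming stretches of the alignment with
    N (intron-skip) operations splitting the span; internal deletions do not
    split a block. ``interval`` is the envelope of the blocks.
    """

    read_id: str
    interval: GenomicInterval
    mapq: int
    aligned_fraction: float
    identity: float
    is_primary: bool
    blocks: tuple[GenomicInterval, ...] = ()

    def __post_init__(self):
        if not self.blocks:
            object.__setattr__(self, "blocks", (self.interval,))


@dataclass
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.contig_id, a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    def _utrs(self) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        if not self.cds:
            return [], []
        cds_lo = self.cds[0].start
        cds_hi = self.cds[-1].end
        left, right = [], []
        for ex in self.exons:
            if ex.start < cds_lo:
                left.append(
                    GenomicInterval(self.contig_id, ex.start, min(ex.end, cds_lo))
                )
            if ex.end > cds_hi:
                right.append(
                    GenomicInterval(self.contig_id, max(ex.start, cds_hi), ex.end)
                )
        return (left, right) if self.strand == "+" else (right, left)

    @property
    def utr5(self) -> list[GenomicInterval]:
        return self._utrs()[0]

    @property
    def utr3(self) -> list[GenomicInterval]:
        return self._utrs()[1]


@dataclass
class QualityProfile:
    per_position_mean_quality: list[float]
    read_length_summary: dict


@dataclass
class MappingSummary:
    """Read-mapping bookkeeping; percentages are computed on demand, never stored
    rounded. pct_mapped is relative to total reads, pct_high_mapq to mapped reads
    (the convention of the printed summary arithmetic)."""

    total_reads: int
    mapped_reads: int
    high_mapq_reads: int
    mapq_threshold: int = 30

    def __post_init__(self):
        if not (self.high_mapq_reads <= self.mapped_reads <= self.total_reads):
            raise ValueError("inconsistent mapping summary counts")

    @property
    def pct_mapped(self) -> float:
        return round_half_up(100.0 * self.mapped_reads / self.total_reads, 1)

    @property
    def pct_high_mapq(self) -> float:
        if self.mapped_reads == 0:
            return 0.0
        return round_half_up(100.0 * self.high_mapq_reads / self.mapped_reads, 1)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[GenomeSequence]:
    """Read a FASTA file into normalized genome sequences.

    Lowercase is uppercased and IUPAC ambiguity codes collapse to N. Duplicate
    contig ids and empty records are hard errors.
    """
    seqs: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if not raw:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        seqs.append(GenomeSequence(rec.id, normalize_genome_seq(raw)))
    if not seen and _file_nonempty(path):
        raise ValueError(f"no FASTA records parsed from {path}")
    return seqs


def _file_nonempty(path) -> bool:
    try:
        with open(path) as fh:
            return bool(fh.read(1))
    except OSError:
        return False


def write_fasta(seqs: Iterable[GenomeSequence], path, wrap: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.contig_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_MD_MISMATCH = re.compile(r"([0-9]+)|(\^[A-Z]+)|([A-Z])")


def _mismatches_from_md(md: str) -> int:
    n = 0
    for num, dele, sub in _MD_MISMATCH.findall(md):
        if sub:
            n += 1
    return n


def _record_from_pysam(aln: pysam.AlignedSegment) -> ReadAlignmentRecord | None:
    """Convert one mapped pysam record; None when identity is not computable."""
    cig = aln.cigartuples
    if cig is None:
        return None
    aligned_cols = sum(ln for op, ln in cig if op in (0, 7, 8))  # M, =, X
    if aligned_cols == 0:
        return None
    ins = sum(ln for op, ln in cig if op == 1)
    dele = sum(ln for op, ln in cig if op == 2)
    if aln.has_tag("NM"):
        mism = aln.get_tag("NM") - ins - dele
    elif aln.has_tag("MD"):
        mism = _mismatches_from_md(aln.get_tag("MD"))
    else:
        return None
    mism = max(0, min(mism, aligned_cols))
    read_len = aln.infer_read_length() or aln.query_length
    if not read_len:
        return None
    # reference-consuming blocks, split only at N (intron skip)
    blocks: list[GenomicInterval] = []
    pos = aln.reference_start
    blk_start = pos
    for op, ln in cig:
        if op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += ln
        elif op == 3:  # N: close the current block
            if pos > blk_start:
                blocks.append(
                    GenomicInterval(aln.reference_name, blk_start, pos)
                )
            pos += ln
            blk_start = pos
    if pos > blk_start:
        blocks.append(GenomicInterval(aln.reference_name, blk_start, pos))
    interval = GenomicInterval(aln.reference_name, aln.reference_start, pos)
    return ReadAlignmentRecord(
        read_id=aln.query_name,
        interval=interval,
        mapq=aln.mapping_quality,
        aligned_fraction=min(1.0, aligned_cols / read_len),
        identity=(aligned_cols - mism) / aligned_cols,
        is_primary=not (aln.is_secondary or aln.is_supplementary),
        blocks=tuple(blocks),
    )


def read_sam(path) -> Iterator[ReadAlignmentRecord]:
    """Stream alignment records from a SAM file (header required).

    Unmapped records are dropped silently; mapped records whose identity cannot
    be computed (no NM/MD and no usable CIGAR) are skipped with a warning.
    """
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            rec = _record_from_pysam(aln)
            if rec is None:
                n_skipped += 1
                continue
            yield rec
    if n_skipped:
        warnings.warn(
            f"{n_skipped} SAM record(s) skipped: identity not computable",
            stacklevel=2,
        )


def count_sam_reads(path) -> tuple[int, int]:
    """(total records incl. unmapped, distinct mapped read ids) for a SAM file."""
    total = 0
    mapped: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            total += 1
            if not aln.is_unmapped:
                mapped.add(aln.query_name)
    return total, len(mapped)


def filter_alignments(
    records: Iterable[ReadAlignmentRecord],
    min_aligned_fraction: float = 0.80,
    min_identity: float = 0.95,
    primary_only: bool = True,
) -> Iterator[ReadAlignmentRecord]:
    """Post-hoc re-expression of the mapper's minimum-overlap settings
    (overlap length >= 80% of the read, overlap identity >= 95%). Thresholds
    are inclusive."""
    for rec in records:
        if primary_only and not rec.is_primary:
            continue
        if rec.aligned_fraction < min_aligned_fraction:
            continue
        if rec.identity < min_identity:
            continue
        yield rec


def mapping_summary(
    records: Iterable[ReadAlignmentRecord],
    total_reads: int,
    mapq_threshold: int = 30,
) -> MappingSummary:
    """Summarize mapping counts the way the source workflow prints them:
    % mapped of all reads, and % with MAPQ strictly above the threshold of
    the mapped reads."""
    if total_reads == 0:
        raise ValueError("total_reads must be positive")
    mapped: set[str] = set()
    high: set[str] = set()
    for rec in records:
        mapped.add(rec.read_id)
        if rec.mapq > mapq_threshold:
            high.add(rec.read_id)
    return MappingSummary(
        total_reads=total_reads,
        mapped_reads=len(mapped),
        high_mapq_reads=len(high),
        mapq_threshold=mapq_threshold,
    )


# ---------------------------------------------------------------------------
# FASTQ QC
# ---------------------------------------------------------------------------

def qc_profile(fastq_path) -> QualityProfile:
    """Per-position mean phred quality and a read-length summary.

    Position i is averaged over reads longer than i (phred+33 input).
    """
    sums: list[float] = []
    counts: list[int] = []
    lengths: list[int] = []
    idx = 0
    try:
        for rec in SeqIO.parse(str(fastq_path), "fastq"):
            idx += 1
            quals = rec.letter_annotations["phred_quality"]
            lengths.append(len(quals))
            if len(quals) > len(sums):
                sums.extend([0.0] * (len(quals) - len(sums)))
                counts.extend([0] * (len(quals) - len(counts)))
            for i, q in enumerate(quals):
                sums[i] += q
                counts[i] += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near record {idx + 1}: {exc}")
    if not lengths:
        raise ValueError(f"no FASTQ records in {fastq_path}")
    means = [s / c for s, c in zip(sums, counts)]
    summary = {
        "min": min(lengths),
        "max": max(lengths),
        "median": statistics.median(lengths),
        "mean": statistics.fmean(lengths),
    }
    return QualityProfile(means, summary)


# ---------------------------------------------------------------------------
# GFF3 / BED / primer table
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into gene models (first mRNA per gene).

    GFF3 coordinates (1-based closed) become 0-based half-open internally.
    An exon outside its gene's span is a hard error naming the feature.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.id
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        exons = []
        for ex in db.children(parent, featuretype="exon", order_by="start"):
            if ex.start < gene.start or ex.end > gene.end:
                raise ValueError(
                    f"exon {ex.id or ex.start} outside span of gene {gene_id}"
                )
            exons.append(GenomicInterval(gene.seqid, ex.start - 1, ex.end))
        cds = [
            GenomicInterval(gene.seqid, c.start - 1, c.end)
            for c in db.children(parent, featuretype="CDS", order_by="start")
        ]
        if not exons:
            continue
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
                cds=cds,
            )
        )
    return models


def write_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            span = gm.span
            fh.write(
                f"{gm.contig_id}\tanchorprimer\tgene\t{span.start + 1}\t{span.end}"
                f"\t.\t{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            mrna_id = f"{gm.gene_id}.1"
            fh.write(
                f"{gm.contig_id}\tanchorprimer\tmRNA\t{span.start + 1}\t{span.end}"
                f"\t.\t{gm.strand}\t.\tID={mrna_id};Parent={gm.gene_id}\n"
            )
            for i, ex in enumerate(gm.exons, 1):
                fh.write(
                    f"{gm.contig_id}\tanchorprimer\texon\t{ex.start + 1}\t{ex.end}"
                    f"\t.\t{gm.strand}\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, c in enumerate(gm.cds, 1):
                fh.write(
                    f"{gm.contig_id}\tanchorprimer\tCDS\t{c.start + 1}\t{c.end}"
                    f"\t.\t{gm.strand}\t0\tID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


def read_bed(path) -> list[tuple[GenomicInterval, str, float, str]]:
    """BED6 rows as (interval, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            rows.append((iv, name, score, strand))
    return rows


def write_bed(rows, path) -> None:
    """Write BED6; rows are (interval, name, score, strand) or bare intervals."""
    with open(path, "w") as fh:
        for row in rows:
            if isinstance(row, GenomicInterval):
                iv, name, score, strand = row, ".", 0.0, "."
            else:
                iv, name, score, strand = row
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n"
            )


PRIMER_TABLE_COLUMNS = [
    "pair_id",
    "gene_id",
    "marker_class",
    "structure_code",
    "contig",
    "fwd_start",
    "fwd_end",
    "rev_start",
    "rev_end",
    "fwd_seq",
    "rev_seq",
    "fwd_tm",
    "rev_tm",
    "fwd_gc",
    "rev_gc",
    "gap",
    "product_len_ref",
    "n_predicted_products",
]


def write_primer_table(rows: Iterable[dict], path) -> None:
    """TSV primer table; genomic coordinates displayed 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("\t".join(PRIMER_TABLE_COLUMNS) + "\n")
        for row in rows:
            out = []
            for col in PRIMER_TABLE_COLUMNS:
                v = row.get(col, "")
                if col in ("fwd_tm", "rev_tm"):
                    v = f"{v:.2f}"
                elif col in ("fwd_gc", "rev_gc"):
                    v = f"{v:.3f}"
                out.append(str(v))
            fh.write("\t".join(out) + "\n")
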