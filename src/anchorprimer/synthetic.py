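"""Fixture generator: a toy reference with gene models, diverged species
genomes carrying planted conserved blocks and duplicated loci, and simulated
transcriptome reads with a truth SAM.

What it emulates: transcriptome reads of two related crucifer species mapped
onto a high-quality reference — long, variable-length reads (40 to ~1,200 nt,
median ~350) sampled from exon-concatenated transcripts of a normalized
library, species backgrounds diverged by i.i.d. substitutions except inside
planted conserved blocks, and duplicated loci that must be caught by the
in-silico PCR screen. Evolution is substitution-only so truth alignments stay
gap-free and the site-search oracle stays exact; reads are sampled with
jittered tiling (stratified starts) so the target depth is met with the low
variance of a normalized library.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .seqio import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    write_bed,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationSpec:
    """Study conditions for the fixture.

    Defaults describe the reference scenario: a 100 kb reference, two query
    species at 8% background divergence, 20 planted conserved block pairs
    (blocks 40-120 bp, zero divergence, inner gaps 360-640 bp so recovered
    anchors stay inside the 300-700 bp pairing window), two duplicated loci,
    and transcript reads at 5x depth with the long-read length profile
    (min 40 / median ~352 / max 1188 nt).
    """

    rng_seed: int = 0
    genome_length: int = 100_000
    genome_gc: float = 0.42
    n_species: int = 2
    substitution_rate: float = 0.08
    # planted conserved blocks, laid out as left/right pairs inside genes
    n_block_pairs: int = 20
    block_len_range: tuple[int, int] = (40, 120)
    block_gap_range: tuple[int, int] = (360, 640)
    block_gc_range: tuple[float, float] = (0.50, 0.60)
    zero_divergence_blocks: bool = True
    block_rate: float = 0.0
    # duplications: whole pair loci copied verbatim elsewhere on the reference
    n_duplications: int = 2
    duplication_block_len: tuple[int, int] = (110, 120)
    duplication_margin: int = 150
    # gene architecture
    p_intron: float = 0.6
    n_extra_genes: int = 4
    exon_len_range: tuple[int, int] = (200, 500)
    intron_len_range: tuple[int, int] = (150, 450)
    utr5_len_range: tuple[int, int] = (40, 120)
    utr3_len_range: tuple[int, int] = (60, 140)
    intergenic_range: tuple[int, int] = (200, 800)
    block_outer_margin: int = 300
    block_inner_margin: int = 30
    # read model
    coverage: float = 5.0
    read_len_min: int = 40
    read_len_median: int = 352
    read_len_max: int = 1188
    read_len_sigma: float = 0.45
    error_rate: float = 0.002
    depth_floor: int = 3
    contig_id: str = "chr1"

    def __post_init__(self):
        for rate in (self.substitution_rate, self.block_rate, self.error_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.substitution_rate > 0.3:
            raise ValueError("substitution_rate above 0.3 is outside the model")


@dataclass
class PlantedPair:
    left: GenomicInterval
    right: GenomicInterval
    gene_id: str
    kind: str  # 'EPIC' | 'NPCL'
    duplicated: bool = False

    @property
    def gap(self) -> int:
        return self.right.start - self.left.end


@dataclass
class GroundTruth:
    contig_id: str
    blocks: list[GenomicInterval] = field(default_factory=list)
    pairs: list[PlantedPair] = field(default_factory=list)
    duplications: list[dict] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)

    def to_json(self, path) -> None:
        def iv(i: GenomicInterval) -> dict:
            return {"contig": i.contig_id, "start": i.start, "end": i.end}

        payload = {
            "contig_id": self.contig_id,
            "blocks": [iv(b) for b in self.blocks],
            "pairs": [
                {
                    "left": iv(p.left),
                    "right": iv(p.right),
                    "gene_id": p.gene_id,
                    "kind": p.kind,
                    "duplicated": p.duplicated,
                    "gap": p.gap,
                }
                for p in self.pairs
            ],
            "duplications": self.duplications,
            "genes": [
                {
                    "gene_id": gm.gene_id,
                    "strand": gm.strand,
                    "exons": [iv(e) for e in gm.exons],
                    "cds": [iv(c) for c in gm.cds],
                }
                for gm in self.gene_models
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------

def simulate_reference(
    spec: SimulationSpec,
) -> tuple[GenomeSequence, list[GeneModel], GroundTruth]:
    """Build the reference genome, its gene models, and the ground truth.

    Genes are laid out left to right with random intergenic gaps; each planted
    pair locus is either an EPIC gene (blocks in two exons flanking one intron
    sized so the genomic inner gap hits the target window) or an NPCL gene
    (both blocks in one exon). Duplicated loci are copied verbatim, with a
    flanking margin, into intergenic space downstream. Deterministic for a
    given rng_seed; raises when the layout does not fit the genome.
    """
    rng = np.random.default_rng([spec.rng_seed, 101])
    m_out = spec.block_outer_margin
    m_in = spec.block_inner_margin
    truth = GroundTruth(contig_id=spec.contig_id)
    genes: list[GeneModel] = []
    cursor = int(rng.integers(*spec.intergenic_range))
    gene_no = 0

    # interleave pair loci and featureless extra genes deterministically
    locus_kinds = ["pair"] * spec.n_block_pairs + ["extra"] * spec.n_extra_genes
    locus_kinds = [locus_kinds[i] for i in rng.permutation(len(locus_kinds))]
    n_pair_seen = 0
    dup_pair_indices = set(
        range(spec.n_block_pairs - spec.n_duplications, spec.n_block_pairs)
    )

    for kind in locus_kinds:
        gene_no += 1
        gene_id = f"gene{gene_no:04d}"
        gstart = cursor
        exons: list[GenomicInterval] = []
        if kind == "pair":
            is_dup = n_pair_seen in dup_pair_indices
            lo, hi = (
                spec.duplication_block_len if is_dup else spec.block_len_range
            )
            lb = int(rng.integers(lo, hi + 1))
            rb = int(rng.integers(lo, hi + 1))
            gap = int(rng.integers(*spec.block_gap_range))
            epic = bool(rng.random() < spec.p_intron)
            if epic and gap > 2 * m_in + spec.intron_len_range[0]:
                e1 = GenomicInterval(
                    spec.contig_id, gstart, gstart + m_out + lb + m_in
                )
                intron_len = gap - 2 * m_in
                e2s = e1.end + intron_len
                e2 = GenomicInterval(spec.contig_id, e2s, e2s + m_in + rb + m_out)
                exons = [e1, e2]
                left = GenomicInterval(
                    spec.contig_id, gstart + m_out, gstart + m_out + lb
                )
                right = GenomicInterval(spec.contig_id, e2s + m_in, e2s + m_in + rb)
                pkind = "EPIC"
            else:
                e1 = GenomicInterval(
                    spec.contig_id, gstart, gstart + m_out + lb + gap + rb + m_out
                )
                exons = [e1]
                left = GenomicInterval(
                    spec.contig_id, gstart + m_out, gstart + m_out + lb
                )
                rs = gstart + m_out + lb + gap
                right = GenomicInterval(spec.contig_id, rs, rs + rb)
                pkind = "NPCL"
            truth.blocks.extend([left, right])
            truth.pairs.append(
                PlantedPair(left, right, gene_id, pkind, duplicated=is_dup)
            )
            n_pair_seen += 1
        else:
            n_ex = 1 + int(rng.random() < spec.p_intron) + int(rng.random() < 0.3)
            pos = gstart
            for i in range(n_ex):
                elen = int(rng.integers(*spec.exon_len_range))
                exons.append(GenomicInterval(spec.contig_id, pos, pos + elen))
                if i < n_ex - 1:
                    pos = pos + elen + int(rng.integers(*spec.intron_len_range))
        # CDS = exon space minus UTR margins at the transcript ends
        utr5 = int(rng.integers(*spec.utr5_len_range))
        utr3 = int(rng.integers(*spec.utr3_len_range))
        cds_lo = exons[0].start + utr5
        cds_hi = exons[-1].end - utr3
        cds = []
        for ex in exons:
            lo2, hi2 = max(ex.start, cds_lo), min(ex.end, cds_hi)
            if lo2 < hi2:
                cds.append(GenomicInterval(spec.contig_id, lo2, hi2))
        genes.append(
            GeneModel(gene_id, spec.contig_id, "+", exons, cds)
        )
        cursor = exons[-1].end + int(rng.integers(*spec.intergenic_range))

    # duplicate loci: copy span (with margin) into downstream intergenic space
    dup_specs = []
    for pair in truth.pairs:
        if pair.duplicated:
            src = GenomicInterval(
                spec.contig_id,
                max(0, pair.left.start - spec.duplication_margin),
                pair.right.end + spec.duplication_margin,
            )
            dest_start = cursor
            cursor = dest_start + src.length + int(
                rng.integers(*spec.intergenic_range)
            )
            dup_specs.append((src, dest_start, pair.gene_id))

    if cursor > spec.genome_length:
        raise ValueError(
            f"infeasible packing: layout needs {cursor} bp, genome is "
            f"{spec.genome_length} bp"
        )

    arr = _random_seq(rng, spec.genome_length, spec.genome_gc)
    for block in truth.blocks:
        gc = float(rng.uniform(*spec.block_gc_range))
        arr[block.start:block.end] = _random_seq(rng, block.length, gc)
    for src, dest_start, gene_id in dup_specs:
        arr[dest_start:dest_start + src.length] = arr[src.start:src.end]
        truth.duplications.append(
            {
                "gene_id": gene_id,
                "src": {"start": src.start, "end": src.end},
                "dest": {"start": dest_start, "end": dest_start + src.length},
            }
        )

    genome = GenomeSequence(spec.contig_id, arr.tobytes().decode("ascii"))
    truth.gene_models = genes
    return genome, genes, truth


# ---------------------------------------------------------------------------
# species evolution
# ---------------------------------------------------------------------------

def evolve_species(
    reference: GenomeSequence,
    truth: GroundTruth,
    spec: SimulationSpec,
    species_id: str,
) -> GenomeSequence:
    """Apply i.i.d. substitutions at the species rate everywhere except planted
    conserved blocks (rate 0, or block_rate when zero-divergence is off)."""
    seed = [spec.rng_seed, 202, zlib.crc32(species_id.encode()) & 0x7FFFFFFF]
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8).copy()
    rate = np.full(len(arr), spec.substitution_rate)
    block_rate = 0.0 if spec.zero_divergence_blocks else spec.block_rate
    for block in truth.blocks:
        rate[block.start:block.end] = block_rate
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if hit.size:
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=hit.size)
        code = np.searchsorted(_BASES, arr[hit])  # ACGT are sorted bytes
        arr[hit] = _BASES[(code + shift) % 4]
    return GenomeSequence(reference.contig_id, arr.tobytes().decode("ascii"))


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    qualities: list[int]
    ref_start: int
    cigar: list[tuple[int, int]]  # pysam op codes
    nm: int
    aligned_cols: int


def _read_length(rng: np.random.Generator, spec: SimulationSpec) -> int:
    ln = rng.lognormal(np.log(spec.read_len_median), spec.read_len_sigma)
    return int(np.clip(ln, spec.read_len_min, spec.read_len_max))


def simulate_reads(
    species_genome: GenomeSequence,
    gene_models: list[GeneModel],
    spec: SimulationSpec,
    species_id: str,
    reference: GenomeSequence,
) -> list[SimulatedRead]:
    """Sample reads from exon-concatenated transcripts of the species genome.

    Starts are jittered tilings at spacing median_length/coverage (stratified
    sampling); lengths follow a clipped lognormal matching the long-read
    profile; sequencing errors are i.i.d. substitutions at the spec rate.
    A top-up pass then adds reads wherever transcript depth would fall below
    depth_floor — normalized libraries are sequenced to an even depth, and
    without the floor, runs of short reads open sub-threshold coverage holes
    that would make region calling measure sampling noise. Each read carries
    its true placement: M segments over exons with N skips over introns, and
    NM counted against the reference.
    """
    seed = [spec.rng_seed, 303, zlib.crc32(species_id.encode()) & 0x7FFFFFFF]
    rng = np.random.default_rng(seed)
    ref_arr = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    sp_arr = np.frombuffer(
        species_genome.sequence.encode("ascii"), dtype=np.uint8
    )
    reads: list[SimulatedRead] = []
    step = max(1, int(spec.read_len_median / spec.coverage))
    for gm in gene_models:
        # transcript coordinate map: cumulative exon offsets
        exon_offsets = []
        t_len = 0
        for ex in gm.exons:
            exon_offsets.append((t_len, ex))
            t_len += ex.length
        spans: list[tuple[int, int]] = []
        n_windows = max(1, int(np.ceil(t_len / step)))
        for w in range(n_windows):
            start = w * step + int(rng.integers(0, step))
            if start >= t_len:
                continue
            length = min(_read_length(rng, spec), t_len - start)
            if length >= spec.read_len_min:
                spans.append((start, length))
        # top-up: keep interior depth at or above the floor
        depth = np.zeros(t_len + 1, dtype=np.int32)
        for s, ln in spans:
            depth[s] += 1
            depth[s + ln] -= 1
        depth = np.cumsum(depth[:-1])
        lo_edge = min(step, t_len)  # tiling cannot stack depth at the edges
        hi_edge = max(0, t_len - spec.read_len_min)
        while True:
            low = np.flatnonzero(depth[lo_edge:hi_edge] < spec.depth_floor)
            if low.size == 0:
                break
            p = int(low[0]) + lo_edge
            length = min(_read_length(rng, spec), t_len)
            start = max(0, min(p - length // 2, t_len - length))
            spans.append((start, length))
            depth[start:start + length] += 1
        spans.sort()
        for k, (start, length) in enumerate(spans, 1):
            # genomic blocks covered by transcript span [start, start+length)
            blocks: list[tuple[int, int]] = []
            for t_off, ex in exon_offsets:
                lo = max(start, t_off)
                hi = min(start + length, t_off + ex.length)
                if lo < hi:
                    g_lo = ex.start + (lo - t_off)
                    blocks.append((g_lo, g_lo + (hi - lo)))
            seq = np.concatenate([sp_arr[a:b] for a, b in blocks]).copy()
            err = np.flatnonzero(rng.random(length) < spec.error_rate)
            if err.size:
                shift = rng.integers(1, 4, size=err.size)
                code = np.searchsorted(_BASES, seq[err])
                seq[err] = _BASES[(code + shift) % 4]
            ref_concat = np.concatenate([ref_arr[a:b] for a, b in blocks])
            nm = int((seq != ref_concat).sum())
            cigar: list[tuple[int, int]] = []
            for i, (a, b) in enumerate(blocks):
                if i:
                    cigar.append((3, a - blocks[i - 1][1]))  # N
                cigar.append((0, b - a))  # M
            qual = np.clip(
                np.round(
                    38.0
                    - 16.0 * (start + np.arange(length)) / 1100.0
                    + rng.normal(0.0, 2.0, size=length)
                ),
                2,
                40,
            ).astype(int)
            reads.append(
                SimulatedRead(
                    read_id=f"{species_id}_{gm.gene_id}_r{k:04d}",
                    sequence=seq.tobytes().decode("ascii"),
                    qualities=list(qual),
                    ref_start=blocks[0][0],
                    cigar=cigar,
                    nm=nm,
                    aligned_cols=length,
                )
            )
    reads.sort(key=lambda r: (r.ref_start, r.read_id))
    return reads


def write_reads_fastq(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qline = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qline}\n")


def write_truth_sam(
    reads: list[SimulatedRead], reference: GenomeSequence, path
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": reference.contig_id, "LN": len(reference.sequence)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 0
            a.reference_id = 0
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigartuples = r.cigar
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            a.set_tag("NM", r.nm)
            out.write(a)


# ---------------------------------------------------------------------------
# one-call fixture emission
# ---------------------------------------------------------------------------

def simulate_fixture(spec: SimulationSpec, outdir) -> dict:
    """Emit the full fixture to a directory; returns a manifest of paths.

    Files: reference FASTA, GFF3 gene models, per-species FASTQ + truth SAM,
    planted blocks BED, ground-truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_reference(spec)
    paths = {
        "genome": str(outdir / "reference.fasta"),
        "gff3": str(outdir / "genes.gff3"),
        "blocks_bed": str(outdir / "planted_blocks.bed"),
        "truth_json": str(outdir / "truth.json"),
        "species": {},
    }
    write_fasta([genome], paths["genome"])
    write_gff3(genes, paths["gff3"])
    write_bed(
        [
            (b, f"block{i:03d}", 0.0, "+")
            for i, b in enumerate(truth.blocks)
        ],
        paths["blocks_bed"],
    )
    truth.to_json(paths["truth_json"])
    for s in range(spec.n_species):
        sp = f"species{chr(ord('A') + s)}"
        sp_genome = evolve_species(genome, truth, spec, sp)
        reads = simulate_reads(sp_genome, genes, spec, sp, genome)
        fq = str(outdir / f"{sp}.fastq")
        sam = str(outdir / f"{sp}.sam")
        write_reads_fastq(reads, fq)
        write_truth_sam(reads, genome, sam)
        paths["species"][sp] = {"fastq": fq, "sam": sam, "n_reads": len(reads)}
    return paths
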