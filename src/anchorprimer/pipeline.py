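"""End-to-end orchestration: SAM ingest → mapped regions → conserved anchors →
anchor pairs → primer design → in-silico specificity → annotation → report,
with a machine-readable run manifest, plus the independent constraint
validator."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotation_stats import classify_marker
from .conservation import (
    PipelineConfig,
    build_majority_pileup,
    call_conserved_anchors,
    call_mapped_regions,
    coverage_tracks,
    intersect_species,
    pair_anchors,
)
from .primer_design import melting_temperature, select_primer_pair
from .seqio import (
    GenomicInterval,
    filter_alignments,
    read_fasta,
    read_gff3,
    read_sam,
    write_bed,
    write_primer_table,
)
from .specificity import GenomeIndex, enumerate_amplicons, find_primer_sites, specificity_verdict
from .util import file_sha256, reverse_complement

log = logging.getLogger("anchorprimer")


@dataclass
class RunManifest:
    config: dict
    inputs: dict
    counts: dict = field(default_factory=dict)
    version: str = __version__
    rng_seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _stage(name: str, msg: str) -> None:
    log.info("[%s] %s", name, msg)


def run_pipeline(
    config: PipelineConfig,
    genome_path,
    sam_paths: dict[str, str],
    gff_path=None,
    outdir="pipeline_out",
) -> RunManifest:
    """Run the full discovery workflow and write all intermediates.

    sam_paths maps species_id -> coordinate-sorted SAM against the reference.
    Outputs under outdir: per-species regions BED, anchors BED, anchor-pairs
    BED, primer table TSV, amplicons BED, verdict audit TSV, manifest JSON.
    Deterministic for identical inputs and config.
    """
    if not sam_paths:
        raise ValueError("no species alignments given: at least one SAM required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        inputs={
            "genome": file_sha256(str(genome_path)),
            **{sp: file_sha256(str(p)) for sp, p in sorted(sam_paths.items())},
        },
        rng_seed=config.rng_seed,
    )

    _stage("ingest", f"reading genome {genome_path}")
    genome = read_fasta(genome_path)
    gene_models = read_gff3(gff_path) if gff_path else []

    regions_by_species = {}
    kept_ids: dict[str, set[str]] = {}
    for sp in sorted(sam_paths):
        records = list(
            filter_alignments(
                read_sam(sam_paths[sp]),
                min_aligned_fraction=config.min_aligned_fraction,
                min_identity=config.min_identity,
                primary_only=config.primary_only,
            )
        )
        kept_ids[sp] = {r.read_id for r in records}
        tracks = coverage_tracks(records, genome)
        regions = []
        for cid in sorted(tracks):
            regions.extend(
                call_mapped_regions(
                    tracks[cid], config.min_anchor_len, config.min_cov, sp
                )
            )
        regions_by_species[sp] = regions
        write_bed(
            [
                (r.interval, f"{sp}_region{i:04d}", round(r.mean_depth, 2), "+")
                for i, r in enumerate(regions)
            ],
            outdir / f"regions_{sp}.bed",
        )
        _stage("regions", f"{sp}: {len(records)} filtered records, {len(regions)} regions")

    intervals = intersect_species(regions_by_species)
    _stage("intersect", f"{len(intervals)} shared intervals")

    pileups = {
        sp: build_majority_pileup(sam_paths[sp], genome, keep_ids=kept_ids[sp])
        for sp in sorted(sam_paths)
    }
    anchors = call_conserved_anchors(
        intervals, pileups, genome, config, regions_by_species
    )
    write_bed(
        [
            (
                a.interval,
                f"anchor{i:04d}",
                round(min(a.per_species_identity.values(), default=1.0), 3),
                "+",
            )
            for i, a in enumerate(anchors)
        ],
        outdir / "anchors.bed",
    )
    _stage("anchors", f"{len(anchors)} conserved anchors")

    pairs = pair_anchors(anchors, config.min_gap, config.max_gap)
    write_bed(
        [
            (p.target_span, f"pair{i:04d}", p.gap, "+")
            for i, p in enumerate(pairs)
        ],
        outdir / "anchor_pairs.bed",
    )
    _stage("pairs", f"{len(pairs)} anchor pairs in [{config.min_gap},{config.max_gap}]")

    index = GenomeIndex(genome)
    table_rows = []
    verdict_rows = []
    amplicon_rows = []
    n_unique = n_multi = n_none = n_nocand = 0
    for i, pair in enumerate(pairs):
        pair_id = f"pair{i:04d}"
        designed = select_primer_pair(pair, config, pair_id)
        if designed is None:
            n_nocand += 1
            verdict_rows.append((pair_id, "no_candidates", 0, ""))
            continue
        verdict = specificity_verdict(designed, index, config)
        coords = ";".join(
            f"{a.interval.contig_id}:{a.interval.start + 1}-{a.interval.end}"
            for a in verdict.amplicons
        )
        verdict_rows.append((pair_id, verdict.status, verdict.n_products, coords))
        if verdict.status != "unique":
            if verdict.status == "multiple":
                n_multi += 1
            else:
                n_none += 1
            continue
        n_unique += 1
        amp = verdict.amplicons[0]
        amplicon_rows.append((amp.interval, pair_id, amp.length, "+"))
        ann = classify_marker(amp, gene_models, pair_id)
        fwd, rev = designed.forward, designed.reverse
        table_rows.append(
            {
                "pair_id": pair_id,
                "gene_id": ",".join(ann.gene_ids) or "-",
                "marker_class": ann.marker_class,
                "structure_code": ann.structure_code,
                "contig": fwd.ref_interval.contig_id,
                "fwd_start": fwd.ref_interval.start + 1,
                "fwd_end": fwd.ref_interval.end,
                "rev_start": rev.ref_interval.start + 1,
                "rev_end": rev.ref_interval.end,
                "fwd_seq": fwd.sequence,
                "rev_seq": rev.sequence,
                "fwd_tm": fwd.tm,
                "rev_tm": rev.tm,
                "fwd_gc": fwd.gc,
                "rev_gc": rev.gc,
                "gap": pair.gap,
                "product_len_ref": designed.product_interval.length,
                "n_predicted_products": verdict.n_products,
            }
        )
    write_primer_table(table_rows, outdir / "primer_table.tsv")
    write_bed(amplicon_rows, outdir / "amplicons.bed")
    with open(outdir / "verdicts.tsv", "w") as fh:
        fh.write("pair_id\tverdict\tn_products\tproduct_coords\n")
        for row in verdict_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    _stage(
        "specificity",
        f"{n_unique} unique, {n_multi} multi-product, {n_none} productless, "
        f"{n_nocand} without candidates",
    )

    manifest.counts = {
        "regions": {sp: len(r) for sp, r in regions_by_species.items()},
        "intervals": len(intervals),
        "anchors": len(anchors),
        "pairs": len(pairs),
        "designed": len(pairs),
        "unique": n_unique,
        "discarded_multi": n_multi,
        "discarded_none": n_none,
        "constraint_failed": n_nocand,
    }
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# independent validator
# ---------------------------------------------------------------------------

def validate_primer_table(table_path, genome_path, config: PipelineConfig) -> list[str]:
    """Re-check every published constraint on a final primer table against the
    genome and config, independently of how the table was produced.

    Returns a list of violation messages (empty when the table is clean):
    primer length in [len_min, len_max], Tm recomputed from the sequence in
    [tm_min, tm_max], inner gap in [min_gap, max_gap], primer sequences match
    the reference at their coordinates, and the pair yields exactly one
    in-silico product within the size cap under the mismatch budget.
    """
    genome = read_fasta(genome_path)
    index = GenomeIndex(genome)
    seqs = {g.contig_id: g.sequence for g in genome}
    violations: list[str] = []
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            pid = row["pair_id"]
            fwd, rev = row["fwd_seq"], row["rev_seq"]
            for label, seq in (("fwd", fwd), ("rev", rev)):
                if not (
                    config.primer_len_min <= len(seq) <= config.primer_len_max
                ):
                    violations.append(f"{pid}: {label} length {len(seq)} outside bounds")
                tm = melting_temperature(seq, config.monovalent_mM, config.primer_nM)
                if not (config.tm_min <= tm <= config.tm_max):
                    violations.append(f"{pid}: {label} Tm {tm:.2f} outside bounds")
            cid = row["contig"]
            f_iv = GenomicInterval(cid, int(row["fwd_start"]) - 1, int(row["fwd_end"]))
            r_iv = GenomicInterval(cid, int(row["rev_start"]) - 1, int(row["rev_end"]))
            ref_f = seqs[cid][f_iv.start:f_iv.end]
            ref_r = seqs[cid][r_iv.start:r_iv.end]
            if ref_f != fwd:
                violations.append(f"{pid}: fwd sequence does not match reference")
            if reverse_complement(ref_r) != rev:
                violations.append(f"{pid}: rev sequence does not match reference")
            gap = r_iv.start - f_iv.end
            # inner gap between the anchors bounds the primer gap; the table
            # stores the anchor gap explicitly
            table_gap = int(row["gap"])
            if not (config.min_gap <= table_gap <= config.max_gap):
                violations.append(f"{pid}: anchor gap {table_gap} outside bounds")
            if gap <= 0:
                violations.append(f"{pid}: primers overlap or are out of order")
            sites_f = find_primer_sites(
                fwd, index, config.max_mismatches, f"{pid}/F",
                config.strict_three_prime,
            )
            sites_r = find_primer_sites(
                rev, index, config.max_mismatches, f"{pid}/R",
                config.strict_three_prime,
            )
            amps = enumerate_amplicons(
                sites_f, sites_r, config.max_product, config.include_self_pairs
            )
            if len(amps) != 1:
                violations.append(
                    f"{pid}: expected a unique product, found {len(amps)}"
                )
            elif amps[0].length > config.max_product:
                violations.append(f"{pid}: product exceeds size cap")
    return violations
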