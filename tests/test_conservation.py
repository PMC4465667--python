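"""conservation: coverage, region calling, intersection, anchors, pairing."""

import random

import numpy as np
import pytest

from anchorprimer.conservation import (
    CoverageTrack,
    MappedRegion,
    PipelineConfig,
    call_conserved_anchors,
    call_mapped_regions,
    coverage_tracks,
    build_majority_pileup,
    intersect_species,
    pair_anchors,
)
from anchorprimer.seqio import GenomeSequence, GenomicInterval, ReadAlignmentRecord


def _rec(start, end, name="r", contig="c1"):
    return ReadAlignmentRecord(
        name, GenomicInterval(contig, start, end), 60, 1.0, 1.0, True
    )


GENOME = [GenomeSequence("c1", "A" * 500)]


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


def test_coverage_single_and_overlapping_records():
    tracks = coverage_tracks([_rec(10, 60)], GENOME)
    d = tracks["c1"].depth
    assert d[10:60].tolist() == [1] * 50 and d.sum() == 50
    tracks = coverage_tracks([_rec(10, 60), _rec(10, 60)], GENOME)
    assert (tracks["c1"].depth[10:60] == 2).all()


def test_coverage_out_of_bounds_is_error():
    with pytest.raises(ValueError, match="beyond contig bounds"):
        coverage_tracks([_rec(490, 510)], GENOME)


def test_coverage_matches_membership_oracle():
    rng = random.Random(11)
    recs = []
    for i in range(500):
        s = rng.randrange(0, 480)
        recs.append(_rec(s, min(500, s + rng.randint(1, 80)), name=f"r{i}"))
    depth = coverage_tracks(recs, GENOME)["c1"].depth
    oracle = [
        sum(1 for r in recs if r.interval.start <= pos < r.interval.end)
        for pos in range(500)
    ]
    assert depth.tolist() == oracle


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------


def _regions_oracle(depth, min_len, min_cov):
    """Brute-force run scanner independent of the numpy implementation."""
    out, run_start = [], None
    for i, d in enumerate(list(depth) + [0]):
        if d >= min_cov and run_start is None:
            run_start = i
        elif d < min_cov and run_start is not None:
            if i - run_start >= min_len:
                out.append((run_start, i))
            run_start = None
    return out


def test_call_mapped_regions_trivial_cases():
    assert call_mapped_regions(CoverageTrack("c1", np.zeros(100))) == []
    d = np.zeros(100); d[10:35] = 3
    (reg,) = call_mapped_regions(CoverageTrack("c1", d))
    assert (reg.interval.start, reg.interval.end) == (10, 35)
    assert reg.mean_depth == 3.0
    d = np.zeros(100); d[10:29] = 5  # length 19: below the length floor
    assert call_mapped_regions(CoverageTrack("c1", d)) == []


def test_call_mapped_regions_matches_oracle_and_is_maximal():
    rng = np.random.default_rng(7)
    for _ in range(50):
        depth = rng.integers(0, 4, size=200)
        regs = call_mapped_regions(CoverageTrack("c1", depth), min_len=5, min_cov=2)
        got = [(r.interval.start, r.interval.end) for r in regs]
        assert got == _regions_oracle(depth, 5, 2)
        for s, e in got:  # maximality: one-base extension violates the contract
            assert s == 0 or depth[s - 1] < 2
            assert e == len(depth) or depth[e] < 2


def test_region_thresholds_are_monotone():
    rng = np.random.default_rng(3)
    depth = rng.integers(0, 5, size=300)
    base = {(r.interval.start, r.interval.end)
            for r in call_mapped_regions(CoverageTrack("c1", depth), 5, 2)}
    stricter_cov = {(r.interval.start, r.interval.end)
                    for r in call_mapped_regions(CoverageTrack("c1", depth), 5, 3)}
    stricter_len = {(r.interval.start, r.interval.end)
                    for r in call_mapped_regions(CoverageTrack("c1", depth), 10, 2)}
    # raising min_cov can only shrink/split runs; raising min_len only removes
    assert all(any(s >= bs and e <= be for bs, be in base) for s, e in stricter_cov)
    assert stricter_len <= base


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------


def _mk_regions(ivs, sp="s"):
    return [MappedRegion(sp, GenomicInterval("c1", a, b), 2.0) for a, b in ivs]


def test_intersect_identical_and_disjoint():
    regs = _mk_regions([(0, 50), (100, 200)])
    same = intersect_species({"a": regs, "b": regs})
    assert [(iv.start, iv.end) for iv in same] == [(0, 50), (100, 200)]
    out = intersect_species(
        {"a": _mk_regions([(0, 50)]), "b": _mk_regions([(60, 90)])}
    )
    assert out == []


def test_intersect_matches_bitmap_oracle_and_order_invariance():
    rng = random.Random(23)
    for _ in range(30):
        species = {}
        for s in range(rng.randint(1, 4)):
            ivs, pos = [], 0
            while pos < 280:
                a = pos + rng.randint(0, 30)
                b = a + rng.randint(1, 50)
                if b > 300:
                    break
                ivs.append((a, b))
                pos = b + 1
            species[f"s{s}"] = _mk_regions(ivs, f"s{s}")
        got = intersect_species(species)
        bitmap = np.ones(300, dtype=bool)
        for regs in species.values():
            mask = np.zeros(300, dtype=bool)
            for r in regs:
                mask[r.interval.start:r.interval.end] = True
            bitmap &= mask
        padded = np.concatenate(([False], bitmap, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        expected = list(zip(edges[::2].tolist(), edges[1::2].tolist()))
        assert [(iv.start, iv.end) for iv in got] == expected
        # species-order invariance
        reordered = dict(reversed(list(species.items())))
        assert intersect_species(reordered) == got


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------


def _write_sam(path, genome_seq, reads):
    """reads: list of (name, start, seq)."""
    lines = [f"@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:c1\tLN:{len(genome_seq)}"]
    for name, start, seq in reads:
        lines.append(
            f"{name}\t0\tc1\t{start + 1}\t60\t{len(seq)}M\t*\t0\t0\t{seq}\t*\tNM:i:0"
        )
    path.write_text("\n".join(lines) + "\n")


def test_anchor_identity_one_when_reads_match_reference(tmp_path):
    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    genome = [GenomeSequence("c1", seq)]
    sam = tmp_path / "a.sam"
    _write_sam(sam, seq, [("r1", 20, seq[20:150]), ("r2", 30, seq[30:160])])
    pileups = {"spA": build_majority_pileup(sam, genome)}
    config = PipelineConfig()
    anchors = call_conserved_anchors(
        [GenomicInterval("c1", 30, 150)], pileups, genome, config
    )
    (a,) = anchors
    assert a.per_species_identity == {"spA": 1.0}
    assert a.interval == GenomicInterval("c1", 30, 150)
    assert a.consensus == seq[30:150]


def test_anchor_rejected_when_one_species_diverges(tmp_path):
    """A species at ~10% uniform divergence fails the 0.95 identity screen."""
    rng = random.Random(9)
    seq = "".join(rng.choice("ACGT") for _ in range(200))
    genome = [GenomeSequence("c1", seq)]
    div = list(seq)
    for i in range(0, 200, 10):  # exactly 10% divergence
        div[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[div[i]]
    div = "".join(div)
    sam_a = tmp_path / "a.sam"
    sam_b = tmp_path / "b.sam"
    _write_sam(sam_a, seq, [("r1", 0, seq), ("r2", 0, seq)])
    _write_sam(sam_b, seq, [("r1", 0, div), ("r2", 0, div)])
    genome_list = genome
    pileups = {
        "spA": build_majority_pileup(sam_a, genome_list),
        "spB": build_majority_pileup(sam_b, genome_list),
    }
    config = PipelineConfig()
    whole = call_conserved_anchors(
        [GenomicInterval("c1", 0, 200)], pileups, genome_list, config, trim=False
    )
    assert whole == []  # identity 0.90 < 0.95
    trimmed = call_conserved_anchors(
        [GenomicInterval("c1", 0, 200)], pileups, genome_list, config, trim=True
    )
    # trimming decomposes into all-agree runs; none reaches 20 bp here
    # (divergent site every 10 bp), so the interval yields nothing
    assert trimmed == []


def test_planted_blocks_recovered_with_high_jaccard(tmp_path):
    """At 20% background divergence, 150-250 bp zero-divergence blocks come
    back as anchors overlapping the planted intervals at Jaccard >= 0.9
    (strong contrast makes the all-species-agree boundary sharp)."""
    from anchorprimer.pipeline import run_pipeline
    from anchorprimer.synthetic import SimulationSpec, simulate_fixture

    spec = SimulationSpec(
        rng_seed=13,
        genome_length=60_000,
        substitution_rate=0.20,
        n_block_pairs=8,
        block_len_range=(150, 250),
        n_duplications=0,
        n_extra_genes=0,
    )
    paths = simulate_fixture(spec, tmp_path / "fx")
    config = PipelineConfig(min_identity=0.75)
    run_pipeline(
        config,
        paths["genome"],
        {sp: v["sam"] for sp, v in paths["species"].items()},
        paths["gff3"],
        tmp_path / "out",
    )
    import json
    from anchorprimer.seqio import read_bed

    truth = json.loads((tmp_path / "fx" / "truth.json").read_text())
    anchors = read_bed(tmp_path / "out" / "anchors.bed")
    for b in truth["blocks"]:
        best = 0.0
        for iv, *_ in anchors:
            inter = max(0, min(iv.end, b["end"]) - max(iv.start, b["start"]))
            union = (iv.end - iv.start) + (b["end"] - b["start"]) - inter
            best = max(best, inter / union)
        assert best >= 0.9, f"block {b} recovered with Jaccard {best:.2f}"


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def _anchor(start, end, contig="c1"):
    from anchorprimer.conservation import ConservedAnchor

    return ConservedAnchor(
        GenomicInterval(contig, start, end), "A" * (end - start), {}
    )


def test_pair_anchors_gap_window_inclusive():
    a, b = _anchor(0, 100), _anchor(600, 700)
    assert len(pair_anchors([a, b])) == 1  # gap 500
    assert pair_anchors([_anchor(0, 100), _anchor(399, 450)]) == []  # gap 299
    (p,) = pair_anchors([_anchor(0, 100), _anchor(400, 450)])  # gap 300
    assert p.gap == 300
    (p,) = pair_anchors([_anchor(0, 100), _anchor(800, 850)])  # gap 700
    assert p.gap == 700
    assert pair_anchors([_anchor(0, 100), _anchor(801, 850)]) == []


def test_pair_anchors_matches_quadratic_oracle_and_window_monotone():
    rng = random.Random(31)
    for _ in range(25):
        anchors, pos = [], 0
        while pos < 4000 and len(anchors) < 25:
            s = pos + rng.randint(0, 400)
            e = s + rng.randint(20, 120)
            anchors.append(_anchor(s, e))
            pos = e
        got = {
            (p.left.interval.start, p.right.interval.start)
            for p in pair_anchors(anchors, 300, 700)
        }
        oracle = {
            (a.interval.start, b.interval.start)
            for a in anchors
            for b in anchors
            if a.interval.end <= b.interval.start
            and 300 <= b.interval.start - a.interval.end <= 700
        }
        assert got == oracle
        wide = {
            (p.left.interval.start, p.right.interval.start)
            for p in pair_anchors(anchors, 200, 800)
        }
        assert got <= wide  # widening the window never removes pairs


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------


def test_config_file_accepts_primer3_names(tmp_path):
    p = tmp_path / "cfg"
    p.write_text(
        "PRIMER_MIN_SIZE = 19\nPRIMER_OPT_TM=59.5\nmin_gap = 250  # bp\n"
        "trim_anchors = false\n"
    )
    cfg = PipelineConfig.from_file(p)
    assert cfg.primer_len_min == 19
    assert cfg.tm_opt == 59.5
    assert cfg.min_gap == 250
    assert cfg.trim_anchors is False


def test_config_validation_errors(tmp_path):
    with pytest.raises(ValueError):
        PipelineConfig(min_gap=800, max_gap=700)
    with pytest.raises(ValueError):
        PipelineConfig(tm_min=63.0)
    p = tmp_path / "bad"
    p.write_text("no_such_key = 1\n")
    with pytest.raises(ValueError, match="unknown key"):
        PipelineConfig.from_file(p)
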