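"""annotation_stats: marker classification, PIC, diversity, pruning, report."""

import random

import numpy as np
import pytest

from anchorprimer.annotation_stats import (
    AlignmentMatrix,
    PruneRules,
    alignment_gc_percent,
    alignment_prune,
    classify_marker,
    count_pic,
    marker_report,
    nucleotide_diversity,
    pic_percent,
    repeat_mask,
    sequencing_success_pct,
    write_marker_report,
)
from anchorprimer.seqio import GeneModel, GenomicInterval
from anchorprimer.specificity import Amplicon, PrimerSite


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _gene(exons, cds, gene_id="g1"):
    return GeneModel(
        gene_id, "c1",
        "+",
        [GenomicInterval("c1", a, b) for a, b in exons],
        [GenomicInterval("c1", a, b) for a, b in cds],
    )


def _amplicon(start, end, plen=20):
    f = PrimerSite("F", GenomicInterval("c1", start, start + plen), "+", 0)
    r = PrimerSite("R", GenomicInterval("c1", end - plen, end), "-", 0)
    return Amplicon(GenomicInterval("c1", start, end), f, r)


# one gene: exons [100,400) and [600,900), CDS trimmed by UTRs
GENE = _gene([(100, 400), (600, 900)], [(150, 400), (600, 850)])


def test_classify_exonic_product_is_npcl():
    ann = classify_marker(_amplicon(160, 380), [GENE])
    assert ann.marker_class == "NPCL"
    assert ann.structure_code == "e"
    assert ann.intron_count == 0


def test_classify_intron_spanning_product_is_epic():
    ann = classify_marker(_amplicon(200, 800), [GENE])
    assert ann.marker_class == "EPIC"
    assert (ann.intron_count, ann.structure_code) == (1, "i")
    two_intron_gene = _gene(
        [(0, 200), (300, 500), (700, 900)], [(50, 200), (300, 500), (700, 850)]
    )
    ann2 = classify_marker(_amplicon(50, 850), [two_intron_gene])
    assert (ann2.marker_class, ann2.structure_code) == ("EPIC", "ii")


def test_classify_intergenic_and_utr_anchored():
    assert classify_marker(_amplicon(2000, 2400), [GENE]).marker_class == "intergenic"
    # forward primer wholly inside the 5' UTR [100,150)
    ann = classify_marker(_amplicon(105, 380), [GENE])
    assert ann.marker_class == "UTR_anchored"


def test_classify_intron_count_matches_bruteforce_on_simulator_models():
    from anchorprimer.synthetic import SimulationSpec, simulate_reference

    spec = SimulationSpec(rng_seed=4, n_block_pairs=8, n_extra_genes=4,
                          genome_length=60_000)
    _, genes, _ = simulate_reference(spec)
    rng = random.Random(2)
    span = genes[-1].span.end
    for _ in range(100):
        s = rng.randrange(0, span - 900)
        amp = Amplicon(
            GenomicInterval("chr1", s, s + rng.randint(100, 900)),
            PrimerSite("F", GenomicInterval("chr1", s, s + 20), "+", 0),
            PrimerSite("R", GenomicInterval("chr1", s + 80, s + 100), "-", 0),
        )
        ann = classify_marker(amp, genes)
        overl = [g for g in genes if g.span.overlaps(amp.interval)]
        if not overl:
            assert ann.marker_class == "intergenic"
            continue
        best = max(overl, key=lambda g: (g.span.overlap_len(amp.interval), g.gene_id))
        expected = sum(
            1
            for intr in best.introns
            if intr.start < amp.interval.end and amp.interval.start < intr.end
        )
        assert ann.intron_count == expected


# ---------------------------------------------------------------------------
# PIC
# ---------------------------------------------------------------------------


def test_count_pic_definition_cases():
    assert count_pic(AlignmentMatrix(list("abcd"), ["ACGT"] * 4)) == 0
    assert count_pic(AlignmentMatrix(list("abcd"), ["A", "A", "C", "C"])) == 1
    assert count_pic(AlignmentMatrix(list("abcd"), ["A", "A", "A", "C"])) == 0
    # gaps and ambiguity codes are missing data
    assert count_pic(AlignmentMatrix(list("abcd"), ["A", "A", "-", "R"])) == 0
    # first column: three states each twice -> informative; second column has
    # a single unambiguous state (T) -> not informative
    assert count_pic(AlignmentMatrix(list("abcdef"),
                                     ["AT", "AT", "C-", "CR", "GT", "GT"])) == 1


def test_count_pic_matches_column_oracle_and_permutation_invariance():
    rng = random.Random(13)
    for _ in range(20):
        rows = [
            "".join(rng.choice("ACGT-RY") for _ in range(200)) for _ in range(8)
        ]
        aln = AlignmentMatrix([f"s{i}" for i in range(8)], rows)
        expected = 0
        for col in zip(*rows):
            counts = {b: col.count(b) for b in "ACGT"}
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                expected += 1
        assert count_pic(aln) == expected
        perm = rng.sample(range(8), 8)
        assert count_pic(
            AlignmentMatrix([f"s{i}" for i in perm], [rows[i] for i in perm])
        ) == expected


def test_count_pic_ragged_is_error():
    with pytest.raises(ValueError, match="ragged"):
        AlignmentMatrix(["a", "b"], ["ACGT", "ACG"])


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def test_diversity_closed_forms():
    assert nucleotide_diversity(
        AlignmentMatrix(["a", "b", "c"], ["ACGTACGT"] * 3)
    ) == 0.0
    # two rows differing at 5 of 100 comparable sites
    row_a = "A" * 100
    row_b = "C" * 5 + "A" * 95
    assert nucleotide_diversity(AlignmentMatrix(["a", "b"], [row_a, row_b])) == pytest.approx(0.05)
    # pairwise deletion: gap/ambiguity columns drop out of the denominator
    row_c = "C" * 5 + "A" * 85 + "-" * 5 + "R" * 5
    assert nucleotide_diversity(AlignmentMatrix(["a", "b"], [row_a, row_c])) == pytest.approx(5 / 90)


def test_diversity_matches_double_loop_oracle():
    rng = random.Random(37)
    for _ in range(15):
        n = rng.randint(2, 7)
        rows = ["".join(rng.choice("ACGT-N") for _ in range(120)) for _ in range(n)]
        aln = AlignmentMatrix([f"s{i}" for i in range(n)], rows)
        dists = []
        for i in range(n):
            for j in range(i + 1, n):
                num = den = 0
                for a, b in zip(rows[i], rows[j]):
                    if a in "ACGT" and b in "ACGT":
                        den += 1
                        num += a != b
                if den:
                    dists.append(num / den)
        if not dists:
            continue
        got = nucleotide_diversity(aln)
        assert got == pytest.approx(sum(dists) / len(dists))
        assert 0.0 <= got <= 1.0


def test_diversity_warns_on_incomparable_pair():
    aln = AlignmentMatrix(["a", "b", "c"], ["AC", "A-", "-C"])
    with pytest.warns(UserWarning, match="no comparable sites"):
        nucleotide_diversity(aln)


# ---------------------------------------------------------------------------
# printed-percentage conventions
# ---------------------------------------------------------------------------


def test_pic_percent_printed_values():
    assert pic_percent(78, 398) == 19.6
    assert pic_percent(58, 725) == 8.0
    assert pic_percent(0, 300) == 0.0
    with pytest.raises(ValueError):
        pic_percent(1, 0)


def test_sequencing_success_printed_value():
    assert sequencing_success_pct(14, 15) == 93.3


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def test_prune_removes_long_monomer_run():
    rows = ["ACGT" + "A" * 10 + "CGTCGTAGC"] * 3
    aln = AlignmentMatrix(list("abc"), rows)
    pruned, mask = alignment_prune(aln)
    assert mask.sum() == 10
    assert pruned.rows[0] == "ACGT" + "CGTCGTAGC"


def test_prune_identity_when_no_repeats():
    rows = ["ACGTACGATCCGTAGACTTGCAG"] * 2
    aln = AlignmentMatrix(["a", "b"], rows)
    pruned, mask = alignment_prune(aln)
    assert not mask.any()
    assert pruned.rows == aln.rows


def test_prune_mask_matches_regex_oracle():
    import re

    rng = random.Random(43)
    rules = PruneRules()
    for _ in range(20):
        core = "".join(rng.choice("ACGT") for _ in range(150))
        insert_at = rng.randrange(0, 140)
        planted = core[:insert_at] + "AT" * 6 + core[insert_at:]
        aln = AlignmentMatrix(["a", "b"], [planted, planted])
        _, mask = alignment_prune(aln, rules)
        oracle = np.zeros(len(planted), dtype=bool)
        for m in re.finditer(r"(A{9,}|C{9,}|G{9,}|T{9,})", planted):
            oracle[m.start():m.end()] = True
        for k in range(1, 7):
            for m in re.finditer(rf"(?=([ACGT]{{{k}}})(?:\1){{{4},}})", planted):
                motif = m.group(1)
                j = m.start() + k
                while planted[j:j + k] == motif:
                    j += k
                oracle[m.start():j] = True
        assert (mask == oracle).all()


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def test_marker_report_composition_and_formatting(tmp_path):
    rng = random.Random(47)
    rows = ["".join(rng.choice("ACGT") for _ in range(398)) for _ in range(14)]
    aln = AlignmentMatrix([f"s{i}" for i in range(14)], rows)
    report = marker_report({"m1": aln}, n_attempted={"m1": 15})
    row = report.iloc[0]
    assert row["pic_count"] == count_pic(aln)
    assert row["pic_percent"] == pic_percent(count_pic(aln), 398)
    assert row["nucleotide_diversity"] == pytest.approx(nucleotide_diversity(aln))
    assert row["sequencing_success"] == 93.3
    out = tmp_path / "report.tsv"
    write_marker_report(report, out)
    text = out.read_text()
    assert "93.30%" in text  # trailing-zero display convention


def test_marker_report_empty_input_is_header_only(tmp_path):
    report = marker_report({})
    assert len(report) == 0
    out = tmp_path / "empty.tsv"
    write_marker_report(report, out)
    lines = out.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("marker_id")
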