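# Methods

## The discovery model

The pipeline operationalizes a simple idea: a genomic span that reads of
*every* query species cover at high identity against a common reference is a
candidate seat for a universal primer, and two such anchors at sequencing-
amplicon distance define a candidate marker. All coordinates are 0-based,
half-open internally; GFF3 (1-based closed) and displayed table coordinates
(1-based closed) are converted only at the I/O boundary, so interval
arithmetic uses a single convention throughout.

Assumptions worth stating explicitly:

* **The reference is the frame.** Anchors, primers and products live in
  reference coordinates and the anchor consensus *is* the reference sequence.
  Species pileups only inform the conservation screen. This matches the
  design goal — primers that work across the clade anchored on the annotated
  genome — and means divergence between a query species and the reference
  reduces anchor identity rather than shifting coordinates.
* **Conservation is majority-base identity.** Per species and position, the
  pileup majority base (ties resolved toward the reference, uncovered
  positions count as disagreement) is compared with the reference base.
  An intersected interval is decomposed into all maximal runs where every
  species agrees with the reference ("trimming", the default), or kept whole
  when its per-species identity clears `min_anchor_identity` (trim off).
  Decomposing into *all* maximal agree-runs (not only the longest) lets one
  intersected interval contribute several anchors, which is what allows more
  marker pairs than genes.
* **Coverage is span-based.** A read contributes depth over its aligned
  blocks; internal deletions stay covered, N (intron-skip) operations split
  the span. Multi-mappers are excluded by default (`primary_only`).
* **"Distance" is the inner gap** between anchors (right start − left end),
  not center-to-center: product length then equals gap plus the
  primer-bearing anchor ends, consistent with marker lengths a few hundred
  bases above the gap window.

## Tunable parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_aligned_fraction` | 0.80 | fraction of read | mapper minimum-overlap setting, re-expressed as a record filter |
| `min_identity` | 0.95 | fraction | mapper overlap-identity setting; lower it below 1 − (divergence + error) when the query species are more diverged |
| `min_cov` | 2 | reads | low on purpose, to suit small datasets |
| `min_anchor_len` | 20 | bp | the shortest span that can seat a primer |
| `min_anchor_identity` | 0.95 | fraction | mirrors the mapping identity setting |
| `min_gap`, `max_gap` | 300, 700 | bp | product sized for current sequencing platforms |
| `primer_len_{min,opt,max}` | 18, 20, 27 | nt | standard primer-design bounds |
| `tm_{min,opt,max}` | 58, 60, 62 | °C | standard annealing window |
| `max_mismatches` | 2 | nt | off-target site tolerance of the uniqueness screen |
| `max_product` | 3500 | bp | a real PCR can amplify this far; beyond it, convergent sites are ignored |
| `mapq_threshold` | 30 | phred | summary statistic cut ("MAPQ above 30") |
| `monovalent_mM`, `primer_nM` | 50, 50 | mM, nM | Tm conditions; conventional oligo-design defaults, surfaced because no published value fixes them |
| `max_homopolymer` | 4 | nt | added guard against slippage-prone primers |
| `self_comp_limit` | 5 | bp | reject 3′-terminal palindromes ≥ this length (minimal dimer guard) |
| `include_self_pairs` | true | — | F–F and R–R convergent site pairs count as products; a real PCR would amplify them |
| `strict_three_prime` | false | — | optional: require the 3′-terminal base to match at a site |

The config file accepts primer3-style names (`PRIMER_MIN_SIZE`,
`PRIMER_OPT_TM`, …) for the parameters that have one, so published settings
read directly onto it.

## Thermodynamics

Melting temperatures use the unified nearest-neighbor duplex parameters
(SantaLucia 1998 ΔH°/ΔS° table with terminal-pair initiation terms), entropy
salt correction ΔS°[Na⁺] = ΔS°[1 M] + 0.368 (N−1) ln[Na⁺], and
Tm = ΔH° / (ΔS° + R ln(C_T/4)) − 273.15 for non-self-complementary duplexes.
Enthalpy/entropy terms are summed with `math.fsum`, which is exact regardless
of summation order, so Tm(s) = Tm(reverse complement(s)) holds to the last
bit. The implementation is self-contained by design — the primer calls must
be reproducible from this package alone — and is cross-checked in the tests
against an independently coded table summation (to 0.01 °C) and against
Biopython's nearest-neighbor implementation of the same parameter family.

The pair penalty (step 5 in the README) is this package's own declared,
weight-configurable objective: the published workflow delegated scoring to an
external designer whose exact objective is not part of the method contract.
Dimer screening is deliberately minimal (3′ palindrome rejection only); a
full thermodynamic dimer/hairpin scan is out of scope.

## In-silico PCR

The site search is an exhaustive Hamming scan (substitutions only, no
indels): per primer and strand, mismatch counts for all windows are
accumulated vectorially and every site within the budget is reported. The
brute-force per-position oracle in the test suite is kept equivalent on
every tested instance; monotonicity in the mismatch budget and the product
cap is tested as a property. Palindromic self-hits deduplicate by
(contig, start, end). Products are counted over F×R and, by default, F×F and
R×R convergent combinations.

## Alignment statistics

* **PIC**: a column is parsimony-informative when ≥ 2 distinct unambiguous
  states (A/C/G/T) each occur in ≥ 2 sequences. Gaps and IUPAC ambiguity
  codes (the heterozygote convention) are missing data.
* **Nucleotide diversity**: mean over all unordered pairs of the p-distance
  with pairwise deletion; a pair with zero comparable sites is excluded with
  a warning. At n = 2 it equals the p-distance exactly. An ambiguity-aware
  fractional mode is deliberately not guessed at; missing-data treatment is
  the one defensible reading of the cited procedure.
* **Repeat pruning** removes consensus columns inside monomer runs > 8 bp or
  perfect tandem motif runs (motif 1–6 bp, ≥ 5 repeats); overlapping
  phase-shifted runs are caught by advancing the scan one column at a time.
* **Display conventions**: percentages round half-up to one decimal and print
  with two digits (`19.60%`); mapping-summary percentages print with one
  decimal; stored values are never rounded. The high-MAPQ percentage is
  relative to mapped reads, the mapped percentage to all reads — the
  convention under which the published summary arithmetic is self-consistent.

## What the synthetic generator emulates — and what it does not

`SimulationSpec` defaults define the reference scenario: 100 kb reference,
two query species at 8 % i.i.d. background substitution, 20 planted
zero-divergence block pairs (blocks 40–120 bp), two duplicated loci, and
transcript reads at 5× with a clipped-lognormal length profile
(min 40, median ≈ 352, max 1188 nt) and 0.2 % substitution errors.
Generator-design choices, made once:

* **Blocks are planted with primer-compatible composition** (GC 0.50–0.60):
  they represent anchors that *pass* a 58–62 °C design step, which skews
  GC-rich relative to bulk exome.
* **Planted inner gaps are drawn from [360, 640] bp**, inside the [300, 700]
  pairing window by a margin, because recovered anchors extend a few bases
  into the diverged flanks (geometrically distributed, mean ≈ 6 bp per side
  at 8 % divergence) and must not be pushed out of the window.
* **Blocks sit ≥ 300 bp inside their transcript** so they clear the
  coverage ramp at transcript starts.
* **Duplicated loci use 110–120 bp blocks** (primer feasibility is near
  certain at that length) and the copied span includes a 150 bp flanking
  margin so primers seated in slightly extended anchors still land inside
  the copy.
* **Reads are jitter-tiled, with a depth floor** (top-up reads wherever
  interior transcript depth would drop below 3). This emulates the flat
  coverage of a normalized library; without it, chance runs of short reads
  open sub-threshold holes and region calling would measure sampling noise
  rather than the method.
* **Majority-pileup ties resolve toward the reference base**, so isolated
  sequencing errors at 2× positions do not flip conservation calls.
* **Evolution is substitution-only** and genes sit on the + strand; truth
  alignments therefore stay gap-free and trivially oriented, which keeps the
  site-search and identity oracles exact. Indels, homopolymer
  (pyrosequencing-style) errors, expression variation and strandedness are
  *not* modeled — so passing tests demonstrate correctness of the method's
  logic under clean mapping, not robustness to real-library artifacts.

When running the pipeline on a fixture with planted background divergence
*d*, the read filter `min_identity` must sit below 1 − d − error (e.g. 0.85
at d = 0.08): reads then enter the pileup and the conservation decision is
made where it belongs, at the anchor-identity stage, whose threshold stays
at 0.95. The equivalent step in the original workflow happens inside the
mapper, which simply fails to map over-diverged reads.

## Numerical and degenerate-input choices

* Interval arithmetic rejects empty/inverted intervals at construction.
* `select_primer_pair` is an exact branch-and-bound over candidates ordered
  by individual penalty (the pair penalty is bounded below by the sum of the
  individual penalties); ties break by smaller product, leftmost forward
  start, then forward sequence, making the output byte-deterministic.
* An anchor pair with an empty candidate list on either side yields no pair
  (counted `constraint_failed` in the manifest); manifest counts satisfy
  designed = unique + multi + none + constraint_failed.
* SAM records whose identity cannot be computed (no NM/MD) are skipped and
  counted in a warning; unmapped records are dropped silently.
* Identity from SAM uses NM minus indel bases over aligned (M/=/X) columns.

## Problem sizes

The test suite and the acceptance script run the reference scenario at
100 kb / 2 species / ~700 reads, oracle-equivalence sweeps at 200 randomized
instances per operation on ≤ 4 kb search texts, and thermodynamic property
sweeps at 1,000 random oligos — sizes at which the whole suite completes in
well under a minute while every oracle remains exhaustively computable.

## Known limitations

* The uniqueness screen scans exactly the supplied FASTA; organellar or
  unplaced sequence is screened only if included.
* No spliced-anchor awareness beyond N-split coverage; anchors never span
  introns (by construction they are runs of covered agreement).
* The penalty is not a reimplementation of any external designer's
  objective; rankings may differ from primer3's even under identical bounds.
* Marker classification assigns one classifying gene (maximal overlap) per
  product; overlapping-gene edge cases list all gene ids but classify by one.
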