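# Methods

This note documents the models, algorithms and parameter choices behind
`archamp`, in the order the workflow runs. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external runs.

## Pairwise alignment

All alignment in the package is affine-gap Smith–Waterman–Gotoh (local) or
Gotoh (global), with a gap of length *L* costing `gap_open + gap_extend·L`.
Two scoring defaults exist for two different jobs:

* **Read/locus alignment** (`ScoringScheme()`): +2 match, −3 mismatch, gap
  open 5, extend 2 — conventional nucleotide-search values suited to ~5–10%
  divergent reads.
* **Panel alignment** (`MSA_SCORING`): same substitution scores with gap
  open 16, extend 6. Marker-gene panels are indel-sparse: near-equal-length
  sequences diverging almost entirely by substitutions. Under search-style
  penalties an aligner will occasionally buy a shift-by-one gap pair inside
  a ~35%-divergent hypervariable block because the double gap costs less
  than the chance matches it gains; the stiffer penalty makes such gap
  pairs strictly unprofitable at panel divergences, so substitution-only
  panels align colinearly (verified by test).

IUPAC handling: every symbol is a 4-bit base mask and two symbols match iff
their sets intersect. This single rule serves degenerate primers, ambiguous
reference bases and N's uniformly. Matches in a degenerate column count
toward identity.

Determinism: among equal-scoring cells the smallest end coordinate on the
first sequence, then on the second, wins; traceback prefers diagonal over
vertical over horizontal moves and closes gaps eagerly. Every downstream
result is therefore bit-reproducible.

The dynamic programs are numba-compiled; a low-memory score-only kernel
pre-selects the best reference per read, and the full traceback runs only
for the winner.

**Identity and coverage.** Pairwise similarity is `matches / columns` with
gap columns in the denominator (the stricter of the two common
conventions; the alternative — matches over read length — is noted as a
deliberate decision, not an oversight). Reference coverage is the aligned
reference span over reference length.

## Panel extraction

The 16S locus of each genome is the best local alignment of the reference
gene against either genome strand; minus-strand hits are reported in
forward-strand coordinates and the extracted sequence is reverse
complemented, so the whole panel shares the reference orientation.
Extraction addresses the genome (subject) side of the alignment — query
coordinates cannot address genome positions. One locus per genome (best
hit); multi-copy 16S operons are out of scope. Qualification thresholds
default to identity ≥ 0.70 and reference coverage ≥ 0.50 — deliberately
liberal, to admit divergent archaea; both are configurable, and genomes
that fail are listed with the failing criterion rather than dropped
silently. Precomputed 12-column tabular hits can substitute for the
internal aligner (`--hits`), taking the best bit-score hit per genome.

## Multiple alignment and conservation

The panel aligner is center-star: the center is the sequence maximizing
summed pairwise global scores; the others merge into it under "once a gap,
always a gap". At panel scale (≤ ~100 × 1.6 kb) this is exact enough —
the panels it aligns are ≥ 90% identical, where center-star and
progressive aligners coincide — and fully deterministic, which matters
more here than optimality. External alignments (aligned FASTA or Clustal)
can be substituted.

Column conservation is the majority-base fraction among non-gap rows; gap
pressure is a separate per-column gap fraction. Conserved windows are all
*maximal* windows (no qualifying strict superwindow) of length ≥ `win_len`
(default 18, a primer footprint) whose columns all pass the gap threshold
(default 0.10) and whose mean conservation passes `min_mean_cons` (default
0.90; declared, since no canonical threshold exists). Overlapping maximal
windows merge into their union span; the union's own mean conservation is
reported and can, on adversarial profiles, fall below the threshold —
windows are candidate regions, and primer placement re-scores inside them
(below). A mean-threshold window can always absorb one or two
lower-conservation flank columns, so recovering a planted block *exactly*
requires a threshold above the flank dilution (the tests use 0.99 against
0.4-conserved flanks).

## Primer design

A primer is `tail + core`: a constant 5′ tag for downstream barcoding
(two tag sequences ship as `TAIL_A`/`TAIL_B`, as used by the packaged
tailed primer set) and a gene-specific degenerate core.

* **Consensus.** Per column, the IUPAC code of every base at frequency
  ≥ `f_min` (default 0.10) among non-gap rows; rarer alleles are treated
  as noise. Columns above the gap threshold are a hard error — primers
  must not span indels.
* **Placement.** Within each conserved window the `core_len`-column
  subspan (default 22) with the highest mean conservation becomes the
  primer footprint; maximal windows overhang into variable flanks, so
  window edges are poor anchors.
* **Thermodynamics.** Nearest-neighbor Tm from the unified duplex
  parameter table (ΔH in kcal/mol, ΔS in cal/mol·K, embedded as data),
  `Tm = ΔH/(ΔS + R·ln(C_T/4)) − 273.15 + 16.6·log10([Na+])`, at 50 mM
  monovalent salt and 0.25 µM oligo by default; the classic
  Schildkraut–Lifson salt term is used deliberately (divalent corrections
  out of scope). A degenerate core is expanded (cap 64 variants) and
  mean/min/max over variants are reported, the mean being the headline
  value. The Wallace rule `2(A+T)+4(G+C)` is available for quick checks.
  Tm is computed on the core only: tails are absent from the template in
  the first cycles, so only the gene-specific part anneals.
* **Tm matching.** Cores are shortened from the 5′ end only (the 3′ end is
  the extension anchor and stays on its conserved position) until the mean
  Tm is nearest the target; ties prefer the longer primer; a floor of 15
  bases is enforced and an unreachable target is an error reporting the
  best achievable Tm. The target Tm is a required user input (typically
  the partner primer set's Tm, so both sets cycle under one program).
* **Pairing.** The reverse core is the reverse complement of its window's
  consensus. The expected amplicon span (forward window start to reverse
  window end, per panel row, tails excluded) must fall inside the read
  window, default 1250–1750 bp, so designed amplicons survive the read
  length filter.

## In-silico PCR

Binding sites are scanned with the degenerate core against both template
strands: set-intersection matching per base, at most `max_mismatch`
incompatibilities (default 2) and none in the 3′-terminal `anchor3_len`
bases (default 3) — the polymerase cannot extend a mismatched 3′ end.
Tails never match. These tolerances are declared assumptions; wet PCR
outcomes, not a binding model, are what they approximate. Amplicons are
every forward(+)/reverse(−) site combination (and the strand mirror) with
positive length up to `max_amplicon` (default 3000). Per-taxon coverage at
a chosen rank is amplified/total sequences, with a superkingdom rollup;
"amplified" means at least one in-bounds amplicon.

## Read classification

Reads are filtered to 1250–1750 bp inclusive (full-length 16S window), then
assigned to the best reference by local alignment score over both read
strands, ties to the lexicographically smallest reference id. An
assignment is *classified* only when reference coverage > 0.60 **and**
identity > 0.80, both strict — "more than" distributes over both
thresholds, so boundary reads (exactly 0.60 or 0.80) stay unclassified;
both boundary cases are tested explicitly so the convention is auditable.
Best-hit single-reference assignment is used (no LCA over near ties); an
LCA mode would be an extension, not the default.

Abundance tables conserve reads exactly (classified + unclassified +
length-filtered = input), count rank-less classified reads as "unranked",
and export to Krona text format losslessly.

**Classifier comparison.** For each rank, over reads classified by both
with a name at that rank: agreement is the fraction with the identical
taxon name, and the L1 distance is between rank-level relative abundance
vectors over the union of taxa. With prefix-closed lineages agreement is
non-increasing toward finer ranks — species-level disagreement atop
genus-level agreement is the structurally expected signature, and the
pipeline demonstrates its classic cause by comparing classification
against a full versus a one-species-per-genus reference database.

## Synthetic communities

The generator emulates what the real workflow depends on, and nothing
more:

* One ancestral ~1.5 kb template; alternating conserved (90 bp) and
  hypervariable (75 bp) blocks, conserved at both ends (the layout of a
  marker gene with primer-suitable termini; nine variable blocks at the
  default length, mirroring the V1–V9 organisation).
* Per-taxon substitution rates 0.01 (conserved) / 0.20 (hypervariable) —
  low within-gene conservation contrast typical of 16S — plus 25 shared
  "clade signature" substitutions per superkingdom so archaea and bacteria
  form separable clades even in conserved regions. Congeneric sibling
  species derive from their partner at 0.02 substitutions/base.
* Genomes: uniform-random background with the 16S inserted at a seeded
  position and strand (GC bias is irrelevant to the logic under test and
  omitted).
* Reads: substitutions first, then indels left-to-right (sub 0.02, ins
  0.015, del 0.015 per base — long-read-scale error after basecalling),
  drawn from amplicons proportional to abundance. The error process is
  independent per base; no homopolymer or quality structure is modeled.

Passing tests on these fixtures demonstrates the *logic* — coordinate
bookkeeping, strand handling, threshold gates, conservation arithmetic —
at realistic divergences and error rates. They do not demonstrate
performance on real nanopore data, whose errors are bursty and
homopolymer-biased, nor robustness to chimeras or multi-copy 16S
variation.

**Primer-bias scenario.** Archaea-targeted primer sites are planted on
every taxon (conserved-region primers bind across superkingdoms), while
universal-pair sites are planted intact on bacteria and diverged beyond
any mismatch tolerance (every other position plus the whole 3′ anchor) on
archaea. Running PCR → reads → classification under each pair then shows
archaeal reads only under the targeted pair, at the community's specified
archaeal fraction up to multinomial sampling error — the qualitative
outcome the design exists to produce, made quantitative.

## Problem sizes and determinism

Default test and acceptance problem sizes — 50 genomes for extraction
recovery, 500 reads for genus recovery, 150 reads per primer pair for the
bias scenario, a 10-taxon demo pipeline — are chosen as the smallest sizes
at which the binomial/multinomial error bounds in the tests are
meaningful. Every random draw flows from an explicit integer seed through
`numpy.random.default_rng`; reruns are byte-identical, and the CLI writes
outputs atomically (temp file + rename).

## Known limitations

* Center-star alignment degrades on panels below ~85% identity; substitute
  an external alignment via the Clustal/aligned-FASTA readers there.
* The Tm model omits divalent cations, dangling ends and mismatch
  thermodynamics; degenerate-core statistics assume equimolar variant
  mixes.
* Binding prediction is combinatorial, not thermodynamic: a site either
  binds (within tolerance, intact anchor) or does not.
* Best-hit classification ignores near-ties; with very close congeneric
  references the species call is only as good as the database, which the
  reduced-database comparison makes visible rather than hides.
* In-silico coverage and read fractions inherit PCR's blindness to
  amplification efficiency differences; all bound templates amplify
  equally.
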