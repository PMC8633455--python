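# Methods

`mirwood` re-implements, as one tested pipeline, the computational procedure
used to characterise miRNAs across three developmental stages of woody stem
tissue (primary, transitional and secondary stem; three replicate small-RNA
libraries per stage), together with a synthetic-data generator that emulates
the study's inputs at desk scale.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Read cleaning

Small-RNA reads are removed, in order: malformed records; low-quality reads
(any `N`, or two or more bases at Phred <= 20 — "more than one low-quality
base" is read strictly, so a single Phred-20 base passes); adapter artifacts;
poly(A) inserts; inserts shorter than 18 nt.  Adapter location uses an exact
8-nt seed of the adapter's 5' end extended with at most one mismatch — the
underlying study names no algorithm, and this rule is deterministic and
adequate for high-quality synthetic reads.  A read with no locatable 3'
adapter has no measurable insert length and is dropped, counted inside the
adapter-artifact class.  Poly(A) means >= 90% A over the insert.  Reads
longer than 30 nt after trimming are retained; length histograms report
18–30 nt.  mRNA pairs use the transcriptome rules (post-trim length >= 50,
<= 10% N, <= 50% of bases at Phred <= 20; a pair dies with either mate).

The cleaning verdict depends only on (sequence, quality), so the pipeline
collapses identical records first and judges each distinct record once; this
is exactly equivalent to per-read cleaning and much faster on deep libraries.

## Annotation cascade

Distinct tags are classified by a fixed precedence:
rRNA > snRNA > snoRNA > tRNA > repeat > miRNA catalogue > exon sense >
exon antisense > intron sense > intron antisense > unannotated.  The miRNA
class deliberately precedes the degradation (exon/intron) classes so that
catalogue miRNAs residing inside annotated genes are not lost.  All matching
is exact: substring against class references (sense only), full-length
against the genome on either strand (via an 18-mer anchor index), identity
against catalogue matures.  scRNA, which the source material mentions once,
is folded into the snRNA reference class.  Distribution tables are
tag-abundance weighted, so per-library category counts sum to the clean-read
total — the arithmetic that makes the distribution table's percentages sum
to 100.

## RNA folding energy model

Folding uses a Zuker-style O(n^3) dynamic program over a simplified
nearest-neighbour model:

* stacking energies per adjacent pair, from a packaged table built additively
  from pair strengths (GC/CG 1.65, AU/UA 0.55, GU/UG 0.25 kcal/mol per half,
  G:U-containing stacks capped at −1.4): CG-on-GC stacks score −3.3, AU-on-UA
  −1.1, wobble-containing stacks −0.5 to −1.4 kcal/mol;
* loop penalties `a + b·ln(size/ref)`: hairpins 4.5 + 1.6·ln(L/3)
  (minimum loop 3 nt), bulges 3.6 + 1.1·ln(L), internal loops
  2.6 + 1.2·ln((L1+L2)/2), interior loops capped at 30 unpaired nt;
* affine multiloops 4.6 + 0.4 per branch (closing pair included) + 0.2 per
  unpaired base; lonely pairs allowed; external bases free.

The model is intentionally self-contained rather than a Turner-parameter
clone: every threshold applied downstream (precursor stability, the MFE-ratio
target rule) is defined relative to this model, and the same model drives the
intermolecular duplex fold, so the ratio criterion is internally consistent.
Absolute energies therefore need not match any external folder.  The
reference routines `structure_energy`, `min_energy_exhaustive` and
`enumerate_duplex_energy` re-derive energies by explicit loop decomposition
and exhaustive enumeration; the test suite verifies the dynamic programs
against them on thousands of random instances.

Ties between equal-energy structures are broken by a fixed traceback order
(hairpin closure first, then interior closures by ascending coordinates, then
multiloops), which makes folding deterministic across runs and platforms; we
do not attempt a global lexicographic minimum over co-optimal structures.

The precursor stability threshold is stored as `precursor_mfe_max = -18.0`
kcal/mol: the sign convention reads "maximal free energy 18 kcal/mol" as
"at least 18 kcal/mol of stabilisation", i.e. MFE <= −18.  This is a
configuration value, not a constant.

## Novel-miRNA prediction

Each unannotated 18–25-nt tag with a perfect genome match (and at most 20
genome copies) is tested as the mature arm of a hairpin.  A partner (miRNA*)
region is sought on the same strand within 16–300 nt using a fast
complementarity prefilter (>= 60% pairable positions of the reversed mature;
up to five nearest offsets are tried), the window plus 20-nt flanks is
folded, and the candidate must satisfy all criteria: mature 18–25 nt, star
20–23 nt, copies <= 20, MFE <= −18 kcal/mol, spacing 16–300 nt, duplex
bulges <= 4 nt, duplex asymmetry <= 4 nt, and a single stem-loop with the
mature wholly on one arm.  The star is delimited by the partner span of the
mature plus a 2-nt 3' overhang (Dicer geometry); the ambiguous
"reference sequence length" bound (20–23 nt) is applied to this star
interval.  Asymmetry is |unpaired mature-side − unpaired star-side| within
the duplex.  The first passing window per locus is kept; candidates sharing
a mature collapse into one record named `novel-mNNNN-<arm>`, numbered by
descending total count then sequence.

`mirwood.validation.revalidate_hairpin` re-derives every criterion directly
from the precursor string and dot-bracket structure, sharing no code with the
candidate constructor; reported candidates must survive it.

## Differential expression

miRNA abundances are TPM over *clean-read* totals (count/total × 1e6) — the
totals are the library's clean reads, not the miRNA-only sum, matching the
normalisation the study states.  When no totals are supplied the matrix
column sums are used, in which case each normalised library sums to exactly
1e6.  Gene abundances are FPKM.

The test is an exact conditional test replacing the original edgeR analysis
(a declared substitution): under the null, the two group sums are negative
binomials with a common success probability, so the group-A sum conditioned
on the total is exactly Beta-Binomial(total, n_a/φ, n_b/φ) — binomial at
φ = 0.  The two-sided p doubles the smaller tail (capped at 1).  Support is
evaluated on a ±16-conditional-SD window, which is exact to double
precision.  Unequal library sizes are pre-scaled to their mean.  The common
dispersion φ is a method-of-moments median across features
(φ = (v − m)/m², floor 1e-6); three replicates cannot support tagwise
estimates.  Fold changes are log2 of mean normalised abundance with a 0.5
pseudocount.  Calling: miRNAs at |log2FC| >= 1 and raw p <= 0.05; genes at
|log2FC| >= 1 and Benjamini–Hochberg FDR <= 0.05 — the asymmetry (raw p for
miRNAs, FDR for genes) is preserved deliberately.

The qPCR helper computes 2^−ΔΔCt against a reference assay and calibrator
sample; the calibrator's point estimate is exactly 1 because ΔΔCt is taken
against the calibrator's mean ΔCt, with the SE from per-replicate folds.

## Target prediction

Sites are ungapped antiparallel windows equal in length to the miRNA,
positions numbered from the miRNA 5' end; Watson–Crick = 0, G:U = 0.5, other
= 1.  Rules: total <= 4; no run of more than two adjacent mismatch events
(G:U counts as an event for adjacency though it weighs 0.5); no two adjacent
full mismatches within positions 2–12; no mismatch at positions 10–11
(strictly — a G:U there rejects; both adjacency readings and the 10–11
strictness are configuration toggles, strict by default, because the
inherited pattern-matching conventions do not define adjacency for G:U);
at most 2.5 weighted mismatches over positions 1–12; and duplex MFE at
least 74% of the perfect-complement duplex MFE (ratio of magnitudes).
Scanning is sense-strand over full cDNA; per (miRNA, transcript) the best
site is kept (lowest weighted total, then highest ratio, then smallest
coordinate).  The production scanner is vectorised over a concatenated
transcript array; a plain per-position checker
(`validation.check_target_rules`) provides the independent decision.

## Integration and enrichment

Pairs per comparison: miRNA called DE, gene carrying a rule-passing site,
gene called DE in the same comparison.  Correlation uses the six replicate
libraries of the two compared stages (three stage means would give n = 3 and
degenerate p-values), on log2(x+1)-transformed TPM/FPKM.  Classes: negative
iff −1 < r < −0.8 and p <= 0.05 (both inequalities strict at the boundary),
positive iff r > 0.8 and p <= 0.05 (a mirrored convention; the source states
only the negative threshold), else none.  Enrichment is hypergeometric
upper-tail with BH control within each annotation namespace, terms with
K < 2 skipped, population = all genes in the expression matrix, no GO-graph
propagation.

## The synthetic-data generator

The generator emulates the nine-library design: a random genome
(default 500 kb, no Ns, no overlapping genes) carrying 300 two-exon genes,
four repeat copies, and 10 planted hairpin loci; ncRNA reference sets;
a 30-entry known-miRNA catalogue (60% focal-species, the rest other-species
for the conserved tier); nine gzipped FASTQ libraries of 200,000 reads
(insert + full 3' adapter, Phred 40 everywhere except deliberately planted
low-quality/N reads that exercise the QC branches; adapter-artifact reads
are added on top); and a 300-gene count matrix at 2,000,000
fragments/library with NB noise at dispersion 0.05.

Planted precursors are perfect stems: arm = 20-nt flank + 21-nt mature, an
18-nt loop drawn from {A, C} only (so the loop cannot pair internally), and
the exact reverse complement as the other arm.  This guarantees a single
stem-loop, star length 23 (= mature + 2-nt overhang), spacing 16–18 nt and
zero bulge/asymmetry by construction — deliberately ideal Dicer substrates.
Stage effects (|log2FC| = 3 by default) are planted in balanced up/down
pairs whose base abundances cancel (an up ×2^e with base b paired with a
down ×2^−e with base b·2^e), keeping total miRNA mass stage-invariant;
without this, strong planted effects shift the relative abundance of every
null miRNA and a conditional test rightly calls them changed.  Per-library
gamma noise at the stated dispersion makes miRNA counts marginally NB, the
model the exact test assumes — parameter recovery is thus a fair test, not a
tautology.  Planted target sites carry 0.5–1.5 weighted mismatches (wobbles
preferred): a site is only planted after verifying it passes all six rules
*and* the MFE-ratio filter, so every planted pair is discoverable in
principle; sites are never exact reverse complements, which would add a
spurious genome locus for the miRNA.  A configured fraction (default 0.8)
of planted (DE-miRNA, target) pairs get inverse stage profiles (the planted
negative correlations); the remainder stay flat and simply produce no pair.

What passing these simulations does **not** show: tolerance to sequencing
error and quality-score structure of real instruments, adapter variants and
partial adapters, isomiR heterogeneity, imperfect natural hairpins (bulged
stems, multi-branch precursors), multi-mapping ambiguity at repeat-rich
loci, library-composition artefacts beyond the planted ones, or database
versioning effects — all of which move real-data counts.  The synthetic
conditions test the logic and the statistics, not robustness to real-world
noise.

All randomness flows through a single seeded `numpy` generator passed
explicitly; gzip members are written with a zeroed timestamp, so identical
configurations give byte-identical files.

## Problem sizes used by the evaluation harness

The harness (`mirwood.harness`, driven by `scripts/acceptance.py` and the
study-level tests) uses: 3 × 10,000 random duplexes for the rule-scorer
cross-check; 2 × 1,000 random sequences (10–20 nt) for the folding oracle;
20 generator-default seeds (10 hairpins, 9 × 200k reads each) for hairpin
recovery; 10,000 null and 2,000 + 8,000 effect/null NB features for test
calibration and power; and three reduced full-pipeline runs (100 genes,
8,000 reads/library) for negative-pair recovery and accounting, sizes chosen
to exercise every stage while keeping a complete evaluation run in the
minutes range on one CPU.

## Known limitations

* The energy model is not Turner-2004; absolute MFEs differ from MFOLD/Vienna
  values.  Thresholds are model-internal by design.
* Common (not tagwise) dispersion; no TMM or similar compositional
  normalisation — the paper-style total-count normalisation is kept, which
  is exactly why the generator plants composition-balanced effects.
* Exact-match annotation stands in for BLAST/Bowtie heuristics; adequate at
  toy scale, not a replacement for them on real genomes.
* Enrichment takes annotation maps as given (no GO-graph parent
  propagation).
* The paper's contingency-table step in the correlation analysis is
  reproduced only as the three-way class tally; the original's exact
  construction is not specified.
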