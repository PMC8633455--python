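# mirwood

Discovery and integration of miRNAs from stem small-RNA sequencing, built for
the three-stage wood-formation design: primary (PS), transitional (TS) and
secondary (SS) stem, three replicate libraries per stage.  The package takes
raw small-RNA FASTQ libraries, a reference genome with gene models, per-class
ncRNA references and a known-miRNA catalogue, and produces — through one
reproducible pipeline — clean reads, an annotation cascade, known (existing /
conserved) and novel miRNAs, differentially expressed miRNAs and genes,
candidate target genes (CTGs), and negatively correlated miRNA–target pairs,
plus term enrichment of the CTG sets.

It is aimed at plant small-RNA analysts who want the complete procedure as a
tested, scriptable library rather than a chain of separate tools, and it
ships a synthetic-data generator with planted ground truth so every stage can
be validated end to end without any downloads.

## The methods at the core

* **Annotation cascade.** Distinct tags (sequence + per-library counts) are
  classified by fixed precedence — rRNA, snRNA, snoRNA, tRNA, repeat, miRNA
  catalogue, exon/intron (sense/antisense), unannotated — with exact
  matching throughout; abundance-weighted category tables sum to the
  clean-read totals.
* **Novel miRNA prediction.** Every unannotated 18–25-nt tag with a perfect
  genome hit is tested as the mature arm of a hairpin under the classic
  plant criteria: star length 20–23 nt (2-nt 3' Dicer overhangs), ≤ 20
  genome copies, precursor MFE ≤ −18 kcal/mol, miRNA/miRNA* spacing
  16–300 nt, duplex bulges ≤ 4 nt, asymmetry ≤ 4 nt, and a single stem-loop
  with the mature on one arm.  Folding uses the package's own
  nearest-neighbour dynamic program, verified in the tests against
  exhaustive enumeration.
* **Differential expression.** TPM (count/clean-read total × 1e6) and FPKM
  normalisation; an exact conditional negative-binomial test (the group-sum
  law given the total is Beta-Binomial(n, n_a/φ, n_b/φ)); calls at
  |log2FC| ≥ 1 with raw p ≤ 0.05 for miRNAs and BH FDR ≤ 0.05 for genes.
* **Target prediction.** Weighted-mismatch duplex scoring over ungapped
  antiparallel windows: Watson–Crick 0, G:U 0.5, mismatch 1; total ≤ 4, ≤ 2
  adjacent mismatch events, no adjacent full mismatches in positions 2–12,
  perfect pairing at positions 10–11, ≤ 2.5 over positions 1–12, and duplex
  MFE ≥ 74% of the perfect-complement MFE.
* **Integration.** For each stage comparison, (DE-miRNA, CTG ∩ DEG) pairs
  are Pearson-correlated across the six replicate libraries; a pair is
  *negative* iff −1 < r < −0.8 and p ≤ 0.05.
* **Enrichment.** Hypergeometric upper tail with BH control per annotation
  namespace; rich factor k/K for plotting.

Full model details, parameter defaults and limitations are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a default study (nine libraries × 200,000 reads, 10 planted novel
hairpins, 18 planted DE miRNAs with |log2FC| = 3, planted negatively
correlated targets) and run the full pipeline:

```python
from mirwood.simulate import SimulationConfig, simulate_dataset
from mirwood.pipeline import run_pipeline, evaluate_against_truth

paths, truth = simulate_dataset(SimulationConfig(seed=7), "bundle")
result = run_pipeline("bundle", "results")
c = result.manifest.counts
print(c["n_existing"], c["n_conserved"], c["n_novel"])
print(c["n_de_mirnas_PS_vs_SS"], c["n_pairs_PS_vs_SS"], c["n_negative_PS_vs_SS"])
print(evaluate_against_truth(result, truth).to_string(index=False))
```

prints

```
18 12 10
18 29 29
            stage               metric  value
hairpin_discovery          sensitivity    1.0
de_mirna_PS_vs_TS          sensitivity    1.0
de_mirna_PS_vs_TS                  fdp    0.0
de_mirna_PS_vs_SS          sensitivity    1.0
de_mirna_PS_vs_SS                  fdp    0.0
de_mirna_TS_vs_SS          sensitivity    1.0
de_mirna_TS_vs_SS                  fdp    0.0
target_prediction          sensitivity    1.0
      integration negative_sensitivity    1.0
      integration        positive_rate    0.0
```

i.e. of the 30 catalogue miRNAs expressed in the libraries, 18 are assigned
as existing (focal species) and 12 as conserved (other species, renamed
-x/-y); all 10 planted hairpins are rediscovered as novel miRNAs; in the
PS-vs-SS comparison 18 miRNAs are called DE, forming 29 DE-miRNA–CTG pairs,
all 29 classified as significantly negatively correlated; and the evaluation
table confirms every planted signal was recovered with nothing spurious.

The same stages are available as CLI verbs (`mirwood simulate`, `qc-srna`,
`qc-mrna`, `annotate`, `discover`, `de`, `targets`, `enrich`, `run-all`,
`evaluate`); `mirwood run-all --bundle bundle -o results` reproduces the run
above and writes per-stage TSVs plus a `manifest.json` whose counts are
bit-identical across reruns.

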