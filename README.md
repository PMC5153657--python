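# circage

Detection, quantification and aging analysis of circular RNAs (circRNAs)
from total RNA-seq, with a fully truth-tracked synthetic-study generator.

circRNAs are covalently closed transcripts formed by *back-splicing*: a
downstream splice donor joins an upstream splice acceptor, so the only
reads that identify a circle are the ones crossing its non-collinear
back-spliced junction. Because circles lack free ends they resist decay and
tend to accumulate in long-lived post-mitotic tissue — the motivating
question for this package is whether, and where, circRNAs accumulate with
age. `circage` is written for computational biologists who want a compact,
testable re-implementation of the standard junction-scaffold workflow
(find_circ-style de novo discovery, 200-nt junction scaffolds, duplicate
removal, unique junction-read counting) together with the downstream
age-stratified statistics, exercised end-to-end on synthetic data with
known ground truth.

## What it computes

**Discovery.** Mates that fail end-to-end linear alignment (genome and
spliced transcriptome, ≤2 substitutions) are split into 20-nt terminal
anchors. When both anchors align uniquely with the tail anchor *upstream*
of the head anchor, the read is extended to a single breakpoint flanked by
canonical splice signals (GT..AG on the plus strand, genomic CT..AC on the
minus strand). A junction is reported as 0-based half-open
`(chrom, start, end, strand)` with `start` the acceptor exon start and
`end` the donor exon end; de novo calls require ≥ 6 distinct supporting
reads.

**Quantification.** Each junction gets a scaffold of the 100 genomic nt on
either side of the back-splice (in transcript orientation), so 125-nt
mates can only align end-to-end if they truly cross the junction. After
start-coordinate duplicate removal, the count of a circle in library *l*
is its number of unique junction-spanning mates, and

    TPM(i, l) = count(i, l) × 10^6 / N(l)

with `N(l)` the library's retained reads (linear + junction). A circle is
kept for a tissue when its six libraries (3 young + 3 old) sum to ≥ 6
reads. Junctions whose two boundaries fall in exons of *different* genes —
the signature of a linear splice across duplicated paralogs, not of
back-splicing — are removed and reported.

**Statistics.** Per tissue, old-vs-young differential accumulation uses
fold change `(mean_old + ε)/(mean_young + ε)` with a 1.5-fold cutoff and a
two-sided t-test at α = 0.05 (no multiple-testing correction for circRNAs;
Benjamini–Hochberg for the simplified exon-union FPKM linear analysis);
the global age shift is a Wilcoxon rank-sum test with continuity
correction on pooled TPM values; the circular-vs-linear independence
analysis contrasts each circle's fold change with its host gene's, plus a
per-circle TPM/FPKM ratio test; PCA runs on log10(x+1) values. Genomic
feature classification (CDS/UTR categories, splice-accepting exon index,
exons per circle, per-gene circle counts, cross-tissue Venn) and a
TargetScan-style conserved microRNA seed-site scanner (8mer, 7mer-m8,
7mer-A1, with a gapped-alignment conservation filter restricted to
annotated exons) complete the workflow.

## Worked example

Simulate a one-chromosome study (18 libraries: cortex, hippocampus, heart
× young/old × 3 replicates; paired-end 125-nt reads; PCR duplicates and
sequencing errors on; 25 % of circles doubled with age in the brain
tissues only) and run the pipeline:

```bash
cat > demo.yaml <<EOF
seed: 7
n_chromosomes: 1
chrom_length: 1000000
n_genes: 60
n_circ_genes: 16
multi_circle_genes: 2
n_fragments_per_library: 20000
circ_fraction_of_reads: 0.05
EOF
circage simulate --config demo.yaml --out demo_study
circage run-all demo_study demo_results
circage report demo_results
```

The run (about a minute) prints a summary ending in:

```
 "cortex":      { "n_retained": 18, "n_up": 1, "n_down": 0, ... },
 "heart":       { "n_retained": 18, "n_up": 0, "n_down": 0, ... },
 "hippocampus": { "n_retained": 18, "n_up": 3, "n_down": 0, ... }
annotated 18
```

Reading it: 18 of the 18 simulated circles were discovered de novo at
exact coordinates and pass the 6-read tissue cutoff everywhere; at this
desk-scale depth the per-circle t-test flags a handful of the truly
doubled circles as age-upregulated — and only in the two brain tissues,
never in heart, reproducing the qualitative design of the study. All
stage outputs (junction counts, TPM, DE tables, volcano/density/PCA
tables, feature and overlap summaries, scaffold FASTA, filter reports)
are TSV/JSON files under `demo_results/`.

The same objects are available as a library:

```python
from circage.synthdata import SimulationConfig, simulate_study
from circage.pipeline import run_pipeline, PipelineParams
import pandas as pd

bundle, circs, truth, libs = simulate_study(SimulationConfig(seed=7))
design = pd.DataFrame([dict(library=l, tissue=t, age=a, replicate=r)
                       for l, t, a, r in truth.libraries])
result = run_pipeline(bundle, libs, design, PipelineParams())
result.summary          # dict, identical to summary.json
truth.true_junction_counts()  # the oracle the pipeline is tested against
```

## Layout

```
src/circage/
  synthdata.py     genome/gene-model/read simulator + TruthSet oracle
  circdetect.py    linear filter, split anchors, breakpoint resolution
  junctionquant.py scaffolds, mate alignment, dedup, counting, filters
  expression.py    TPM/FPKM, differential tests, global shift, PCA
  features.py      region categories, exon indices, overlap tables
  mirtargets.py    seed-site scanning and conservation filtering
  pipeline.py      orchestration and summary JSON
  cli.py           `circage simulate | run-all | report`
docs/methods.md    model, parameters, numerical choices, limitations
```
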