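# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations behind `circage`. Coordinates are 0-based half-open
on the forward genomic strand throughout; GTF I/O converts to 1-based
inclusive at the boundary.

## The synthetic study

The generator emulates a ribo-depleted total RNA-seq aging study: three
tissues (cortex, hippocampus, heart) × two ages (young, old) × three
biological replicates, paired-end 125-nt reads. Defaults
(`SimulationConfig`) define the study conditions:

| parameter | default | rationale |
|---|---|---|
| genome | 2 chromosomes × 1.5 Mb | desk-scale; 20-mers are unique with overwhelming probability, so anchors behave as in a real genome |
| genes | 150, 4–8 exons | internal exons available for circles |
| exon length | 150–350 nt | at the high end of the mammalian distribution, chosen so the 100-nt genomic scaffold flanks never leave the terminal exons and the quantification oracle stays exact |
| intron length | 300–1200 nt | compact but long enough that genomic and spliced alignment differ |
| fragments/library | 11,000 | ≈200k read pairs across 18 libraries |
| fragment length | Normal(300, 60), truncated to [125, 450] | standard Illumina insert model; mates are inner-facing (FR) |
| circular fragment fraction | 0.004 | only ~27 % of circular mates cross the junction, so the realized junction-read share is ≈0.08 % of reads — just inside the "<0.1 %" regime of deep total-RNA studies |
| abundances | log-normal, σ(ln) = 1 | typical expression heterogeneity |
| age effect | 25 % of circles ×2 up, 5 % ×1.5 down, brain tissues only | a strong but not universal accumulation phenotype; host linear abundance untouched, so circular changes are independent of transcription by construction |
| substitution error | 0.002/base | Illumina-like; no indels, no quality model (quality is never used downstream) |
| PCR duplicate rate | 0.05 | exact re-emission of both mates under a new, truth-flagged name — what start-coordinate duplicate removal can detect |

Circles are drawn on internal exons only: the splice-accepting exon index
is ≥ 2 (exon 1 has no upstream acceptor site) and the donor exon is at
most the penultimate one (the last exon has no downstream donor). The
acceptor-index distribution defaults to mode 2, matching the empirical
preference of back-splicing for 5'-proximal exons. Member exons are a
contiguous run of the host transcript's exons; the mature circle sequence
is their spliced concatenation in transcript orientation, and fragments
are sampled uniformly from its circular permutation (fragments longer than
the circle are redrawn — no rolling-circle reads). The circular sampling
weight is scaled so the *baseline* circular fraction equals the configured
value; age effects then add or remove circular read mass rather than
redistributing a fixed total, which would otherwise make every effect
compositional.

Every emitted read is traceable: read names encode fragment identity, and
the `TruthSet` records each junction-spanning mate with its donor-side
length, every injected duplicate, per-library totals and the true effect
table. `TruthSet.true_junction_counts(min_overhang)` and
`TruthSet.expected_scaffold_counts(flank, min_overhang)` are the oracles
the detector and quantifier are tested against; the latter reproduces the
exact geometry of scaffold alignment (per-circle flank `min(100, span)`,
end-to-end fit, overhang rule) and start-coordinate deduplication, so
matrix equality is a meaningful exact check.

What the simulator does **not** model — and hence what green tests do not
show about real data: intronic/pre-mRNA reads and rRNA carryover, indels,
position- or motif-dependent error profiles, fragment GC bias, isoform
diversity within a gene, rolling-circle fragments, strand-specific
protocols (pairs are unstranded-equivalent; a flag exists but both
orientations are always tried), and repeat-rich genomes where anchor
uniqueness genuinely breaks down (the optional duplicated-gene pairs are
the one controlled exception, used to exercise the multi-gene filter).

## Detection

The linear filter is a seed-and-verify end-to-end matcher: three disjoint
20-mers per mate are looked up in hash indexes of the genome and of the
spliced transcriptome; candidates are verified by direct comparison with a
budget of ≤ 2 substitutions. By pigeonhole the seeding is complete for the
error model (no indels). Mates failing both references enter breakpoint
resolution: both orientations are tried (only one can match the forward
genome), the 20-nt terminal anchors must each have a *unique* exact hit on
the same chromosome with the tail anchor upstream of the head anchor, and
the breakpoint `b` is scanned over the whole read with prefix/suffix
mismatch arrays (O(L) per read). A candidate breakpoint is valid when the
total extension mismatches are ≤ 2, the span is ≤ 1 Mb, and the flanking
dinucleotides are GT..AG (plus) or CT..AC (minus, genomic orientation).
If two or more valid breakpoints tie at the minimal mismatch count the
read is discarded and counted as ambiguous — never arbitrarily assigned.
Support for a junction is the number of distinct (library, read sequence)
pairs, so exact PCR duplicates add nothing; de novo calls default to a
6-read minimum.

## Quantification

Scaffolds concatenate the genomic `min(100, span)` nt before the donor end
and after the acceptor start, reverse-complemented for minus-strand
circles so the scaffold reads 5'→3' in transcript orientation. Flanks are
genomic, not spliced — faithful to getfasta-style extraction — so
scaffolds with terminal exons shorter than the flank are flagged
`intronic_flank` and short circles (< 200 nt span) are flagged
`short_circle_overlap`. Mate alignment is substitution-only end-to-end
with score −6 per mismatch against a −15 floor (≤ 2 mismatches); gapped
alignment is not implemented because the error model contains no indels.
An alignment must cover the junction with ≥ 10 nt on each side — at
125-nt reads on 200-nt scaffolds the geometry already forces ≥ 25 nt, so
the default never binds. Mates tying across different scaffolds are
dropped as ambiguous; duplicates collapse on (library, circle, scaffold
start, strand), keeping the best score and, on ties, the smallest read id
(idempotent); fragments whose two mates hit different circles are excluded
entirely.

## Statistics

* **TPM**: junction reads × 10⁶ / N, with N = linearly aligned mates +
  deduplicated junction mates. This makes TPM depth-invariant; the choice
  of denominator is recorded in output headers.
* **Fold change**: `(mean_old + ε)/(mean_young + ε)` with ε the TPM (or
  FPKM) equivalent of 0.5 reads at the mean library depth — finite fold
  changes when one group is zero, raw means also reported. The 1.5 cutoff
  is inclusive.
* **t-test**: two-sided on raw normalized values, pooled-variance by
  default. At n = 3 vs 3 the pooled test holds its nominal size
  (empirically ≈ 0.049 at α = 0.05 on Poisson(30) counts) whereas Welch is
  noticeably conservative (≈ 0.035) because its degrees of freedom drop
  below 4; Welch remains available (`equal_var=False`), as does a
  log-scale option (`log_transform=True`, the default for the linear-RNA
  analysis, which also gets Benjamini–Hochberg correction). circRNA
  p-values are deliberately uncorrected. Zero-variance/equal-mean features
  get p = 1 and a `zero-variance` flag.
* **Global shift**: Mann–Whitney U on pooled old vs pooled young values,
  normal approximation with continuity correction and tie-corrected
  variance; for tie-free groups of ≤ 8 the exact enumeration is used, and
  the implementation is tested against an independent brute-force
  enumeration. *Limitation*: pooling replicate values across circles with
  heterogeneous abundances violates the test's exchangeability assumption
  (values from the same circle are correlated), making the pooled test
  anti-conservative-in-variance and badly calibrated under the null; the
  calibration studies therefore use homogeneous per-circle means, and
  pooled-shift P values on heterogeneous data should be read
  qualitatively.
* **Independence**: co-upregulation overlap counts, per-circle
  circTPM/hostFPKM ratio t-tests (intergenic circles excluded and counted
  separately), and the (log2 linear FC, log2 circ FC) density table.
* **PCA**: log10(x+1), features centered, no scaling, SVD; variance
  fractions sum to 1 except for the defined all-zero output on constant
  input.

Count-level calibration studies (`simulate_count_study`) draw Poisson
counts around per-circle means (optionally log-normal across circles,
optionally fold-scaled in the old group) — they exercise the statistics at
exactly stated conditions without paying for read-level simulation.

## Feature classification and microRNA sites

The host transcript is the one with the longest CDS (ties by transcript
id). Region categories come from the circle's two boundary bases relative
to the 5'UTR/CDS/3'UTR partition, ordered 5'→3' in transcript
orientation; boundaries outside host exons give `other`, no gene overlap
gives `intergenic`. The splice-accepting exon index is the transcript-order
index of the exon whose start (plus) or end (minus) coincides with the
circle boundary, falling back to the nearest containing exon with an
`inexact` flag.

The seed scanner implements the three canonical site types against the
seed (mature microRNA bases 2–8): 7mer-m8 (reverse complement of bases
2–8), 7mer-A1 (reverse complement of bases 2–7 followed by A) and 8mer
(both), with 8mers subsuming their component 7mers; 6mer sites are
deliberately excluded. Conservation requires, for every required species
of a user-supplied gapped alignment, a site of the same family within the
aligned columns of the reference hit (same-type matching behind
`strict_type`); missing orthologs mark a hit unevaluable rather than
conserved. Sites are restricted to hits fully inside annotated exons of
the circle's locus. The bundled family list is a small representative
subset of broadly conserved mouse families and is an editable input, not a
database.

## Determinism and problem sizes

All randomness flows from a single seed through named substreams (genome,
circles, abundance, one per library), so stages are individually
reproducible and two runs from one seed produce byte-identical FASTQ,
truth tables and summary JSON. The bundled test-suite and acceptance
studies run at desk scale — ≈3 Mb genome, 150 genes, 40 circles, ≈200k
read pairs for the detection/quantification oracles; 1,000–5,000 circles
for the count-level calibration studies; a 1 Mb study for the end-to-end
determinism check — sizes chosen so the full suite completes in a few
minutes on one CPU while every check retains its statistical meaning.
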