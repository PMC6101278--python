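# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical conventions, and the design decisions behind
`apcscreen`.

## Screening model

The screen treats a gene as a candidate target of chromatin-associated
APC when five independent lines of evidence agree. Stages are pure
functions of their inputs; rerunning with identical inputs and
configuration is bit-identical. All thresholds live in one
`ScreenConfig` object whose defaults are the study values: 400 bp summit
distance (strict `<` for replicate intersection, `≤` for cross-factor
center matching — both comparators exist because the two rules are
quoted differently in the source protocols), q < 0.05 for human DE,
1.5-fold and FDR < 0.1 for mouse concordance, 10 kb upstream window,
top-500 subset, and a binned-genome universe.

### Replicate intersection

Peaks from two replicates are matched one-to-one, greedily by ascending
summit distance with a symmetric tie-break (distance, lower coordinate,
higher coordinate), so swapping the input lists yields the same pair
set. Greedy nearest-first matching is our choice for resolving
many-to-many candidates; the original procedure does not state its
resolution rule. The representative interval of a pair is the
replicate-1 peak. Replicate agreement is summarized by the Pearson
correlation of log10 peak scores over matched pairs.

### Gene assignment and region classes

Each peak summit is assigned to the gene with the nearest TSS on the
same chromosome (ties: lower TSS coordinate, then lexicographic gene
id), with no distance cap by default (an optional cap exists). Signed
distances are negative upstream in gene-strand orientation. A peak is a
*regulatory-element* peak for its gene when the summit lies 1..10,000 bp
upstream of the TSS (inclusive boundary) or inside the first intron;
first-intron containment takes precedence when both could apply.
Coordinates are 0-based half-open throughout, matching BED/narrowPeak;
GTF input is converted on ingest.

### Motif scanning

Consensus motifs are matched under IUPAC degeneracy on both strands with
overlapping hits reported; sequence `N` matches nothing, so assembly
gaps cannot inflate prevalence. Prevalence is *presence* (≥ 1 hit per
peak), not hit count. The scanned window defaults to the full peak
extent; a fixed ±flank around the summit is available because the
original scanned window is unstated and prevalence percentages depend on
it. "Top" peaks are those with the highest −log10 p (interpreting the
ranking as most-significant-first), ties by descending score then
ascending coordinate.

### TF co-occupancy enrichment

Public TF peak sets are consolidated to replicate-shared peaks
(pairwise, left-to-right over the input lists, logged because greedy
pairing can be order-sensitive; a heterodimeric factor such as AP-1 is
consolidated across all four subunit replicate lists). Overlap between a
query APC peak and a TF peak is scored when the interval midpoints are
no more than 400 bp apart; midpoints rather than summits are the default
because public BED-style sets may lack summits (a summit mode exists).

The null model treats the genome as `N = effective_size / 400` disjoint
slots: expected overlap `E = n_query · n_ref / N`, fold
overrepresentation `k / E`, and an upper-tail hypergeometric p-value
`P(X ≥ k)` with population `N`, `n_ref` successes and `n_query` draws
(scipy's survival function; validated against exact rational enumeration
in the tests). The universe is configurable because the original
"expected background" is not fully specified; a seeded within-chromosome
peak-shuffling permutation null is provided as a model-free cross-check.
Reported folds therefore depend on the universe choice — a known
limitation when comparing against externally published fold values.

### Expression filters

The human filter consumes Cuffdiff-style tables as deposited (FPKM,
log2 fold change, p, q) and never recomputes the DE statistics; records
pass at q strictly below the cutoff, split by fold-change sign.

The mouse filter computes, per gene and model, per-sample linear fold
changes of tumor samples against the mean of that model's controls. A
gene passes when (i) the mean linear fold is ≥ 1.5 (human direction up)
or ≤ 1/1.5 (down) in both models, (ii) the direction matches the human
call in both models, and (iii) a one-sample t-test of the per-sample
log2 fold changes against 0 — samples pooled across the two models by
default, since one test per gene is reported; a per-model variant takes
the larger p — survives BH correction below the FDR cutoff across all
tested genes. Log2 is our choice of t-test scale (the source does not
state it) because it treats up- and down-regulation symmetrically.
The default cutoff is FDR < 0.1 (the value quoted with the headline
result) with 0.05 (quoted in the protocol text) available via
configuration; the discrepancy is surfaced in logs. Noise-free data
would have zero sample variance, so genes whose log2 fold changes are
constant to within 1e-9 are flagged and assigned p = 0 (nonzero mean)
or p = 1 (zero mean) rather than excluded; this keeps idealized
synthetic data testable while real data are unaffected.

Human/mouse symbols are paired case-insensitively by default; an
explicit mapping table overrides, and duplicate mapping rows are an
error.

### Multiple-testing correction

`bh_fdr(mode="literal")` is the default everywhere: each p-value is
multiplied by the number of tests and divided by its rank (ascending p,
stable ties). This is the arithmetic exactly as stated in the source
protocol; it is not forced monotone and can exceed 1.
`mode="step-up"` applies the conventional cumulative-minimum
correction capped at 1 and is cross-checked against
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`.

### Reporter assays

Each well's firefly/Renilla ratio is normalized to the mean ratio of the
empty-vector wells of the same experiment and condition, making
empty-vector activity average to exactly 1 and canceling any common
plate scale. Construct responsiveness is an equal-variance Student's
t-test of knockdown versus scrambled activities — two-tailed by default,
with the one-tailed option (half the two-tailed p in the hypothesized
direction) available because both conventions appear in the source;
FDR is computed within each knockdown-condition panel. Degenerate arms
(both constant, equal means) give p = 1 by convention, logged.

## Synthetic-data generator

The generator emulates the *shapes* and planted effect structure of the
real inputs, not their biology: a uniform-random genome (no repeats, GC
≈ 0.5, no assembly gaps), non-overlapping two-exon gene models, peaks
with log-scale scores correlated between replicates, and idealized noise
models (Gaussian on log2 expression, log-normal multiplicative on
luminescence). Passing tests on these fixtures demonstrates the
correctness of the *computations* — matching, counting, testing,
thresholding — not robustness to mappability artifacts, annotation
ambiguity, batch effects or dispersion structure in real sequencing
data.

Determinism: one global seed fans out to per-component child seeds via
`blake2s(f"{seed}:{label}")`, so each component is individually
reproducible and identical seeds give byte-identical fixture
directories.

Key parameters (defaults; all are study-shaped choices at desk scale so
the full suite runs in seconds):

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 1 Mb | two random chromosomes |
| genes | 200 | two-exon models, strand-balanced |
| peaks | 300 | summit-centered, widths 300–700 bp |
| replicate jitter | sd 20 bp (clipped at width/4) | summit disagreement between replicates |
| dropout | 0.10 | exact fraction of peaks present in one replicate only |
| top fraction | 0.15 | most-significant subset with denser motifs |
| motif plan | AP-1 0.50/0.20, TCF7L2 0.60/0.25 | carrier fraction in top/remaining peaks |
| mouse effect | 2.5-fold | planted concordant expression change |
| expression noise | sd 0.3 log2 (0 in the default fixture) | per-sample Gaussian noise |
| reporter effects | TOPFLASH ×2.0 under siAPC, etc. | planted condition multipliers |
| reporter noise | CV 0.05 | multiplicative log-normal |

Planted counts are exact by construction: accidental IUPAC matches
inside any peak's reachable scan window are removed by bounded point
mutation before instances are written (planted spans protected), and
background TF peaks are rejection-sampled ≥ 1 kb from every APC summit
so planted co-occupancy is exactly recoverable under the 400-bp rule.

The default full fixture plants four gene roles: complete candidates
(two regulatory-region peaks carrying TCF7L2/AP-1 motifs and TF
co-occupancy, human DE, mouse concordance), region decoys (identical but
with their only peak in exon 2, so they fail the location filter; random
background peaks are excluded from their regulatory windows to keep the
planted candidate set exactly recoverable), mouse decoys (human-DE with
a peak, null in mice), and DE-only genes without peaks. Anchor positions
are verified against a brute-force nearest-TSS oracle at build time so
every planted peak is guaranteed to assign to its intended gene.

## Numerical conventions and degenerate inputs

* Interval midpoints and summit-centered windows use floor division.
* Empty peak files, empty stages and empty strata produce warnings and
  zero/NaN-marked rows, never crashes; malformed records raise errors
  naming the line.
* Non-positive scores make the log-scale correlation undefined and raise
  an error naming the peak.
* `fold` is 0 when expected overlap is 0; the hypergeometric tail at
  k = 0 is exactly 1.
* Chromosome-name normalization (e.g. stripping `chr`) is available on
  ingest and logged when applied.

## Known limitations

* The hypergeometric universe is a modeling choice; folds and p-values
  shift with it (the permutation null is the internal consistency
  check).
* Nearest-TSS assignment is a 2D proximity heuristic; real regulatory
  relationships mediated by 3D chromatin contacts can violate it.
* The literal BH mode can produce non-monotone adjusted values by
  design; use step-up mode for conventional q-values.
* The generator does not simulate reads, GC bias, mappability or
  dispersion; operating-characteristic results (recall, false-pass
  rates) are statements about the planted noise model only.
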