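# Methods

## The essentiality model

In a saturated transposon-insertion screen, every tolerated insertion
site in the genome is represented by surviving mutants; genes whose
disruption kills the cell are depleted of insertions.  The per-gene
statistic is the **insertion index**

    ii_g = (unique insertion sites in gene g) / (gene length in bp),

computed exactly over 0-based half-open gene spans with no 5'/3'
trimming.  At saturation (about one unique insertion per 12 bp of
tolerant sequence) the genome-wide distribution of `ii` is bimodal: a
near-zero mode of essential genes and a broad right mode of
non-essential genes.

The two modes are fitted separately on two *sections* of the
distribution chosen to minimise overlap in the transition region:

* **essential (exponential) mode** — genes with `ii <= cutoff_low`
  (default 0.006).  The rate is the closed-form MLE, the reciprocal
  section mean.  If the section is entirely insertion-free (a fully
  saturated library with zero leakage), the mean is replaced by one
  pseudo-insertion over the section's combined gene length: the rate
  stays finite and the mode keeps its physical scale.
* **non-essential (gamma) mode** — genes with `ii >= cutoff_high`
  (default 0.03).  Because this section is a left-truncated sample of
  the mode, the fit maximises the *conditional* likelihood
  `pdf(ii; k, θ) / SF(cutoff_high; k, θ)` (Nelder–Mead in
  log-parameter space, method-of-moments start, tolerance 1e-9).  An
  unconditional fit inflates the shape by ~10–15% whenever an
  appreciable tail of the mode leaks below the cut-off; the
  conditional fit reduces to the ordinary MLE when it does not.

Genes strictly between the cut-offs take no part in fitting but are
classified like every other gene.  Each gene is scored by the log2
likelihood ratio

    llr(ii) = log2[ f_exp(ii; λ) / f_gamma(ii; k, θ) ],

with both densities floored at 1e-300 before the ratio and the result
clamped to ±1000 (log2 units), so an insertion-free gene under a
shape>1 gamma scores +1000 rather than +∞.  The call is

* `essential` iff `llr > log2(F)`,
* `non_essential` iff `llr < -log2(F)`,
* `unclear` otherwise,

with fold threshold F = 12 by default: "essential" means the essential
mode is at least 12 times more likely.  (The source analyses state the
two inequalities with inconsistent orientation in different places;
the orientation used here — exponential density in the numerator,
essential above +log2(12) — is the self-consistent reading and is a
single constant in the code.)

Published call counts are conventionally reported as percentages of
the genome's gene inventory *excluding* pseudogenes, even though
pseudogenes are classified too.  `summarize_calls` therefore reports
both denominators (`percent_of_classified` and `percent_of_genes`);
with counts 644/5,493/141 only the 6,244-gene denominator reproduces
the conventional (10, 88, 2)% — the sum-of-counts denominator gives
87% for the non-essential class.

## Essential-domain correction

A gene with tolerant termini can hide an indispensable core.  A window
of 300 bp starts at the beginning of the gene and slides every 150 bp;
a window with zero unique insertions flags the gene.  Only genes
currently called non-essential or unclear are scanned, and flagged
genes are promoted to essential by default (`promote=False` gives a
report-only mode).  Placement rules where the stride underdetermines
the scan: genes shorter than the window get a single whole-gene
window, and when the length is not step-aligned an extra window is
anchored at the 3' end so the union of windows covers every base
(`terminal_window=False` reproduces a strict full-windows-only
reading, which can leave a 3' tail unscanned).  Note a zero-run must
be at least `window + step - 1` bp long (449 bp at the defaults) to be
*guaranteed* to contain a placed window; shorter insertion-free cores
are detected only when their position happens to align.

## Ortholog agreement

Orthologs between two proteomes are 1:1 bidirectional best hits over
filtered tabular similarity searches.  Filters: E-value ≤ 1e-5 and
query and subject coverage ≥ 70% (inclusive), with coverage computed
from the single best-scoring HSP as `(end - start + 1) / length × 100`
— multi-HSP chaining is not performed, a known conservative bias for
split alignments.  Best hits are ranked by bit score, with ties broken
by lower E-value, then higher percent identity, then lexicographically
smallest subject id, so results are deterministic.  A protein is
*paralogous* if it has any non-self within-proteome hit passing the
same filters; every pair touching a paralogous protein is removed,
because a paralog could complement the disrupted copy and confound the
essentiality comparison.  This is the strictest defensible operational
definition; it is switchable.

One property worth stating because it is easy to assume and false:
tightening the hit filters does **not** monotonically shrink the
reciprocal pair set.  Removing a query's best hit can expose a
lower-scoring hit that *is* reciprocated, creating a new pair (this
occurs in roughly a quarter of random toy tables).  What is monotone
is the filtered hit set itself, and that is the invariant the tests
assert.

Per-pair agreement categories separate exact agreements (E/E, N/N,
U/U) from hard essential-vs-non-essential conflicts in either
direction and from mismatches involving an unclear call.  The
agreement percentage is rounded half-up to the nearest integer.

## Functional and phyletic profiles

COG profile: a gene with a multi-letter COG label contributes one
count per letter; genes with no orthology group or an empty label
count once under an `unannotated` pseudo-label.  Counts are therefore
label counts, not gene counts.

Phyletic profile: a binary proteome × orthology-group matrix (a group
present one or more times scores 1; all-zero columns are retained),
clustered by complete linkage on Euclidean row distances — the
defaults of the pheatmap-style tools this mirrors, on raw 0/1 values
with no scaling.  The number of flat clusters k is a user choice made
by inspecting the tree, not an automatic criterion.  Agglomeration
order for exactly tied merge heights follows scipy's deterministic
nearest-neighbor-chain order.

## The synthetic-data generator

The generator emulates the statistical regime the classifier assumes,
with a ground-truth manifest for every emitted artefact.  Defaults
(one `SimulationConfig`, all randomness from one seed through named,
stage-separated generators):

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2,000 | non-overlapping genes on one contig |
| `genome_length_bp` | 2,500,000 | contig length (bp) |
| `gene_length_mean`, `sd`, `min` | 1,000 / 250 / 200 bp | truncated-normal gene lengths (typical bacterial mean) |
| `essential_fraction` | 0.10 | typical bacterial essential fraction |
| `domain_essential_fraction` | 0.0025 | genes essential only through a core domain — a few per thousand, the rate such screens report |
| `domain_core_bp` | 450 | insertion-free core; ≥ window+step−1 so the scan is guaranteed to flag it |
| `insertion_density` | 1/12 bp⁻¹ | mean unique-insertion density of tolerant sequence, matching the saturation the cut-offs were chosen for |
| `nonessential_shape` | 5.0 | gamma shape of per-gene insertion rates |
| `leakage_rate` | 0.0 | insertions per bp inside essential genes/cores |
| `read_length` | 50 | genomic flank per junction read |
| `mean_reads_per_site` | 9.0 | read depth per unique site |
| `decoy_fraction` | 0.1 | tag-less reads mixed into the FASTQ |

The insertion process is site-level (each tolerant base becomes a
unique site independently), because the classifier consumes unique
sites; per-gene rates are gamma-distributed around the density so the
non-essential insertion-index mode is genuinely gamma-shaped with
known parameters.  The optional FASTQ layer adds read-level realism
for the tag-selection/mapping stages only: every site emits
`read_count` copies of primer+tail+flank on a random strand, so tag
selection followed by exact mapping reproduces the site table
identically.

What passing on this generator does **not** show about real data: no
sequencing errors or quality artefacts, no GC or origin-proximity
insertion bias, no growth-based fitness gradients (essentiality is
binary), no multi-copy regions (the exact mapper's multi-mapping path
is exercised only by constructed repeats), and gene models without
operonic structure or polar effects.

With zero leakage the essential mode is a point mass at zero, so the
exponential rate has no finite generator truth; recovery checks
compare the fitted rate against the same estimator evaluated on the
manifest's true per-gene counts (exactly the pseudo-insertion rule),
which verifies fit/data consistency rather than statistical recovery.
The gamma parameters are compared against the genuine generator truth
(shape 5, scale 1/60) and recover within a few percent at the default
problem size; the residual bias is the binomial sampling noise of
counts over finite gene lengths, which the fit does not model.

## Numerical and procedural choices

* Internal coordinates are 0-based half-open everywhere; conversion
  happens only at file boundaries (GFF3 is 1-based inclusive).
* Unique sites collapse across strands by default — a unique site is
  (contig, position) — since duplicate-removal conventions upstream
  are ambiguous; `collapse_strand=False` keeps strands separate.
* Tag selection requires an exact primer+tail match anywhere in the
  read (a `max_mismatch` option exists, default 0); the trimmed
  remainder must be strictly longer than `min_len` (default 20 bp).
* The exact mapper reports the coordinate of the read's first genomic
  base — the base adjacent to the transposon junction — so a
  reverse-strand read maps to the high end of its footprint.  Reads
  matching ≥ 2 loci are dropped and counted.  The mapper builds an
  in-memory k-mer index per read length and is intended for
  synthetic-scale genomes (a few Mb).
* For the CDS/intergenic site partition, only CDS-class features count
  as coding; RNA genes and pseudogenes fall to intergenic while still
  receiving insertion indices and calls.
* Pipeline runs are deterministic: the JSON summary embeds the config
  echo, package version and seed, carries no timestamps, and is
  byte-identical across reruns of the same configuration.

## Problem sizes used in validation

Classifier recovery runs at the generator defaults (2,000 genes,
2.5 Mb).  The FASTQ end-to-end identity check runs on a 150-gene,
220 kb bundle — the identity property is size-independent and the
exact mapper's index makes the full-size check needlessly heavy.  The
sliding-window oracle uses 500 random genes up to 5 kb against
per-base brute force; the reciprocal-best-hit oracle uses 100 random
tables of up to 20 proteins per side against exhaustive enumeration;
phyletic recovery uses 12 proteomes in 3 planted blocks.

## Known limitations

* The classifier is a hard two-distribution ratio, not a mixture
  model with soft assignment; no replicate- or condition-aware calls.
* No insertion-bias correction (GC content, distance to origin).
* Coverage filtering needs `qlen`/`slen` columns (or sequence FASTAs)
  in hit tables; fused or extended genes that fail the 70% coverage
  bound are simply not paired — no rescue is attempted.
* The sliding-window scan attaches no statistical significance to an
  insertion-free window; very short genes are a single whole-gene
  window and flag whenever they are empty.
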