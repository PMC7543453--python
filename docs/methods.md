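# Methods

## Normalization

RPKM divides each gene's count by the sample's total mapped reads in
millions, then by gene length in kilobases. The library size is the column
total of the supplied matrix: reads not represented in the matrix (e.g.
unassigned reads from upstream quantification) cannot be recovered here, so
they are not part of the denominator. Gene length is taken as supplied in
the length table; the package does not compute union-exon lengths from
annotation, because no single length model is canonical and the choice
belongs upstream.

TPM length-normalizes first and rescales each sample to 10^6, so columns
are comparable as relative abundances (each column sums to 10^6 to within
1e-6 relative tolerance — an invariant the tests enforce). Within one
sample, RPKM and TPM differ only by a positive factor, so every rank-based
step downstream (Spearman, argmax) is indifferent to the unit.

The detection floor zeroes RPKM values **strictly below** 0.5; a value of
exactly 0.5 survives. The floor applies to RPKM only — TPM is used
un-floored by the similarity stage. By default the floor is applied per
sample *before* donor averaging (`floor_stage="sample"`), and a gene is
"not detectable" exactly when every floored per-sample value is zero; a
`floor_stage="mean"` switch floors the donor means instead. The two orders
agree on the argmax in all but near-floor cases; the per-sample default
matches a display pipeline in which floored per-sample values are what gets
averaged.

## Argmax classification

Per cell type, donor samples are combined by arithmetic mean. A gene's
relative profile sets its maximum cell type to 100 %; the gene is assigned
to that cell type, or to `NOT_DETECTABLE` when the whole floored profile is
zero (the package's numerical definition of "not detectable", since
detectability has no other natural threshold once the 0.5-RPKM floor is
in place). Classification is scale-invariant, so whether relative
percentages are computed from floored or raw means cannot change the
assigned category.

Exact ties are broken deterministically by the canonical cell-type order
(PBMC, LB, F, iPSC, CN, then any other labels in first-appearance order)
and flagged; with continuous expression values ties essentially never
occur, but determinism must not depend on that.

Summary percentages are 100 × count / group size, rounded half away from
zero to one decimal. A gene in several disease groups counts once in each
group and once overall, so per-group counts partition each group and the
overall counts partition the panel — an invariant checked property-based.
Panel genes absent from the expression matrix are classified
`NOT_DETECTABLE` by `classify_panel` (strictness available via
`missing="error"`), keeping the partition invariant on real inputs.

## Gene-set coverage

For each gene set and cell type, the covered count is the number of member
genes present in the matrix whose donor-mean RPKM is **strictly above**
3. Coverage is normalized to the reference cell type's covered count
(default), with the set's in-matrix total reported alongside;
`normalize_to="total"` divides by that total instead, so both conventions
for "coverage relative to cortical neurons" are recoverable from one
output. A zero denominator leaves the normalized value undefined (NaN) and
the term listed, never an infinity. This is a descriptive metric — no
enrichment statistics, no propagation through the ontology graph.

## Reference similarity

Spearman ρ is computed per (bulk sample, reference column) over the
intersection of gene identifiers, with midrank tie handling, implemented as
Pearson correlation of column ranks. No expression filter and no log
transform are applied: rank correlation is invariant to strictly monotone
transforms, so filtering/transform choices would only add parameters
without changing results.

Each (bulk group, reference column) is tested one-sided (greater) by a
Wilcoxon rank-sum test of the group's ρ values against the **background of
all comparisons** — by default the full ρ matrix including the tested
entries themselves (`background="others"` excludes them). For test sets of
at most 10 values the p-value is exact: the permutation distribution of the
rank sum over all C(N, m) subsets is computed by an integer dynamic program
over doubled midranks, which handles ties exactly; larger test sets use the
tie-corrected normal approximation (the two agree within 0.02 at the
crossover sizes on random data, a property the tests check). p-values are
floored at the smallest positive double before −log10, and a
Benjamini–Hochberg column is reported alongside raw p since the appropriate
multiplicity treatment of the heatmap is a display decision.

Ordination uses classical (Torgerson) MDS: eigendecomposition of the
double-centered −D²/2, coordinates = top-k eigenvectors scaled by
√eigenvalues, k = 3 by default. Negative eigenvalues among the top k (the
input not being Euclidean-embeddable) are truncated to zero with a warning.
The dissimilarity is 1 − Spearman ρ between samples by default, with
`euclidean-log1p` as an alternative, since neither choice is canonical for
expression data.

## qPCR quantification

ΔCT = mean of detected target CT replicates − arithmetic mean of the
housekeeping genes' replicate-mean CTs (for two housekeeping genes this
equals geometric-mean normalization in linear expression space). The
reference cell line per gene is the ΔCT minimizer — the line with highest
expression — and relative expression is 2^(−ΔΔCT), exactly 1 at the
reference. Undetected reactions are missing values, never imputed to a
maximum cycle number: imputation would fabricate a detection limit the
instrument did not report. Partial detection (some replicates missing) uses
the detected replicates and is flagged.

Per gene, replicate-level ΔCT values are compared across cell lines by
one-way fixed-effects ANOVA (scipy). Pairwise comparisons are corrected by
Tukey's HSD by default — the convention of common graphing/statistics
software for all-pairs follow-ups — with Holm on pooled-variance t-tests as
the alternative; stars map p to \*, \*\*, \*\*\*, \*\*\*\* at 0.05, 0.01,
0.001, 0.0001. The degenerate all-values-identical case reports F = 0,
p = 1 with a warning rather than NaN.

## Synthetic data

The generator emulates the targeted study design: 5 cell types × 2 donors
of bulk counts over a 168-gene panel. Counts are negative binomial with
variance μ + αμ² (α = `nb_dispersion`, default 0.1, a typical RNA-seq
overdispersion for biological replicates; α = 0 degenerates to Poisson). A
gene planted to win in cell type c has mean `base_mean × fold_change`
(default fold 10, the order of magnitude of a clear cell-type-specific
marker) in c's samples and `base_mean` elsewhere; planted-undetectable
genes are identically zero. Per-sample means are rescaled so each expected
library size is `library_size` (default 2 × 10^6; small enough to keep the
fixture fast, large enough that every detectable gene sits far above the
0.5-RPKM floor). Gene lengths are log-uniform on [500, 10000] bp so RPKM
and TPM rank genes differently. The canonical fixture plants the
per-disease-group category breakdown of the targeted study (group sizes
65/30/18/55; overall 50 CN, 41 F, 26 LB, 22 iPSC, 14 PBMC, 15 not
detectable).

The single-cell-style reference mixes each cell type's standardized
log-generative-TPM profile with independent Gaussian noise at latent
correlation `rho` (default 0.95), then rescales columns to TPM; `rho = 1`
reproduces a monotone transform of the generative profile exactly. qPCR
plates encode CT = 30 − log2(relative abundance) + N(0, 0.15²) per
replicate (0.15 cycles is a typical technical-triplicate SD), with flat
housekeeping genes at CT 20 and 22; at zero noise the ΔΔCT analysis inverts
this model exactly.

What the generator does *not* emulate: donor-specific biology (donors are
i.i.d. replicates), gene–gene correlation, GC/length biases beyond the
length model, compositional competition between cell-type programs, and
reference matrices with cell types absent from the bulk design. Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted structure under realistic noise — not robustness
to every artifact of real RNA-seq.

## Problem sizes and determinism

The default test and acceptance workloads use the 168-gene canonical
fixture (10 samples) and 60–80-gene variants for multi-seed property
checks — sizes chosen so the full suite exercises every stage end to end in
seconds on one core. All randomness flows through
`numpy.random.default_rng` seeded from the config, so every output is
bit-reproducible; TSV floats are written at 6 significant digits and
`summary.json` is key-sorted, making report bundles byte-identical across
reruns.
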