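# mndprofiler

Choosing a cell culture model for a genetic disease starts with a simple
question: does the candidate cell type actually express the disease gene?
`mndprofiler` implements a comparative expression-profiling pipeline for
answering that question across a panel of disease genes and several
candidate cell types at once — the setting it targets is motor neuron
disorders (hereditary spastic paraplegia, ALS, SMA and related spasticity
disorders) profiled across PBMCs, lymphoblasts, fibroblasts, iPSCs and
iPSC-derived cortical neurons, but every stage is generic over cell types
and panels.

The pipeline:

1. **Normalization** — raw read counts to RPKM,
   `RPKM(g,s) = count / (total_s/10^6) / (len_g/1000)`, and TPM (length-
   normalize first, then scale each sample to 10^6). A detection floor
   zeroes RPKM values strictly below 0.5.
2. **Classification** — floored per-sample RPKMs are averaged over donors
   per cell type; each panel gene's profile is rescaled so its maximum is
   100 % and the gene is assigned to its argmax cell type, or
   `NOT_DETECTABLE` if floored expression is zero everywhere. Summaries
   report counts and percentages per category, overall and per disease
   group.
3. **Gene-set coverage** — per GO-style gene set and cell type, the number
   of member genes with donor-mean expression strictly above 3 RPKM,
   normalized to a reference cell type (cortical neurons by default).
4. **Reference similarity** — Spearman ρ of every bulk sample against
   per-cell-type single-cell reference profiles (TPM, shared genes,
   midrank ties), with a one-sided Wilcoxon rank-sum test of each
   (bulk group, reference) pair against the background of all comparisons,
   reported as −log10 p (exact enumeration for small groups). Classical
   (Torgerson) MDS provides the sample ordination.
5. **qPCR validation** — ΔCT against the mean of two housekeeping genes
   (GAPDH, TBP by default), ΔΔCT relative to the highest-expressing cell
   line (set to 1, ratio `2^(−ΔΔCT)`), and per-gene one-way ANOVA with
   Tukey HSD (or Holm) corrected pairwise comparisons.
6. **Synthetic data** — a negative-binomial simulator that generates every
   input with planted ground truth (per-gene winning cell type, reference
   assignment, gene-set membership, qPCR ratios), so the whole pipeline is
   testable end to end without any external data.

## Worked example

```python
import mndprofiler as mp

cfg = mp.canonical_config(seed=1)        # 168-gene synthetic panel, 5 cell types x 2 donors
cm, sheet, truth = mp.simulate_counts(cfg)

floored = mp.apply_detection_floor(mp.rpkm(cm), floor=0.5)
means = mp.donor_mean(floored, sheet)    # one column per cell type
panel = truth.to_panel()
summary = mp.summarize(mp.classify_panel(means, panel), panel)

print(summary.counts)
print(summary.percentages)
```

prints

```
{'PBMC': 14, 'LB': 26, 'F': 41, 'iPSC': 22, 'CN': 50, 'NOT_DETECTABLE': 15}
{'PBMC': 8.3, 'LB': 15.5, 'F': 24.4, 'iPSC': 13.1, 'CN': 29.8, 'NOT_DETECTABLE': 8.9}
```

i.e. of the 168 panel genes, 50 (29.8 %) are best expressed in cortical
neurons, 41 (24.4 %) in fibroblasts, …, and 15 (8.9 %) are not detectable
in any cell type — the classification recovers the planted category of
every gene at the default 10-fold expression margin.

The same pipeline runs from the shell:

```sh
profiler simulate --seed 1 --outdir fixtures/
profiler run --config run.json --outdir results/
```

where `run.json` points at the counts/lengths/samples/panel tables (plus
optional GMT gene sets, reference TPM matrix and qPCR plate); the output
bundle contains every numeric table and a machine-readable
`summary.json`.

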