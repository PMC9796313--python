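# tcresponse

Analysis toolkit for short treatment time courses in bulk RNA-seq, built
around the question of how a bacterial signal molecule (a guanidine
macrolide, polaramycin B) rewires secondary metabolism in the fungus
*Aspergillus nidulans*. The design has three conditions — untreated,
30 min and 3 h after treatment — and the package covers the full chain
from a raw count matrix to interpretable gene groups:

1. **Normalization** — TMM scaling factors (trimmed mean of M-values),
   log2-CPM and log2-RPKM, and voom-style mean–variance precision
   weights.
2. **Differential testing** — per-gene weighted linear models with
   empirical-Bayes moderated t-statistics for the two sequential
   contrasts (30 min − 0 and 3 h − 30 min). The moderated statistic is
   `t = log2FC / (u · s̃)` with posterior variance
   `s̃² = (d₀s₀² + d s²)/(d₀ + d)` on `d₀ + d` degrees of freedom.
3. **Kinetic classification** — a gene is *regulated* in a window only
   when |log2FC| > 1 **and** p < 0.01 (strict; disagreement between the
   two criteria means no call). The ordered pair of window calls maps
   onto eight response classes: immediate-steady (A1/A2), continuous
   (B1/B2), delayed (C1/C2) and transient (D1/D2), up or down, plus
   "none".
4. **GO over-representation** — upper-tail hypergeometric tests per
   kinetic gene set with Benjamini–Hochberg correction, then clustering
   of enriched terms by undirected shortest-path distance in the `is_a`
   DAG and reduction of each cluster to its deepest common ancestor.
5. **BGC summaries** — per biosynthetic gene cluster, counts of up- and
   downregulated members decomposed over the two windows, with the
   total as the union of the window sets (`17 (2, 15)` style).
6. **Spatial grid analysis** — Spearman rank association between
   metabolite concentrations and 400 nm pigment absorbance across a
   4 × 9 lattice of agar blocks from a confrontation assay, with
   t-approximation and permutation p-values.
7. **Synthetic data** — a negative-binomial count simulator with planted
   kinetic classes, toy ontologies, BGC tables and gradient grids, so
   the whole chain is testable without any download.

## Worked example

Simulate the study design (2 000 genes, 3 replicates per time point,
planted |log2FC| = 2 on 16 % of genes spread over the eight classes) and
run the statistical chain:

```python
from tcresponse.simulate import SimulationConfig, simulate_counts
from tcresponse import normalize, de, kinetics

cfg = SimulationConfig(n_genes=2000, effect_size=2.0, seed=42)
exp, truth = simulate_counts(cfg)
filtered = normalize.filter_low_counts(exp)
norm = normalize.normalize_experiment(filtered)
X = de.design_matrix(filtered.design)
weights = normalize.voom_weights(norm.log_cpm, X, lib_sizes=norm.effective_lib_sizes)
mfit = de.moderate(de.fit_models(norm.log_cpm, weights.weights, X))
tables = de.test_contrasts(mfit)
calls = kinetics.classify_genes(tables)
print(kinetics.summarize_classes(calls)[["class", "n_genes"]].to_string(index=False))
```

This prints (prior: d₀ = 132.8, s₀² = 1.092):

```
class  n_genes
   A1       37
   A2       48
   B1       43
   B2       36
   C1       39
   C2       40
   D1       39
   D2       34
 none     1684
```

i.e. ~316 genes called into the eight kinetic classes; 98.5 % of the
classified genes match their planted class at this effect size. The
`tcresponse` console script exposes the same stages as subcommands
(`simulate`, `normalize`, `de`, `classify`, `enrich`, `bgc-summary`,
`spatial`, `run-all`); `run-all` takes a YAML config and writes every
stage table plus a run manifest.

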