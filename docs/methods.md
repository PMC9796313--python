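# Methods

## The statistical model

The pipeline treats a three-condition treatment time course (untreated,
30 min, 3 h; `n` replicates per condition) as a cell-means linear model
per gene on log2-CPM, with two sequential contrasts: the immediate
response (30 min − 0) and the late response (3 h − 30 min), oriented so
a positive log2 fold change means upregulation at the later time.

**Library scaling.** TMM factors follow the trimmed-mean-of-M-values
construction: the reference sample is the one whose upper quartile of
CPM is closest to the mean upper quartile; for each sample, gene-wise
log2 expression ratios M and average abundances A against the reference
are computed over genes positive in both; 30 % is trimmed from each M
tail and 5 % from each A tail (rank-based, average ranks for ties); the
factor is `2^f` with `f` the mean of the retained M values weighted by
the inverse delta-method binomial variance
`(N_s − y_s)/(N_s y_s) + (N_r − y_r)/(N_r y_r)`. Factors are rescaled to
geometric mean 1. A sample sharing no positive gene with the reference
gets factor 1 with a warning. (Cross-checked once against the standard
R implementation during development: agreement to machine precision.)

**Expression scales.** `log2CPM = log2((y + 0.5)/(L̃ + 1) · 10⁶)` with
effective library size `L̃ = L · TMM`; `RPKM = (y + prior)/(len/10³)/(L/10⁶)`,
reported in log2. Genes without an exon-union length get missing RPKM,
never zero. RPKM uses raw library sizes by default (a flag switches to
TMM-effective sizes; which one the original analysis used is not
documented, so the simpler convention is the default).

**Precision weights.** Per gene, an OLS fit of log2-CPM on the design
gives a residual standard deviation; the mean–variance trend is a
lowess fit (span 0.5, non-robust) of `sd^1/2` on average log2 count.
Each observation's predicted `sd^1/2` is interpolated at its fitted
log2 count (linear between knots, constant beyond the range, floored at
0.01) and the weight is `sd⁻⁴`. Non-robust lowess keeps the trend
strictly local: the fit at one abundance depends only on genes inside
the local window.

**Moderation.** Gene-wise residual variances `s²` with `d` residual df
are shrunk toward a prior: the marginal moments of `log s²` are matched
to a scaled-F model, giving prior df `d₀` (by Newton inversion of the
trigamma function) and prior variance `s₀²`. When the observed spread
of `log s²` does not exceed the chi-square sampling noise, `d₀ = ∞` and
the prior value is the mean of the `s²` (so identical variances pass
through unchanged). The posterior variance
`s̃² = (d₀s₀² + d s²)/(d₀ + d)` enters `t = c·β̂ /(u·s̃)` with
`u = √(cᵀ(XᵀWX)⁻¹c)`, on `d₀ + d` df (normal when `d₀ = ∞`). P-values
are two-sided and raw; a Benjamini–Hochberg column is attached for
reporting only — the classifier consumes raw p.

**Kinetic taxonomy.** Regulation in a window requires *both*
|log2FC| > 1 and p < 0.01, strictly (values exactly at either boundary
are not regulation; a NaN statistic is "ns" with a warning). The pair
of window calls indexes the eight classes A1–D2 plus "none" via a fixed
truth table; negating all fold changes swaps each class with its
mirror.

**BGC summaries.** Per cluster, `up_w1`/`up_w2` count member genes
up-called in each window and `up_total` is the size of the union of the
two sets (likewise down). Union semantics are forced by the published
table's arithmetic: a cluster with 2 window-1-only and 15 window-2-only
up-genes totals 17, while 4 window-1 calls nested in 13 window-2 calls
total 13. Genes absent from the expression table count as unregulated;
the bracketed per-window counts are raw (not "newly regulated"), which
is the reading consistent with both published rows.

**GO over-representation.** Annotations are closed under ancestors
(true-path rule) before testing. For each gene set, each term with at
least `min_term_size` (default 3) annotated universe genes is tested
with the upper-tail hypergeometric `P(X ≥ k)`; BH correction is applied
within the gene set. The universe defaults to all genes in the filtered
count matrix carrying at least one annotation. Enriched terms are
clustered by average-linkage agglomeration on undirected shortest-path
distance in the `is_a` DAG, cut at cophenetic distance 2 (which merges
parent–child pairs and siblings); disconnected terms (distance ∞,
encoded as a large sentinel) never share a cluster. Each cluster is
represented by the deepest common ancestor of its terms (ties broken by
lexicographically smallest id); a singleton represents itself. This
graph-distance summarization deliberately approximates
information-content semantic similarity, which is out of scope.

**Spatial grid.** Blocks are indexed (row, col), row 1 at the top of
the plate photograph, column 1 at the left. Spearman rho is the Pearson
correlation of average ranks; the parametric p uses
`t = ρ√((n−2)/(1−ρ²))` on `n − 2` df, two-sided; the permutation p uses
add-one correction `(1 + #{|ρ*| ≥ |ρ|})/(B + 1)`. Missing blocks are
dropped pairwise and the n actually used is reported; fewer than 4
complete pairs is an error, and zero variance in either channel flags
the association as degenerate rather than inventing a value.

## The synthetic-data generator

`simulate_counts` plants a kinetic class per gene (default: 2 % of
genes in each of the eight classes, 84 % unregulated — about the
regulated fraction seen in the real experiment) and draws counts from
NB(mean `m`, variance `m + φm²`); `φ = 0` degenerates to Poisson.
Effects act cumulatively on the condition means:
`b, b·2^e1, b·2^(e1+e2)`, with `|e| = effect_size` (default 2) on the
steps the class marks significant and 0 elsewhere. Baselines are
`2^U(3, 10)` by default; the replicate count defaults to 3 because the
original study does not state one. If `library_size_range` is given,
each sample's means are rescaled to a drawn target column sum;
by default no rescaling happens, so the planted baseline means are
honored literally. One global seed feeds deterministic per-stage child
streams.

The toy ontology is a random single-root DAG (each term gets one tree
parent subject to a children cap, plus an occasional second parent);
gene annotations are Bernoulli per (gene, term) and closed under
ancestors. The grid generator lays a monotone gradient along one axis
(default: columns, i.e. toward the inducing colony) with Gaussian
noise; absorbance is a saturating monotone map of the *true* pigment
gradient plus its own noise, so zero noise yields rank correlation
exactly 1 and large noise attenuates it toward 0.

What the generator does **not** emulate: batch or lane effects, GC and
length biases, outlier samples, correlated genes (counts are
independent given their means), zero inflation, and realistic GO term
size distributions. Passing the recovery and calibration tests
therefore shows the chain is correct and well calibrated under the
stated NB model, not that it is robust to every artifact of real
sequencing data.

## Problem sizes and numerical choices

The calibration suite uses 5 000 genes × 2 seeds under the global null
(Kolmogorov–Smirnov distance of the p-distribution from uniform, and
the classifier's non-null rate) and 2 000 genes × 2 seeds for planted
class recovery at |log2FC| = 3 on baselines ≥ 2⁷ with dispersion 0.05 —
sizes chosen as the smallest at which the Monte-Carlo error is clearly
below the tested margins. The hypergeometric statistic is verified by
exhaustive subset enumeration for every universe size up to 12, and the
permutation machinery against full enumeration of all 8! orderings of
an 8-block fixture.

Numerical details worth knowing: counts are validated as true integers
(a value like `3.7` is rejected, not rounded); GFF3 exons are 1-based
closed intervals, merged when overlapping *or* adjacent, strand
ignored, with parentage resolved transitively through any number of
levels; the trigamma inversion runs Newton steps to relative tolerance
1e-8; p-values are clipped into (0, 1]; the lowess sqrt-sd floor (0.01)
caps weights at 10⁸; TMM trims use average ranks so ties are handled
deterministically; classification of a gene missing from one contrast
table yields "ns" for that window.

## Known limitations

- The prior-df estimator assumes a common residual df across genes (true
  here by design) and no abundance trend on the prior variance; the
  trended variant is deliberately out of scope.
- Time is modelled as three cells, not a curve; spline trends,
  duplicate-correlation blocking and gene-level F-tests are out of
  scope.
- The published real-data gene-set sizes and Table rows depend on the
  deposited sequencing data and cannot be reproduced from synthetic
  inputs; the package reproduces the *arithmetic and semantics* of
  those summaries exactly, and its statistical engine was spot-checked
  against the standard R implementations during development.
- Ontology handling covers `is_a` only; other relationship types and
  information-content similarity measures are not implemented.
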