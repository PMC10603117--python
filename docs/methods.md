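# Methods

This note records the models, estimators and numerical choices behind
stratanet, and what the synthetic-data tests do and do not establish
about real data.

## The analysis model

The pipeline targets a case/control bulk RNA-seq design with two sexes:
a gene × sample count matrix, metadata with sex ∈ {male, female},
phenotype ∈ {MDD, CTRL}, technical/clinical covariates, spike-in
control-gene flags and binary symptom indicators defined only for
patients. The default cohort geometry is 25 male MDD, 25 female MDD,
17 male CTRL and 22 female CTRL samples (89 total), configurable.

Analysis proceeds: preprocessing → per-sex differential expression →
transcriptional-overlap map between the sex signatures → co-expression
networks per stratum → between-condition module statistics → symptom
association. All stages are deterministic given their inputs and
seeds.

## Preprocessing

**Low-expression filter.** A gene is removed iff, in at least one
sex × phenotype group, the fraction of samples with fewer than
`min_count = 5` reads is ≥ `low_fraction = 0.20`. This is the strictest
reading of a per-group rule (failing any one group suffices); both
numbers are parameters. The filter is idempotent.

**Normalisation.** log₂-CPM with a prior count of 0.5:
`log2((c + 0.5) / (L + 1) · 1e6)`. Voom-style precision weights (lowess
trend of √SD on mean log-count, inverted to fourth-power weights) are
implemented but off by default, so the identical unweighted matrix
feeds both the DE models and the correlation networks.

**Unwanted variation.** Control genes are assumed to carry only
unwanted variation. The samples × controls matrix of gene-centred log
expression is decomposed by SVD; the first k = 1 left singular vector
(scaled by its singular value, first nonzero entry positive) is stored
and enters every downstream design. This is the control-gene (RUVg
style) variant; no surrogate-variable analysis beyond it.

**Outlier samples.** A sample network is built from Euclidean distance
on log expression, adjacency `1 − d/max(d)`; connectivity is the row
sum excluding self; samples with standardized connectivity strictly
below −3.5 are excluded. The adjacency dialect is pinned in config
because only the threshold is canonical. Outlier detection runs on
normalized, *unadjusted* data, before covariate regression; the report
records this order.

**Covariate adjustment.** For network construction, per-gene least
squares residuals against the covariates plus the unwanted-variation
factor, with gene means restored. Categorical covariates are one-hot
with the lexicographically first level as reference; a rank-deficient
design raises an error naming the redundant columns. DE does not use
these residuals — covariates enter its design directly.

## Differential expression

Per-gene ordinary least squares with sex and phenotype as factors. The
pipeline estimates each sex's MDD − CTRL contrast on that sex's samples
(equivalently, a full interaction model with sex-specific residual
variances); a pure main-effects model is also available but forces the
two within-sex contrasts to coincide, which cannot express sex-specific
signatures. Positive log₂FC means up in MDD.

Variance moderation follows the standard empirical-Bayes scheme:
residual variances are modelled as scaled inverse-χ²; the prior df d₀
solves `trigamma(d₀/2) = var(log s²) − trigamma(d/2)` (Newton on the
inverse trigamma) and the prior variance s₀² comes from the matching
mean identity; posterior variances are the df-weighted blend and t uses
d + d₀ degrees of freedom. The implementation reproduces the reference
Bioconductor implementation to ~1e-13 on a frozen fixture (see
tests/test_diffexpr.py).

DEGs are nominal p ≤ 0.05, uncorrected, split by fold-change sign; this
is a deliberate sensitivity choice carried into everything downstream
(multiple-testing control happens at the map/enrichment/permutation
level instead). p-values are floored at 1e-300 before the ranking
metric −log₁₀(p)·sign(t).

## RRHO

Two signatures are each sorted by the signed metric, most up-regulated
first, ties broken lexicographically; the universe is the intersection
(dropped ids logged). For thresholds i·step, j·step the overlap of the
top lists is scored by the upper-tail hypergeometric probability; the
full matrix is adjusted jointly by Benjamini–Yekutieli and reported as
−log₁₀ adjusted p. The default step gives a ~100 × 100 map. Cells are
labelled up/up, down/down or discordant from the sign of the metric at
each threshold; with both lists up→down, concordant up-regulation
accumulates near the origin corner and concordant down-regulation in
the opposite corner. Tail probabilities for maps are computed from
cached log-gamma tables (exact, and ~30× faster than per-cell library
calls); the scalar `hypergeom_tail` uses the independent scipy route,
so the two implementations cross-check each other in the tests.

## Co-expression networks

**bicor.** Tukey-biweight midcorrelation with tuning constant 9:
weights (1−u²)² for |u| < 1, u = (x − median)/(9·MAD). Genes with zero
MAD fall back to Pearson (logged). At least 4 samples are required.

**Soft power.** Unsigned adjacency |cor|^β; β is the smallest power in
1..20 whose connectivity distribution is approximately scale-free
(signed R² ≥ 0.8 of the log-log regression of p(k) on mean k over ten
equal-width connectivity bins — the standard scale-free fit index;
equal-occupancy binning would make p(k) constant and the fit
undefined). If no power qualifies, the argmax-R² power is used with a
warning flag.

**TOM and modules.** TOM as in the README formula; dissimilarity
1 − TOM; average-linkage tree. Module detection is a tree-based dynamic
cut: a static cut at 0.99 of the merge-height range defines candidate
branches; a branch becomes a module when it has ≥ `min_size = 50` genes
(the smallest module the method is expected to resolve) and is
*coherent* — its attachment height exceeds the 0.75-quantile of its
internal merge heights by at least `min_gap = 0.04`. The quantile
criterion tolerates the straggler chains average linkage appends to a
tight branch while rejecting noise continua whose internal merges hug
the attachment height; an accepted branch splits only where both
children are themselves coherent modules. Everything else is
`unassigned`. Labels are colour strings in decreasing size order. No
eigengene-based module merging is performed by default.

**Eigengenes and connectivity.** ME is the first principal component of
the standardized member genes (sign aligned with the module's average
profile); kME is the Pearson correlation of each gene with an ME; kIM
is a gene's summed adjacency to the rest of its module (NaN for
unassigned genes); hubs are the top ⌈5%⌉ of members by kIM, ties
lexicographic.

## Module differential connectivity

MDC = Σ_{i<j}|bicor^A|^β / Σ_{i<j}|bicor^B|^β with the two conditions
sharing one β (from the network whose modules are being tested) so the
sums share a scale; mdc(A,B)·mdc(B,A) = 1 exactly. Significance uses a
label-shuffle permutation null: condition labels are permuted across
the pooled samples n_perm times and the FDR is the +1-smoothed fraction
of null |log MDC| at least as large as observed. This null is exact
under exchangeability and empirically calibrated (≈5% at the 0.05
level). A second null — random gene sets of the module's size — is
also computed and reported as `random_set_fdr`, but deliberately kept
out of the class call: it answers "does this module change more than an
arbitrary gene set", which any genuinely co-expressed module exceeds
even with no condition difference (measured false-positive rate ≈ 60%
for that purpose), so folding it into the FDR would destroy
calibration. GOC = mdc > 1 and fdr < 0.05; LOC = mdc < 1 and
fdr < 0.05; else NS.

## Module preservation

For each reference module, observed density = mean off-diagonal soft
adjacency in the test data; observed connectivity = correlation of the
members' kIM between reference and test. Each is Z-scored against
n_perm random same-size gene sets drawn from the shared universe
*excluding the module's own genes*: allowing them in bimodalises the
null sets' kIM profiles (module genes high in both datasets, background
low) and inflates the null connectivity correlation enough to drive
Z_connectivity of genuinely preserved modules negative.
Z_summary = (Z_density + Z_connectivity)/2 exactly; preserved means
Z_summary > 10; the median rank orders modules by observed density and
connectivity. With modest sample sizes Z_density dominates: the kIM
*pattern* is harder to preserve than overall density, and
Z_connectivity is correspondingly small even for planted modules.

## Symptom association

Associations run within the MDD samples of one sex (symptoms are
undefined for controls; pooled-sex is available by passing the combined
sample set). The statistic is the point-biserial correlation —
algebraically the Pearson correlation of the 0/1 coding with the
eigengene — requiring ≥ 3 samples in each symptom class.
Family-wise adjustment is max-T: each of the n_perm = 1000 permutations
of the symptom vector records the maximum |r| across modules, and
p_perm = (1 + #{null max ≥ |r_obs|})/(n_perm + 1) ∈ [1/(B+1), 1]. Gene
significance (GS) is the per-gene point-biserial with the symptom, with
"symptom-associated genes" at nominal parametric p < 0.05 (mirroring
the DEG convention); the GS-vs-kME fit reports r, the least-squares
line and the 95% confidence band of the fitted mean. Enrichment tests
are one-sided Fisher exact with Benjamini–Hochberg across each family
submitted together; GMT terms are reduced to the background before
testing and disjoint terms are skipped and recorded.

## Synthetic data

The generator draws counts from a negative binomial
(gene-level dispersion φ = 0.1 by default, log-normal library sizes,
mean 2×10⁶, CV 0.2) over a log₂-scale latent structure:

    log2 q_gs = μ_g + λ_g·rewire(sex_s)·f_m(s) + δ_g·1[MDD]
                + b_g·1[batch 2] + ε_gs

with module factors f_m ~ N(0,1), loadings jittered ±10% around each
module's `loading_mean`, planted log₂ fold changes δ (half up, half
down), gene-level batch shifts b_g ~ N(0, 0.3) and noise
ε ~ N(0, 0.5²). Control genes receive only baseline, batch and noise.
Sex-specific rewiring multiplies the loadings per sex, so a rewire
multiplier of 0 destroys a module's connectivity in that sex with a
predictable MDC in expectation. Symptoms are Bernoulli in MDD samples
with logit = base + Σ effect·f_m (log-odds 2.0 for the planted
association in the default study); controls get NA. The default study
plants three 60–80-gene modules with loading 0.8 — one rewired off in
females, one driving the sleep-disturbance symptom in both sexes, one
stable — plus 100 DE genes at |log₂FC| = 1 and 30 control genes among
2000 total.

Two measurement effects matter when predicting correlations from the
factor model and are part of the test oracles: the delta-method count
noise on the log₂ scale, (1/m + φ)/ln²2, adds to the configured noise
variance; and per-million scaling attenuates loadings by the module's
share of reads (the share co-varies with the factor), so the effective
loading is λ(1 − share).

**What the generator does not emulate:** six-region anatomical
structure beyond a label, correlated symptom batteries, gene-length and
GC effects, isoform structure, cell-type composition shifts, or
outlier-contaminated count distributions beyond a global displacement
option. Passing the planted-recovery tests therefore shows the
machinery is correct and calibrated under the assumed statistical
structure, not that the pipeline's biological conclusions transfer to
any particular cohort.

## Numerical and design choices

- Problem sizes: the reference study is 2000 genes × 89 samples;
  recovery checks use 10 seeds, calibration checks 200 simulated
  datasets/draws with permutation counts of 100–1000. These sizes give
  stable pass/fail margins for the stated thresholds.
- p-value floors: 1e-300 before logs; permutation p lower bound
  1/(B+1); degenerate variances raise errors or, where a sentinel is
  specified (zero residual variance, zero null SD), warn and return it.
- Determinism: every stochastic routine takes a seed; identical
  configs reproduce byte-identical pipeline outputs.
- Tie-breaks are lexicographic throughout (ranking metrics, hub
  selection, top-DEG selection), making orderings reproducible.
- The pipeline builds pooled, male and female networks; MDC compares
  MDD vs CTRL within each sex on that sex's modules, and male MDD vs
  female MDD on the male network's modules; preservation tests male
  modules in the female samples; symptom association uses the pooled
  network's eigengenes. A module whose connectivity exists in only one
  sex is expected to be found in that sex's network (and possibly not
  in the pooled one) — this is the phenomenon of interest, not a
  failure of detection.

## Known limitations

- Average-linkage + tree cut on 1 − TOM is quadratic in genes held in
  memory; no blockwise approximation is provided, so ~30k-gene inputs
  need substantial RAM.
- The moderated-t scheme assumes roughly Gaussian log-expression;
  heavy-tailed counts at very low expression are only partly handled by
  the low-expression filter and optional voom weights.
- Z_connectivity is underpowered at n ≲ 50 samples (see above); the
  preserved/not-preserved call effectively leans on density at this
  scale.
- The max-T adjustment controls the family across modules within one
  symptom and sex; no adjustment is applied across symptoms, mirroring
  per-symptom reporting conventions.
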