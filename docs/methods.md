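# Methods

This note records the models and procedures implemented in `ecotme`, the
parameters that matter, the design choices made where the design was open, and
what the synthetic benchmarks do and do not establish.

## Cellular modules (TIME subtypes)

The substrate is a samples × clusters matrix of non-epithelial cell-cluster
frequencies. Samples with fewer than 1,000 non-epithelial cells are excluded
(strict "fewer than": exactly 1,000 is retained). Raw rows are per-sample
proportions; the *normalized* matrix is the per-cluster z-score across samples
(sample standard deviation, ddof = 1), which makes rare and abundant clusters
comparable and lets normalized frequencies be summed across clusters when
assigning a dominant module. Columns with zero variance get z-score 0 rather
than NaN; such clusters are set aside during clustering and assigned
afterwards to the module with the nearest raw-frequency centroid.

Modules are detected by agglomerative clustering with the Ward.D2 update on
the correlation distance *d* = 1 − Pearson *r* between normalized cluster
profiles. Field workflows often fix the module count by visual dendrogram inspection; here a
reproducible criterion is used: *k* maximizes the mean silhouette on the
precomputed distance over *k* ∈ 2..8, and a best silhouette below 0.25 flags
the result as "weak structure" (the null cohort with no planted co-occurrence
lands below this). Dominance sums *normalized* frequencies per module
(argmax; exact ties resolve to the lowest module id and are logged), while
the monotypic/heterotypic call uses *raw* frequency shares (monotypic iff the
largest single-module share is ≥ 0.65) — the two rules are deliberately on
different scales, matching their respective definitions.

Module signatures take the five most prevalent cell types per module (by cell
count) and the top 10 marker genes per type. The marker test is not
prescribed anywhere authoritative, so a simple stand-in is used: one-vs-rest
log2 fold change of mean expression within the module's cells, requiring
detection in ≥ 10% of the type's cells. The ranking is configurable and the
signature is the deduplicated union (≤ 50 genes).

## Meta-programs

Filters are applied in the stated order and with strict boundaries: cells
with < 300 detected genes, then genes detected in < 5 cells; samples with
< 100 tumor cells are dropped. Over-dispersion is scored as the residual of
log CV² from a log-log linear fit against mean expression — a variance-mean
trend residual standing in for the v-score, whose exact formula is cited but
not printed; the top 2,000 genes are kept.

`consensus_nmf` is a light in-package consensus factorization, not a port of
the external cNMF tool: genes scaled to unit variance, multiplicative-update
NMF (Frobenius loss, max 200 iterations) over `restarts` seeds, pooled
components L2-normalized and k-means clustered, components farther from their
cluster median than the 0.9 distance quantile dropped as outliers, consensus
loadings = cluster medians, and per-cell usages refit by nonnegative least
squares then row-normalized. Rank selection trades restart stability (mean
silhouette of pooled components) against min-max-normalized reconstruction
error with weight λ = 0.5. The module equally accepts externally produced
usage/loading matrices.

Programs with mean cell usage strictly above 0.01 are retained. Retained
loading vectors (union gene universe, missing genes 0) are clustered on
1 − Pearson *r*; the linkage is unstated upstream, so *average* linkage is
used — the standard choice for correlation distances. Aggregation follows the
literal arithmetic: union of per-program top-100 gene sets; per gene, sum the
loadings of the programs whose top-100 contains it (exclusive genes keep
their single loading); divide every total by the number of programs in the
cluster; markers are the top 30 by aggregated loading, with boundary ties
resolved lexicographically and logged. The division is applied after the
top-100 restriction — the literal reading of the rule. A cell is "programmed"
for a meta-program iff it expresses (raw count > 0) at least 70% of the 30
markers; 21/30 qualifies exactly. A cell may be programmed for several MPs;
its primary MP is the highest coverage, with exact ties left unassigned.

## Interactions

Expected counts are the contingency margin products row·col/total (the
chi-square expectation), which preserves both margins exactly; Ro/e is the
elementwise observed/expected ratio and enrichment is strict (Ro/e > 1, so a
uniform table enriches nothing). Cells with zero expected count are flagged
undefined and excluded from enrichment. Top-k pairs per group sort by Ro/e,
then observed count, then pair id. The CellphoneDB-style frequency constraint
("below 0.1% or above 2%") does not state whether the band is retained or
dropped; the implementation *retains* pairs inside [0.1%, 2%] — this reading
is prominently configurable (`lo`, `hi`) because the opposite convention is
defensible.

## Ecosystems and ssGSEA

Component abundance profiles (4 CM + 6 MP columns of per-sample fractions)
are clustered with Ward.D2 on 1 − *r* across samples; auto-k maximizes mean
silhouette over 2..6 (bounded because there are only 10 components). An
ecosystem lacking either a CM or an MP is flagged, not repaired. Ecosystem
signatures union member CM signatures, member MP markers, and the gene
symbols of the ecosystem's ten highest-Ro/e ligand-receptor pairs (complex
pairs expand to all component symbols); provenance is kept per gene.

The ssGSEA variant is the canonical single-sample formulation: genes ranked
per sample (descending, average ranks on ties), enrichment = the sum over all
ranked positions of the weighted in-set ECDF (weights rank^α, α = 0.25)
minus the unweighted out-set ECDF. At α = 0 the score reduces to an
unweighted rank-sum statistic, which the tests verify against a direct
evaluation. The normalization used upstream is unstated; the global
(max − min) range convention over the whole score matrix is chosen and
configurable (`normalize=False` returns raw enrichment). Scores are invariant
to monotone transforms of a sample's expression, so linear or log-scale bulk
matrices score identically. Samples are assigned to the argmax ecosystem;
exact ties are left unassigned with the top-two margin recorded.

## Survival primitives

The Cox proportional-hazards solver maximizes the partial likelihood by
Newton-Raphson with **Efron** tie handling (the standard default, better than
Breslow with tied event times), converging when the largest score component
falls below 1e-7 (cap 50 iterations); step halving keeps the log likelihood
nondecreasing, and |β| > 50 is reported as non-converged (monotone
likelihood/perfect separation). When no event times are tied — true of all
the synthetic cohorts, which draw continuous times — Efron and Breslow
coincide and a fully vectorized path is used; the test suite checks both
paths against lifelines to 1e-5. P-values are Wald (chosen over likelihood
ratio for univariate screening speed). A vectorized single-covariate batch
fitter (`univariate_cox_scan`, Breslow risk sums, Newton steps clipped at 2)
fits thousands of genes per second and backs the DEG screen, stepwise
selection, SuperPC screening and the Kang-style bootstrap.

Harrell's C counts pairs where the shorter time carries an event (plus
event-vs-censored ties at the same time), with risk ties worth 0.5; it is
computed by scikit-survival and verified against exhaustive pair enumeration.
Kaplan-Meier curves and the log-rank test come from lifelines; BH-FDR from
statsmodels. The "optimal cutoff" is the maximally selected log-rank
statistic over midpoints between consecutive distinct marker values, with at
least `min_frac` = 0.1 of samples per arm (configurable); `min_frac = 0.5`
degenerates to the median split.

## Prognostic model search

The combination count reconstructs the printed total from the stated
ingredients: 9 plain algorithms + 9 Enet mixing values (α ∈ 0.1..0.9) + 3
stepwise directions = 21 modeling variants; the five screening-capable
algorithms (LASSO, Kang score, RSF, StepCox, CoxBoost) each pair with all 21,
plus the 21 standalone variants: 126. Selector = modeler pairs are included,
and each selector's gene set is computed once and reused across its 21
modelers. In the screening role StepCox runs direction "both".

Per-algorithm choices (all on within-cohort z-scored genes):

- **LASSO / Enet / ridge** — scikit-survival Coxnet path with the penalty
  weight chosen by 3-fold C-index CV; ridge uses l1_ratio = 0.01 and reports
  every gene in the model.
- **StepCox** — p-value-driven stepwise on the in-package Cox solver (enter/
  remove at 0.05); backward pre-reduces to the top 25 univariate genes when
  the input is larger.
- **RSF** — 500 log-rank trees, √p features, half-sample bootstrap, minimum
  leaf 20. "Genes used" are the features appearing in at least one split; in
  the selector role, genes with positive permutation importance (3 repeats on
  a 300-sample subset).
- **CoxBoost role** — componentwise gradient boosting on the Cox loss
  (scikit-survival), step count from {50, 100, 200} by 3-fold CV; nonzero
  coefficients are the selected genes.
- **SuperPC** — univariate-Cox z-screen with threshold ∈ {1.5, 2, 2.5} and
  1-3 principal components, both chosen by 3-fold CV; Cox on the components.
- **plsRcox** — PLS (2 components) of the null-model deviance residuals on
  expression; the fitted linear weights are the risk score.
- **survival-SVM** — scikit-survival's linear ranking formulation.
- **GBM** — gradient-boosted Cox trees, depth 2, shrinkage 0.01, up to 500
  rounds with early stopping on a 20% validation split.
- **Kang score** — a documented *reconstruction* (the upstream description is
  only "similar to Kang et al."): univariate Cox on 100 bootstrap resamples,
  keep genes with p < 0.05 in ≥ 80% of resamples, risk = Σ sign(β)·z(expr).

DEG screening computes fold change on log-scale expression as the difference
of group means reported as a linear ratio, a Wilcoxon rank-sum p-value (the
DEG test is not named upstream) with BH-FDR < 0.01, |FC| > 1.5, and direction
consistency against univariate Cox (up in the high-risk group ⇒ HR > 1, up
elsewhere ⇒ HR < 1). The high-risk group label is a **parameter**, not a
constant, because the upstream text is internally inconsistent about which
ecosystem is high-risk. The 70/30 split is event-stratified with
largest-remainder allocation so the training side is exactly round(0.7·n).

The leaderboard scores each fitted combination on every validation cohort
(genes z-scored within the cohort; missing genes imputed at the cohort mean,
i.e. zero, with a warning; a cohort missing > 50% of a model's genes is
skipped for that model) and ranks by the arithmetic mean C over validation
cohorts. Selection returns the best mean C among models with ≤ 15 genes;
ties prefer the smaller model, then the lexicographically first name; if no
model satisfies the bound the best overall is returned with a prominent
constraint-violated flag. Cross-validation is event-stratified 10-fold,
reporting per-fold held-out C and the R² of held-out risk scores against the
full-data model's scores on the same samples (the upstream R² quantity is
unstated; this definition is a documented choice).

## Synthetic cohorts

The generators are pure functions of (config, seed); one global seed expands
into per-generator substreams by fixed offsets, so each stage reproduces
independently. Defaults are the study conditions the tests run under:

- **Cell cohort** — 60 samples × 40 clusters, 4 planted modules (round-robin,
  ≥ 2 clusters each), 1,500-3,000 cells per sample plus a ~40% epithelial
  admixture. Cluster abundances are Dirichlet with base concentration 1.0 and
  a ×5 boost on the sample's dominant-module clusters — strong enough to be
  detectable, weak enough that most samples are heterotypic.
- **GEP matrices** — 6 shared archetype loading vectors (50 dedicated
  high-loading genes each over a sparse exponential background, 1,000 genes),
  copied into each sample with additive Gaussian noise (sd 0.1, clipped at 0)
  in random order, plus 2 sample-private noise programs whose Dirichlet usage
  concentration keeps their mean usage below the 0.01 retention threshold.
  Usage rows are Dirichlet and exactly renormalized.
- **Bulk + survival** — Gaussian log-scale expression (log-normal on the
  natural scale); each sample belongs to one of 4 ecosystems and its
  ecosystem's 40 signature genes are shifted by +1.5. Prognostic genes (5 by
  default, |log HR| = 0.7 per SD) are risky genes from the high-risk
  ecosystem's signature and protective genes from the others; protective
  genes are additionally depleted in high-risk samples so that every planted
  prognostic gene is a genuine DEG of the high-vs-rest contrast. Event times
  are exponential (baseline hazard 0.05/month — closed-form and sufficient
  for proportional-hazards recovery); censoring is independent exponential
  with its rate solved numerically so the expected censored fraction equals
  `censoring_rate` (default 0.3).
- **LR counts** — Poisson around a product-of-margins baseline (expected
  counts ≥ 20 so the null Ro/e concentrates near 1), with a ×3 boost on two
  planted pairs per group.
- **Abundance profiles** — two Dirichlet simplexes (4 CMs, 6 MPs) per sample
  with the sample's ecosystem components boosted ×5.

What the generators deliberately do **not** emulate: raw reads or UMI counts,
ambient contamination, batch effects, compositional distortions between
cohorts, non-proportional hazards, or informative censoring. Passing the
planted-recovery suites therefore shows the algorithms are implemented
correctly and recover structure at realistic signal-to-noise; it does not
certify performance on real cohorts with those additional artifacts.

## Problem sizes and numerical notes

The default benchmarks use 60-sample cell cohorts, 20-sample GEP cohorts, and
bulk cohorts of 400-1,000 samples × 150-300 genes; the model-search benchmark
uses 800 training and 3 × 400 validation samples with 5 planted prognostic
genes among 200 — sizes chosen so every planted effect is comfortably
identifiable while whole suites run in minutes on one CPU. Correlation
distances are clipped to [0, 2] and symmetrized before linkage; NMF restarts
and k-means are seeded; all silhouettes use precomputed distances. Known
limitations: the consensus NMF is a deliberately small reimplementation (no
spectra TPM re-normalization or density-threshold diagnostics of the external
tool); the Kang score and the marker-gene ranking are documented
reconstructions; auto-k criteria can differ from a visual dendrogram cut on
real, noisier data.
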