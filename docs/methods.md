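# Methods

This note documents the models and procedures implemented in `cfrepeat`,
the defaults and why they were chosen, and what the simulation-based tests
do and do not demonstrate.

## Feature catalog

Repeat annotations follow the RepeatMasker three-level hierarchy:
instance → subfamily (`repName`, e.g. `AluY`, `(TA)n`) → family
(`repFamily`) → class (`repClass`, called *superfamily* here: SINE, LINE,
LTR, Simple_repeat, …). The catalog maps every repeat instance onto one
feature per subfamily, namespaced `rmsk:<subfamily>` so a gene that
happens to share a subfamily's name can never collide with it. Gene
features are keyed by `gene_id` and grouped by GENCODE biotype. Three
modes — `repeat_naive` (genes only), `repeat_aware` (genes + subfamilies),
`repeat_alone` (subfamilies only) — partition the aware feature set
exactly into the other two.

Coordinate conventions: `rmsk` tables are consumed as 0-based half-open
(as stored by the UCSC table browser); GTF is 1-based inclusive and
converted on parse; everything internal is 0-based half-open. The rmsk
`C` strand notation is normalized to `-`; a trailing `?` on `repClass`
(e.g. `SINE?`) is stripped for grouping while the raw value is retained.
Simple-repeat subfamily names like `(TA)n` are used verbatim. No minimum
instance length is imposed. Overlapping gene/repeat loci are all indexed
as independent reference units; disambiguation of multi-mapping reads is
the quantifier's job, not the catalog's.

## Quantification and aggregation

Per-sample abundance tables in the `quant.sf` dialect
(Name/Length/EffectiveLength/TPM/NumReads) are aggregated by summing
`NumReads` over the unit→feature map. Estimated counts can be fractional
(EM-based quantifiers split multi-mapping reads); fractions are preserved
through aggregation and rounded to integers only where the NB likelihood
requires it. Units missing from the catalog are dropped with a warning
rather than erroring, tolerating reference/catalog drift; aggregate mass
is conserved exactly over the resolvable units. Mapping rate is assigned
reads over total input reads; the repeat-naive vs repeat-aware comparison
uses the paired two-sided signed-rank test, since each sample contributes
one rate under each reference.

## Normalization and composition statistics

Size factors are median-of-ratios: over features positive in every
sample, each sample's factor is the median of count/geometric-mean; they
are defined only when at least one such feature exists (otherwise the
error message points at a pseudo-reference fallback rather than silently
switching). Shannon entropy is computed per sample within each feature
group (biotype for genes, superfamily for repeats) on normalized counts,
in bits, with 0·log 0 = 0; a group with zero total in a sample yields NaN
with a warning rather than a fabricated zero. Both grouping levels
(subfamily and superfamily) are available; entropy defaults to
superfamily because that is the level at which repeat transcriptome
diversity is biologically interpretable with ~15k subfamilies collapsing
to a handful of clades.

Z-scores use the n−1 standard deviation (the R `scale` convention);
constant features are dropped first. PCA treats samples as observations,
removes zero-variance features, centers and scales, and caps the rank at
min(50, samples−1, features), computed by SVD. In place of a
variance-stabilizing transform we use log2(normalized + 1) ahead of
PCA/correlation: it preserves the centered/scaled rank-50 contract while
keeping the transform transparent and dependency-free. This is a
deliberate simplification — it slightly over-weights low-count features
relative to a fitted VST.

The rank-sum test uses exact enumeration when both groups have n ≤ 8 and
the pooled sample is tie-free, otherwise the tie-corrected normal
approximation; the paired version is the signed-rank test with zero
differences dropped (all-zero input returns p = 1 with a warning).
Multiple testing is Benjamini–Hochberg step-up.

## Differential expression

Each feature is fit with a negative-binomial log-linear model:

    log μ_ij = log s_j + x_j' β,    Var(y) = μ + α μ²

with `s_j` the size factor entering as an offset, covariates (continuous
ones standardized; categorical ones dummy-coded) preceding a two-level
condition indicator that is always the last term, and per-feature
dispersion α from method-of-moments on normalized counts,
α = max(0, (var − mean)/mean²). α < 1e−8 falls back to a Poisson family.
The condition effect is tested by Wald z = β/se with a two-sided normal
p; BH runs over converged features only (non-converged or unstable fits —
se ≥ 15 on the natural-log scale, i.e. complete separation — are flagged
and excluded from the BH m). Significance is called at p_adj < 0.01.

Relative to a full DESeq2-style analysis this surrogate has no dispersion
shrinkage, no fold-change shrinkage, no independent filtering and no
outlier refitting; on clean, moderately dispersed data the condition
estimates agree closely (the test suite cross-checks fold changes and
significance calls against pydeseq2 on a planted fixture), but on small
cohorts with outliers the surrogate will be noisier. Externally computed
DE tables in the DESeq2 column dialect can be imported instead
(`diffexp.read_de_table`).

Key invariants, enforced by tests: swapping condition labels negates
every log2 fold change and preserves p-values; doubling all counts is
absorbed by the size factors; with a confounded design the covariate
absorbs the spurious condition effect.

## Classifier protocol

Per disease: cases and controls are split 80/20, stratified by condition,
deterministically from a seed. Features are standardized with training
means/sds, which are frozen into the model and applied unchanged to test
data. For each elastic-net mixing value α on an 11-point grid in [0, 1]
(α = 1 lasso, α = 0 ridge; note some glmnet-era texts state this mapping
reversed — we follow the standard convention), a log-spaced λ path is
anchored at the data-derived λ_max and the λ minimizing mean 10-fold CV
binomial deviance is selected; each α's winner is refit on the full
training split. The reported model maximizes training sensitivity at 90%
specificity, ties broken by training AUC.

The 90%-specificity threshold is the smallest candidate t with
specificity(t) ≥ 0.90 on training controls, candidates being the
midpoints between adjacent distinct control probabilities plus sentinels
0 and 1; a sample is called positive when its probability ≥ t. Because
specificity is non-decreasing in t, the smallest qualifying candidate
maximizes sensitivity subject to the constraint. With fewer than 10
controls the attainable specificities are coarse (steps of 1/n) and the
op warns; in the worst case only the sentinel t = 1 qualifies and
sensitivity collapses to 0 — a faithful reflection of the protocol's
granularity, not a defect to paper over. Evaluation on the held-out split
reuses the frozen threshold verbatim and reports sensitivity,
specificity, AUC (Mann–Whitney formulation, ties ½) and an exact
Clopper–Pearson 95% CI on sensitivity — chosen over normal-approximation
intervals for reproducibility at the small test-split sizes involved.

Leakage guards: DE-filtered feature sets must carry provenance proving
the DE ran on training samples only, and construction fails otherwise;
test standardization never sees test statistics. Identical seeds produce
byte-identical serialized models.

## Fragment-length analysis

Long-read cfRNA fragments carry their molecule length in the alignment
template-length field (primary alignments only; TLEN 0 falls back to the
aligned span). Where a fragment's interval overlaps several catalog units
(≥ 1 bp intersection), the unit whose length is closest to the template
length is chosen; ties go to the shorter unit, then the lexicographically
smaller id — an arbitrary but deterministic rule. Summaries per group:
median (midpoint convention), max, and KDE mode locations (Gaussian KDE,
bandwidth factor 0.3, local maxima below 10% of the peak discarded as
noise — narrower bandwidths hallucinate modes on unimodal data, and this
setting still resolves the 150/300 nt SINE mixture). Observed/expected
ratio = template length / annotation length; "full-length" means ratio
≥ 0.9 and "half-length" ratio ∈ [0.4, 0.6], both configurable constants
capturing qualitative descriptions of full- and half-length Alu RNA.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions for all tests:

* **Toy genome** — one chromosome, random background, per-subfamily
  random consensus (300 nt, Alu-scale) planted as mutated copies (3%
  per-base substitutions) on both strands at non-overlapping positions,
  plus genes (500 nt, 1–3 transcripts with small 5' truncations).
* **Toy quantifier** — exact-substring assignment with equal fractional
  splitting of multi-hit reads. It reproduces the accounting semantics of
  a real quantifier (fractional counts, unassigned reads, mass
  conservation) but none of its alignment model: no mismatches, no bias
  correction, no EM reassignment.
* **Count cohorts** — NB (Gamma–Poisson) counts, log-normal base
  abundances (log-mean 4, log-sd 1) and library factors (log-sd 0.3),
  dispersion 0.3 (typical bulk RNA-seq midrange), default 30 + 30
  samples, planted condition log2 fold changes on named features, and
  optional per-feature covariate effects on the log scale. Metadata
  carries condition, age, gender, input_volume, stage.
* **Fragments** — per-group Gaussian-mixture template lengths truncated
  positive, defaults matching observed plasma cfRNA scales
  (protein-coding ~456 nt, lncRNA ~303, LINE ~258, LTR ~167; SINE
  bimodal 0.5·N(300, 20²) + 0.5·N(150, 15²)).

All randomness flows from a single seed with deterministic per-stage
child generators, so identical configs give byte-identical files.

Passing tests on these cohorts demonstrate that the statistical machinery
is correct and calibrated under its own assumptions (NB counts, clean
labels, planted effects); they cannot demonstrate performance on real
plasma cfRNA, where contamination, batch effects, mapping ambiguity of
diverged repeat copies and biological covariate structure all bite. The
end-to-end checks use a 60-sample cohort, 4 subfamilies × 5 instances,
25 genes and 300 reads/sample — sizes chosen so the whole 10-seed
protocol runs in minutes while keeping ≥ 24 training controls, enough for
the 90%-specificity grid to be meaningful.

## Numerical choices and degenerate inputs

* Elastic-net fits use scikit-learn solvers (lbfgs for ridge, liblinear
  for lasso, saga otherwise) with C = 1/(n·λ) to match the per-observation
  loss scaling of glmnet-style λ; the ridge λ path borrows the α = 0.05
  anchor since λ_max diverges at α = 0.
* CV folds are reduced (with a warning) when a class has fewer members
  than folds; a single-class training set is an error.
* A fold's failed fit contributes infinite deviance rather than crashing
  the path.
* Aggregation treats an already feature-level table under an identity map
  as a no-op; duplicate sample ids and duplicate quant unit names are
  errors.
* Entropy of an empty group, evaluation without both classes, catalogs
  missing a required record class, rank-deficient designs: all hard
  errors with specific messages, not silent repairs.

## Known limitations

* The NB surrogate's method-of-moments dispersions are noisy for small
  cohorts; no shrinkage is applied by design.
* The toy quantifier cannot model mapping ambiguity between diverged
  instances of the same subfamily (reads are exact substrings).
* The specificity threshold is a step function of the control count; for
  < 10 controls the protocol is honest but coarse.
* K-means and heat-map ordering are exposed as labels/CSV only; no
  rendering beyond that.
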