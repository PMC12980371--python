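# Methods

This note documents the models, parameter choices and numerical
conventions behind `strokepanel`, and what the synthetic-data results do
and do not establish about real cohorts.

## Synthetic cohort model

Counts for transcript *t* in sample *i* are negative-binomial,
`NB(mean = 2^η_ti, var = mean + φ·mean²)`, sampled as Gamma–Poisson with
a single global dispersion φ (`nb_dispersion`, default 0.08 — moderate
bulk-RNA overdispersion; gene-wise dispersion is deliberately out of the
default model). The log2 mean stacks:

- a per-transcript baseline ~ N(`baseline_log_mean` = 6, 1.5), i.e. a
  typical transcript around 64 counts with a heavy right tail; planted
  transcripts sit exactly at the baseline so low-count Poisson noise does
  not drown their effects;
- a class effect of ±`signature_log2fc` (default 1.5, alternating sign
  across a class's signature transcripts) for that class's samples only —
  the three signature sets, the time set and the severity set are
  disjoint by construction;
- `slope · onset_hours` for time transcripts in ischemic samples and
  `slope · NIHSS` for severity transcripts. Slopes are specified in
  units of the residual log2 SD implied by the NB noise at baseline
  (delta method: σ_log2 ≈ √(1/m + φ)/ln 2), so one dimensionless knob
  controls the realized correlation. Defaults (0.17/h for time, 0.09 per
  NIHSS point) put realized |r| near 0.75 given onset ~ U(0.5, 24) h and
  NIHSS ~ U{0..42}, i.e. inside the 0.60–0.85 band the analysis expects;
- per-(batch, transcript) offsets ~ N(0, 0.15), per-transcript age/sex
  coefficients ~ N(0, 0.03)/N(0, 0.05), and a per-sample library-size
  offset ~ N(0, 0.25).

Default cohort structure is 13 hemorrhagic / 29 ischemic / 42 mimic — the
84-sample training cohort of the source study; TIA and unknown-diagnosis
samples can be appended to exercise exclusion rules. Ages are
N(60, 12) truncated to [18, 100] (adult stroke cohort); sex is 0/1;
onset and NIHSS can be masked at configurable rates (default 0).

**What the generator does not emulate:** library depths are in the ~10⁵
range rather than millions of reads (effects are calibrated on the log
scale, where depth mostly cancels through CPM); NIHSS is uniform rather
than the right-skewed distribution of real admissions; expression is
independent across transcripts given covariates (no co-expression
modules); there are no isoform structures, rRNA contamination or
wake-up-stroke onset censoring. Passing tests therefore demonstrate that
the pipeline recovers the structure it assumes, at desk-scale problem
sizes — not that the published patient-level accuracies transfer.

## Preprocessing

TMM follows the edgeR definition exactly (reference library by the
75th-percentile rule; two-sided trims of 30% on M and 5% on A;
inverse asymptotic-variance weights; factors rescaled to geometric mean
1) and is verified against `edgeR::calcNormFactors` in the test suite.
Expression is log2-CPM with a prior count of 0.5 on TMM-effective
library sizes; precision weighting of the mean–variance trend is
deliberately not implemented — differential expression uses ordinary
least squares on log2-CPM, which reproduces the retained-transcript rule
(1.5-fold, p < 0.05) without the full limma machinery. The
low-expression default keeps transcripts with CPM ≥ 1 in ≥ 25% of
samples.

Batch adjustment is a per-transcript, per-batch location-scale
standardization to the grand mean and pooled within-batch SD — a simple,
rank-preserving stand-in for count-level batch regression. It is only
ever applied within one pool (e.g. the combined validation sets), never
across the train/validation boundary, which would leak distributional
information between cohorts.

## Feature selection

Differential expression fits, per transcript, `log2CPM ~ group + age +
sex` by (optionally weighted) least squares, vectorized across
transcripts; the group coefficient is the log2 fold change and its
two-sided t-test the p-value (checked against statsmodels OLS).
Constant transcripts report log2fc 0, p 1. The retention rule gates on
raw p < 0.05 together with |log2fc| ≥ log2 1.5 — exactly as the printed
rule states, with BH q-values computed and reported alongside. Top-50
up/down lists break ties by effect magnitude, then smaller p, then
transcript ID, so panel inputs are reproducible.

Condition-specific sets are the **intersection** of a condition's two
pairwise contrasts' survivors (altered relative to *both* other groups);
cross-condition uniqueness is then applied. A union-based attribution
would place every pairwise hit in two conditions at once and no
transcript could ever be condition-unique.

Covariate balance ahead of DE uses greedy full matching on Mahalanobis
distance (ridge 1e-6 if the covariate covariance is singular): each
minority-group sample claims its nearest unclaimed control, remaining
controls attach to their nearest matched set; treated weight 1, controls
share weight 1 per set. The tested contract is reduction of the
weighted standardized mean difference, not matching optimality.

Correlation screening computes Pearson r of log2-CPM (the scale is a
package choice; the source text does not state one) against onset hours
or NIHSS over non-missing samples, p from the t transform, q by BH;
selection is |r| ≥ 0.6 and q < 0.05. Replication across cohorts
additionally requires sign-concordant r with |r| ≥ 0.40 in validation —
an anti-correlated "replication" would be spurious.

## Gaussian HMM

Emissions are diagonal Gaussians; with 3–5-transcript panels and ~84
training samples, full covariances risk singular fits. Two sequence
modes exist because cross-sectional patients have no natural ordering:

- `per_sample` (default): every sample is a length-1 sequence. There are
  no transitions, the initial distribution coincides with mixture
  weights, the transition matrix is frozen uniform and excluded from the
  BIC parameter count, and EM is exact Gaussian-mixture EM.
- `concatenated`: rows form one ordered sequence, fitted by Baum–Welch
  with scaled forward–backward; provided to probe the alternative
  reading (e.g. samples ordered by onset time).

Initialisation slices the first principal direction into K quantile
groups (restart 0 jitter-free; later restarts add 0.25·SD jitter);
defaults: 10 restarts (4 in the panel-search inner loop), tol 1e-6
relative log-likelihood, max 500 iterations, variance floor 1e-6. EM
monotonicity is asserted every iteration (1e-8 slack); the best restart
by final log-likelihood wins, ties to the earliest, so fits are
bit-reproducible per seed. Forward–backward is verified against
exhaustive path enumeration and against hmmlearn on fixed parameters.
BIC is −2 log L + p ln n with n the number of observations.

## Panel search and evaluation

Single-transcript screening fits a 1-D HMM per candidate, maps states to
labels by majority posterior vote (ties toward the rarer, positive
class), classifies at posterior 0.5 and passes transcripts with training
accuracy 1.0 (configurable floor); constant transcripts are flagged
degenerate and never pass. Panels are all subsets of sizes 3–5 of the
passing set, lexicographically ordered, with a 250,000-panel cap that
refuses rather than subsamples. When fewer transcripts pass than the
minimum panel size, the pool is backfilled with the highest-accuracy
non-degenerate transcripts — panels are built from perfect *or
near-perfect* separators — which also lets null-data audits run to
completion instead of erroring.

Evaluation freezes everything on training: the fit, the state→class
map, and the decision threshold (Youden's J maximized over midpoints of
adjacent sorted unique training posteriors; ties to the smallest
candidate; under complete separation this is the midpoint of the
separating gap). Validation data are scored with the frozen model only;
a test perturbs validation data and asserts bit-identical parameters.

Among panels, the representative is chosen deterministically:
max min(train, validation accuracy) → widest training separating gap
(threshold stability) → fewest transcripts → fewest unannotated MSTRG
members → lexicographically smallest tuple. This ladder is this
package's formalization of "consistent performance, threshold stability,
interpretability"; reports flag it as such.

## Triage cascade

Stage 1 (hemorrhage vs rest) runs on all samples; stage 2 (ischemic vs
mimic) on stage-1 negatives; window and severity classifiers on samples
called ischemic (a flag runs them on all samples for research use). The
window label is onset ≤ 3.5 h **inclusive**, samples missing onset are
excluded from that task; the severity boundary assigns NIHSS 5 to the
severe class (positive iff NIHSS ≥ 5) — the source's text ("<5" vs ">5")
leaves 5 unassigned while its figure partitions at >4 vs ≤4; the ≥5
convention matches the figure and is a config knob. Sensitivity or
specificity with a zero denominator is reported as undefined, never
silently zeroed, so cohorts lacking a class (e.g. a held-out set with no
hemorrhages) audit cleanly.

## Problem sizes and determinism

The test suite and acceptance script run cohorts of 84–168 samples and
53–2,000 transcripts, 20-seed replicate loops for the stochastic
properties, and exhaustive path enumeration up to K = 3, T = 4 — sizes
at which every stage's behaviour is measurable in seconds while
preserving the cohort proportions of the study design. All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical seeds give bit-identical studies, fits, panels and reports.

## Known limitations

Severity and window classification on the default generator are
intrinsically harder than subtype classification: those labels threshold
a *continuous* planted gradient (at NIHSS 5 and 3.5 h) rather than
separating discrete planted classes, so a 2-state mixture splits the
gradient near its middle, not at the clinical cutoff, and validation
accuracy is honest-but-imperfect there. The pipeline does not implement
read-level processing, count-level batch regression, GO enrichment, the
caret/SMOTE/XGBoost benchmarking arm, optimal (network-flow) full
matching, or voom precision weights.
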