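# Methods

`ctcnet` re-implements, as a tested and reusable pipeline, a
cerebello-thalamo-cortical (CTC) connectivity analysis for survivors of
childhood acute lymphoblastic leukemia treated with chemotherapy only:
functional connectivity graphs and metrics, permutation inference for
group differences, score-based Bayesian-network effective connectivity
with a sex × impairment interaction test, and cohort statistics linking
morphometry, chemotherapy exposure, and neurocognitive z-scores.  Because
the subject-level study data are not deposited, a synthetic-cohort
generator is a first-class component: it emulates the statistical
structure every downstream stage assumes, so the whole pipeline runs with
no download.

## The synthetic cohort

**What it emulates.**  A cohort of 87 male and 89 female survivors
(configurable).  Per subject: age at diagnosis (mean 6.8, SD 4.5 years,
clipped to 1–18), age at evaluation (diagnosis age + 7.7 ± 1.7 years),
intracranial volume, cerebellar and thalamic volumes and precuneus/DLPFC
cortical thicknesses drawn per sex from published survivor-cohort
means/SDs with a 0.3 coupling to intracranial volume, dexamethasone and
methotrexate area-under-curve exposures, and an intrathecal-administration
count (uniform 13–25).  Exposure scales are free parameters (only
regression coefficients, not exposure distributions, are published);
defaults were chosen once so that realistic coefficient magnitudes are
numerically stable.

**Neurocognitive scores.**  Each measure's age-adjusted z-score is
generated as `z = mean(sex) + Σ β·(covariate − sex mean) + σ(sex)·ε`, with
per-sex reference means/SDs taken from the published survivor
distributions (e.g. male verbal fluency −0.49 ± 1.03, male Rey–Osterrieth
copy −2.44 ± 2.37).  All scores are stored lower-is-worse (timed measures
are sign-flipped at ingestion).  Default planted brain–behavior effects
are modest (e.g. 5×10⁻⁵ z per mm³ of left cerebellar volume on the
Rey–Osterrieth copy) and exist so that regression-recovery tests have a
known truth; tests that assert recovery always configure their own
effects explicitly.

**Impairment.**  A subject is impaired when any executive measure
(number–letter switch, color–word switch, verbal fluency, digit backward,
Rey–Osterrieth copy, 20 questions) has z strictly below −1.3 (the
operational 10th percentile).  By default the label is *derived* from the
generated scores, so label and scores are consistent by construction and
prevalence is emergent — with the published score distributions roughly
85% of subjects are impaired, driven almost entirely by the
Rey–Osterrieth means near −2.4 (the published per-measure impairment
rates for that test alone are 55–63%).  When an explicit per-sex
prevalence is supplied instead, labels are binomial draws and the
executive scores are rejection-sampled to agree with them.

**Time series.**  ROI signals come from a contemporaneous linear-Gaussian
structural model: at each timepoint, nodes are evaluated in topological
order as `child = Σ weight·parent + noise`, with optional stationary
AR(1) smoothing of the innovations (default off, keeping timepoints
i.i.d., which matches the structure learner's likelihood).  This model
family was chosen because the downstream Bayesian-network learner assumes
Gaussian conditional-linear dependence; no generative claim about
hemodynamics is made.  The default 174 timepoints is floor(360 s / 2.06 s)
— six minutes of rest at the study TR; the retained volume count after
scrubbing is not published, so this is a derived, configurable default.

**Planted group structure.**  All groups except impaired females share,
per hemisphere: cerebellum → thalamus, cerebellum → DLPFC,
precuneus → DLPFC (weight 0.5, noise SD 1).  Impaired females have the
cerebellum–DLPFC edge reversed (DLPFC → cerebellum) and *attenuated*
(weight 0.25), and no DLPFC–precuneus edge.  The attenuation is
deliberate: within a linear-Gaussian model a pure direction reversal of a
single edge is Markov-equivalent to the original and therefore
undetectable from observational data; the group difference reported for
the real cohort concerns both directionality *and* connectivity strength,
so the planted effect includes both.  There is intentionally no
thalamus → DLPFC edge, so the reversal cannot create a cycle.  A weakly
coupled six-region language control network (bilateral BA 40/44/45,
weight 0.25, identical in every group) is available for control analyses.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic response and autocorrelation
structure beyond AR(1); measurement noise and motion artifacts;
between-subject variation in connection strengths within a group (all
subjects of a group share one ground-truth network); correlations between
neurocognitive measures beyond shared covariate effects; non-Gaussian
score distributions; missing data.

## Functional connectivity and graphs

Pairwise Pearson correlations between ROI time courses are Fisher-z
transformed, with r clipped to ±(1 − 10⁻⁷) so degenerate inputs stay
finite.  Graphs are binary, built by proportional density thresholding:
the ⌈d·n(n−1)/2⌉ largest positive z-values become edges.  Negative
correlations are never admitted (common connectomics practice); ties are
broken by lexicographic region-pair order so edge sets are exactly nested
across densities and results are bit-reproducible.  "Removing
false-positive connections" is operationalized as the minimum-density
search: the smallest grid density (default grid 0.05–0.50, step 0.01) at
which no region is isolated.  Subjects for whom even the largest grid
density leaves isolated regions are reported as fragmented, with the
persistently disconnected regions listed; an alternative edge-significance
mode (per-edge correlation test with Benjamini–Hochberg FDR) is available
behind a flag.  Thresholding is per-subject by default; a group-mean
matrix mode is provided.  The pipeline computes metrics at the
cohort-common minimum density (the largest per-subject minimum among
non-fragmented subjects), mirroring the idea of a common threshold that
fragmented subjects fail to reach.

Global efficiency is the binary (hop-count) definition,
E = mean over ordered pairs of 1/d_ij with 1/∞ = 0, so it is defined on
fragmented graphs; fragmented subjects are flagged and summarized
separately rather than dropped.  The within-module degree z-score uses
the population (divide-by-n) SD of within-module degrees, with z = 0 for
modules with zero degree spread (including singletons); this is the
standard Guimerà–Amaral convention, stated explicitly because either SD
convention is defensible.  The default partition is anatomical
(cerebellar / thalamic / frontal / parietal); a hemispheric partition is
provided for left/right subnetwork analyses.

## Permutation inference

Group differences in network metrics are tested by shuffling subject
labels (the subject is the exchangeable unit), recomputing the mean
difference for each of 2000 shuffles by default.  The default p-value is
the literal one-sided rule — the proportion of permutation mean
differences ≥ the observed difference, with no +1 correction — because
that is the printed procedure; it can return p = 0, so a +1-corrected
and a two-sided variant sit behind flags.  The 95% interval of the null
distribution is reported alongside (observed differences outside it are
significant at that level).  For cohorts of ≤ ~10 subjects the full
assignment enumeration replaces sampling.

## Effective connectivity

Structure learning is greedy hill-climbing over add/delete/reverse
single-edge moves, scored by the decomposable Gaussian BIC
(−(n/2)·log(RSS/n) − (|parents|+2)/2·log n per node), with per-node score
caching and random restarts (default 10; restart 0 is always the empty
graph, so the returned model never scores below it).  Ties and move order
are deterministic given the seed.  The score family and search are
choices of this package — only "score-based structure learning" is
specified by the source analysis.

For stratified fits (sex × impairment) and the whole-cohort common model,
each subject's regional series are z-standardized and rows concatenated;
the pooling scheme is a documented choice since the original is unstated.
Because edge direction between two Gaussian variables is not identifiable
in isolation, structural comparisons are reported both at the raw-DAG
level (added/removed/reversed edges, structural Hamming distance) and at
the equivalence-class level (skeleton + v-structures), which is exactly
what the data can distinguish.  At the default sample sizes the learner
recovers the planted structure's skeleton and v-structures essentially
always; its occasional error mode is one spurious extra edge in roughly a
third of replicates at 500 timepoints — the expected finite-sample
false-discovery behavior of BIC (≈22 null pairs at ≈1.3% each), which
vanishes as n grows.

Per-subject connectivity weights regress each child on its common-model
parents within that subject's panel.  Standardized coefficients (default)
are scale-free and appropriate for arbitrary-unit ICA time courses and
for the cohort ANOVA; raw-scale coefficients (``standardize=False``)
recover generative coefficients directly and are used in recovery tests.
The cerebellum–DLPFC analysis takes the common-model edge between those
labels in either orientation (direction is carried by the parent→child
record) and averages a subject's left/right matching edges.  The
sex × impairment comparison is a two-way fixed-effects ANOVA with
interaction, using Type II sums of squares because the crossed cells are
unbalanced; each cell must contain at least two subjects.

## Cohort statistics

Impairment proportions are reported in percent with Wald 95% intervals
(z = 1.96), clipped to [0, 100] — the interval family that reproduces the
published table arithmetic exactly, e.g. 17/104 → 16.35 (9.24–23.45);
Wilson is available behind a flag, and the Wald interval degenerates with
a warning at k ∈ {0, n}.  Comparisons against the reference population
(μ = 0, σ = 1) are classical one-sample two-sided t-tests.  The
brain–exposure–cognition models are sex-stratified OLS fits adjusting for
age at diagnosis, age at assessment, and intracranial volume; by default
the regional measurement is the response (so coefficients carry the
conventional units: mm³ per 1-SD z, mm³ per g×hr/L, mm³ per intrathecal
count), with a score-response orientation available that matches the
generator's causal direction and is the one used for recovery checks.
Designs are checked for full rank before fitting, and collinear columns
are named.  Correlations are Pearson with t-based two-sided p.  FDR
control is Benjamini–Yekutieli step-up by default (harmonic-sum factor
c(m) = Σ 1/i, valid under arbitrary dependence), with Benjamini–Hochberg
available; BY rejections are always a subset of BH rejections at the same
level.

## Reproducibility and numerics

A single global seed deterministically derives per-stage and per-subject
seeds by SHA-256 name hashing (always < 2³¹), so any stage can be rerun
in isolation from the seeds recorded in the run manifest; rerunning an
identical config reproduces byte-identical numeric outputs.  Strict
score-improvement in the hill climber uses a 10⁻⁹ tolerance to avoid
floating-point cycling; residual sums of squares are floored at 10⁻³⁰⁰ so
exact interpolation does not produce −∞ scores.

Problem sizes in the test and acceptance suites are chosen to keep a full
run on one CPU in the low minutes: exhaustive graph-oracle checks cover
all graphs on ≤ 6 nodes; permutation calibration uses 1000 null
replicates of 20+20 subjects at 500 permutations; structure recovery uses
50 replicates at 500 timepoints; ANOVA power uses 100 replicates of the
full 176-subject cohort with the common model learned once (it is a
single fixed best-fit structure) and weights/ANOVA recomputed per
replicate.

## Known limitations

* Region identity is purely a label; no atlas geometry or voxel data are
  touched, and ICA-component-to-region assignment is out of scope.
* The permutation test's printed one-sided rule can return p = 0; the
  +1-corrected variant exists for small-sample use.
* BIC structure learning at a few hundred timepoints carries a small
  false-edge rate (see above) and cannot orient edges beyond the
  equivalence class.
* The generator's group networks are homogeneous within group; real
  cohorts have subject-level heterogeneity that would widen the ANOVA
  weight distributions.
* Exposure scales and their β defaults are package conventions, not
  published distributions; only relative/recovered effects are
  meaningful.
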