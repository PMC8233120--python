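# Methods

## Data model

A cohort is an atlas, a subject table and per-subject connectomes. The
default atlas has 109 regions: 54 homotopic left/right pairs (matched by
name, `<base>_L` / `<base>_R`) plus the bilateral brainstem. Four
resting-state networks of five bilateral regions each are labelled 1–4
along the transmodal→unimodal functional gradient (default mode,
attention, primary visual, motor/sensorimotor); one region per
hemisphere is flagged as the anterior hippocampus (the presumed seizure
focus). Matrices are symmetric with an ignored (zero) diagonal. FC is
Fisher-z and complete; for SC and LEN a value of exactly zero means the
edge was not detected and is carried as missing — never as a small
count, and never pseudocounted.

Patients carry a focus side. The canonical ipsi/contra frame places
ipsilateral regions in the left-hemisphere slots: a left-focus patient
is untouched, a right-focus patient has every region swapped with its
homotopic partner (an involution; bilateral regions are fixed points).
Controls are never flipped — all control-side computations run in
native left/right space.

## Age normalisation

Per edge, OLS of control values on age (natural log for SC over present
edges only). The fit RMSE uses the biased 1/n denominator (a `n-2`
switch exists); `res` is the residual, `corr` = res / RMSE, i.e. SD
units from an age-matched control. Edges present in fewer than 3
controls are unfittable and propagate as missing, as do edges missing in
the subject; an edge with zero residual variance (degenerate) is missing
in `corr` only. Controls are corrected with the model fitted on all
controls (no leave-one-out — switchable in principle but not exposed, as
nothing downstream compares control corr values across controls).

## Distance models and binning

Matrix topologies (LEN, SC, FC) are element-wise control means per
hemisphere over the 55-region block (54 + brainstem); an edge missing in
every control is missing (NaN) in the topology and excluded from
binning. FC averages signed z-values; ranking then uses the absolute
value of the averaged FC. The RSN model is the atlas labels themselves.

Seed edges are ranked — LEN ascending, FC by descending |z|, SC
descending — and chunked into contiguous near-equal bins, earlier bins
taking the remainder (54 edges, 5 bins → 11/11/11/11/10). Ties break by
region index (stable sort). Default bin counts are 5 for LEN and FC and
4 for SC and RSN: the SC topology can lose edges absent from the control
average, and the RSN model has exactly four classes. The brainstem
carries RSN label 0 and therefore never enters RSN bins.

## The deviation statistic

M = (s − μ)ᵀ C⁻¹ (s − μ) on res-scale values, squared form by default
(`squared=False` returns the root). C is the Ledoit–Wolf shrinkage
estimator toward a scaled identity, guaranteeing positive definiteness
at 50 controls × 7 edges. The subsampling scheme holds k = 7 constant
across bins of 10–11 edges and absorbs missing SC edges:

* outer loop — 500 (default) random 7-edge subsets of the bin; a draw is
  discarded if the patient is missing a drawn edge;
* inner loop — 500 random 50-of-70 control subsets; controls missing a
  drawn edge are excluded from that draw, and the draw is discarded if
  fewer than 45 complete controls remain.

The reported M is the mean over all retained (edge, control) pairs
(pooled); the mean of per-outer inner means is also reported, the two
differing only when discard counts vary across outer draws. RNG streams
derive deterministically from (seed, patient id, modality, hemisphere,
topology, bin), so results are reproducible and independent of
evaluation order. For throughput, the inner loop is evaluated as batched
linear algebra: draw-indicator matrices multiply per-control outer
products, yielding every draw's mean, covariance, shrinkage intensity
and quadratic form in a handful of BLAS calls; the batched shrinkage is
verified against `sklearn.covariance.ledoit_wolf` to ~1e-12 in the unit
tests. The desk-scale profile used throughout the tests is 100×100
permutations (50×50 in the 200-replicate calibration run), which the
Monte-Carlo-error tests show is already well past the point where the
subsampling noise is negligible relative to between-patient variance.

## Gradient hypothesis test

Three simultaneous criteria: (1) one-way repeated-measures ANOVA (bin as
within-subject factor, no sphericity correction) significant at alpha —
0.05/4 when four topologies are examined for a modality, 0.05/3 when the
RSN model is excluded for SC (its bins span cross-hemisphere edges where
SC is unreliable); (2) strictly decreasing bin means; (3) no uncorrected
two-sided paired t-test showing a higher-index bin significantly
(p < 0.05) above a lower-index one. Patients with any undefined bin are
dropped with a warning; fewer than 3 complete patients is an error. The
duration analysis groups patients at (≤10, 11–30, >30] years, repeats
the test per group (≥3 members), and reports the bin-by-group
interaction of a mixed ANOVA (pingouin, conventional degrees of
freedom). ANOVAs are delegated to pingouin and paired tests to scipy.

## Whole-brain hybrid ICA

The joint matrix stacks each patient's FC_corr and SC_corr upper
triangles (ipsi/contra frame). SC edges missing in >10% of patients are
dropped; remaining missing entries are imputed as 0 = the age-expected
control level. FC and SC columns enter jointly without block rescaling,
both already being in control-SD units. PCA (patients as observations,
edges as variables) fixes the source count at the smallest number of
components reaching 90% cumulative explained variance; FastICA then runs
in edge space (edges as samples), once per seed, 40 times by default; a
run that hits the iteration cap without converging is dropped and
counted. Components are z-scored over edges — thresholds are therefore
in component-SD units — with weights rescaled to compensate.

Merging replaces the order-dependent greedy pairing with connected
components of the |r| > 0.8 graph, sign-aligned before averaging, and
repeats until every merged pair sits below the threshold; identification
frequency is distinct contributing runs / converged runs. Components are
sign-flipped so the Spearman correlation of weights with duration is
non-negative. Selection keeps components significant at 0.05 after
Bonferroni correction across the merged set (ties broken by largest
rho): with dozens of merged components an uncorrected 0.05 screen would
flag a noise component in a large fraction of null cohorts, which the
negative-control tests here are designed to exclude; an `"none"` option
restores the uncorrected screen. An empty selection is a result, not an
error.

Degree projection zeroes edges below ±0.55 (FC) / ±0.175 (SC) and sums
the surviving signed incident values per region ("net connectivity"; an
absolute-value variant exists). A density mode instead solves the
threshold for a target edge density (20% by default) — useful because
fixed thresholds are scale-dependent while ICA components are only
defined up to scale; the recovery tests use the density mode. Model
correlations average the left- and right-hemisphere model distances for
each homotopic pair (the degree lives in the ipsi/contra frame, the
models in native space), exclude the seed pair and regions with
undefined distance, and use Pearson for LEN/SC/FC and Spearman for the
ordinal RSN labels at the 0.0125 family threshold.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not the biophysics (no BOLD, no tractography):

* geometry — mirror-symmetric random 3-D coordinates; latent LEN =
  Euclidean distance × 1.2 tortuosity; per-subject LEN adds 3% relative
  jitter and inherits the SC missing mask;
* FC — mean Fisher-z = 0.7·exp(−LEN/60 mm) plus a per-edge linear age
  trend (slope ~ N(0, 0.004 z/y)) and N(0, 0.2) between-subject noise;
* SC — log-normal, log-mean = 3 − 0.04·LEN, age slopes N(0, 0.008/y),
  dispersion 0.5; edges drop out per subject with probability 0.30
  cross-hemisphere and 0.02 within (undetected ⇒ exactly 0);
* cohort — 70 controls, 40 patients (29 right-sided), ages uniform
  18–71; duration ~ N(21, 15²) truncated to [2, 50] and resampled to
  respect duration < age so the patient age marginal equals the
  controls' (with a zero effect profile the groups are exchangeable by
  construction, which the null tests exploit);
* focal effect — edges from the ipsilateral anterior hippocampus to
  same-hemisphere regions, binned by the latent LEN from the seed, are
  shifted by profile[b]·(duration/30)·SD on the FC and log-SC scales
  (default profile (3, 2.25, 1.5, 0.75, 0) control-SD at the 30-year
  reference, direction negative, i.e. connectivity loss; both the
  exponent of the duration growth and the direction are parameters,
  since the deviation statistic is unsigned);
* whole-brain component — `plant_ica_component` adds a rank-1 edge
  pattern (random sign-consistent support, or magnitudes decaying with
  latent LEN from the focus) in the ipsi/contra frame, mapped into each
  patient's native orientation, with a per-patient loading mixed from
  duration ranks and orthogonalised noise so the realised Spearman
  correlation is as close as possible to the requested target (target
  1.0 is exact by construction).

What passing tests show — and what they do not: parameter recovery on
these cohorts demonstrates that the statistics detect the structures
they were designed for at realistic sample sizes and noise levels. Real
connectomes have heavier tails, spatially correlated noise, site and
motion effects and atlas misregistration, none of which the generator
emulates; results on real data additionally depend on preprocessing
choices upstream of this package.

## Problem sizes and numerical choices

The test suite and acceptance script run the full 70 + 40 cohort with
100×100 permutations for single-replicate checks and recovery runs
(20 replicates), 50×50 permutations with a 40 + 15 cohort (30-of-40
control draws, ≥27 complete) for the 200-replicate type-I calibration,
and 10 ICA runs for component recovery — sizes chosen so the whole
battery completes on a laptop-class single core. Full-fidelity settings
(500×500, 40 ICA runs) are the library defaults and sit behind the
CLI's `--full` flag.

Degenerate inputs: zero age variance among controls is an error;
rmse = 0 edges are flagged, not divided by; a bin with zero retained
draws yields an undefined M with a recorded reason; an ANOVA on
zero-variance profiles reports NaN and a false verdict; a constant
degree vector reports an undefined correlation. Matrix I/O uses 17
significant digits and round-trip float parsing, making save/load bit
exact.

## Known limitations

* The repeated-measures ANOVA on raw M profiles is mildly
  anti-conservative under the null: every patient is referenced to the
  same finite control sample, so each bin carries a common offset in
  E[M | controls] that the within-subject test reads as a bin effect.
  The suite measures this directly — null cohorts at study size produce
  an excess of small ANOVA p-values, while the same statistic computed
  against private per-patient control pools
  (`test_progression_calibration.py`) is calibrated. The full
  three-criterion verdict (ANOVA + strictly decreasing means + pairwise
  direction checks) remains conservative, since the offset mechanism
  does not impose an ordering on the bins.
* The mixed-ANOVA degrees of freedom follow the conventional
  formulation; no sphericity correction is applied anywhere by default.
* Connected-component merging can, in principle, chain dissimilar
  components through intermediates; the iterated re-merge keeps the
  final set pairwise below the threshold but is not a clustering
  optimum.
* The fixed ±0.55/±0.175 degree thresholds presume component-SD
  scaling; use the density mode when comparing across cohorts.
* Exchangeability of null patients and controls holds by construction
  only for the generator's sampling scheme; with `fixed_duration` the
  patient age marginal is truncated from below.
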