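# netprog

Analysis pipeline for measuring how MRI network alterations in unilateral
mesial temporal lobe epilepsy (mTLE) are organised by the architecture of
the *healthy* brain — and how they evolve with duration of disease.

In mTLE, seizures originate in one hippocampus. The working hypothesis is
that network change is not spatially random: it is largest "close" to the
presumed focus (the anterior hippocampus) under some healthy-brain notion
of distance, and decays outward over decades of disease. `netprog`
implements that analysis for cohorts of per-subject connectomes in three
modalities — functional connectivity (FC, Fisher-z), structural
connectivity (SC, volume-scaled streamline counts, with undetected edges
treated as missing) and mean streamline length (LEN) — plus a synthetic
cohort generator with planted ground truth so that every stage is
testable end to end without any imaging data.

## The method

**Age normalisation.** For each edge, an OLS line of the control values
against age (SC on the log scale) yields residual connectomes
(FC_res/SC_res) and SD-standardised ones (FC_corr/SC_corr = residual /
fit RMSE).

**Distance models.** Four healthy-brain topologies *T* rank "distance"
from a seed region *n* via the model vector (row of the topology)

  R × T = [T(n,1), …, T(n,N)]

with T the control-averaged LEN, SC or FC connectome (within hemisphere,
N = 55), or membership in four resting-state networks ordered along the
transmodal→unimodal gradient (default mode > attention > primary visual >
motor/sensorimotor; N = 109).

**Hippocampal gradient.** Seed edges are ranked by a topology and chunked
into 4–5 bins of ~10 edges (bin 1 = closest/strongest). Each patient's
deviation from the controls over a bin is the squared Mahalanobis
statistic

  M = (s − μ)ᵀ C⁻¹ (s − μ)

with s the patient's residual edge values, μ and C the control mean and
Ledoit–Wolf-shrunk covariance. Because bins differ in size and some SC
edges are undetected, M is averaged over nested subsampling: random
7-edge subsets (draws where the patient lacks an edge are discarded)
crossed with random 50-of-70 control subsets (draws with fewer than 45
complete controls are discarded). The decreasing-gradient hypothesis
(M bin 1 > … > bin 5) must pass three criteria: a significant
repeated-measures ANOVA at the Bonferroni-adjusted alpha, monotonically
decreasing bin means, and no pairwise t-test showing a farther bin
significantly above a closer one. Patients are also split into short
(≤10 y), medium (11–30 y) and long (>30 y) duration groups with a mixed
ANOVA on the bin-by-group interaction.

**Whole-brain hybrid ICA.** Patient FC_corr and SC_corr connectomes
(flipped into an ipsilateral/contralateral frame) are concatenated
edge-wise, reduced by PCA to 90% variance, and decomposed with FastICA
40 times; near-duplicate components across runs (|r| > 0.8) are merged.
Components whose patient weights correlate with duration of disease
(Spearman) are projected to a per-region weighted degree after edge
thresholding, and the degree vector is correlated against the four
distance models (Pearson; Spearman for the ordinal RSN model; family
threshold 0.0125).

## Worked example

```bash
python examples/03_hippocampal_gradient.py
```

simulates 70 controls and 40 patients with a planted per-bin effect
profile of (3, 2.25, 1.5, 0.75, 0) control-SDs at 30 years duration,
profiles every patient at 100×100 permutations, and prints:

```
group-mean M per bin: [73.  44.1 24.9 10.4  6.7]
RM-ANOVA F(4, 156) = 282.0, p = 2.72e-70
means monotonically decreasing: True
verdict (all three criteria): True
```

The deviation is largest on the seed edges closest to the anterior
hippocampus and decays across bins — the planted gradient is recovered.
Other scripts in `examples/` demonstrate the generator, age
normalisation, the hybrid ICA with a planted duration-linked component,
and the Euclidean-vs-Mahalanobis contrast on a 2-D toy cloud.

A thin CLI mirrors the library (`netprog simulate | normalize | models |
hippocampal | wholebrain | run | report`), each stage reading/writing
plain TSV/CSV/JSON files; `netprog run --config cfg.json --out dir` runs
everything from one config and writes a run manifest and report.

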