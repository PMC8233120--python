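"""Hybrid functional-structural connectome ICA across patients.

Each patient contributes one row built by concatenating the upper
triangles of the FC and SC deviation connectomes (corr scale, SD units
from age-matched controls, ipsi/contra frame). FastICA — run repeatedly
because of its stochastic initialisation, after a PCA retaining 90% of
variance — yields edge-space components with per-patient weights; near-
identical components across runs are merged, components whose weights
track duration of disease are selected, and a thresholded weighted degree
projects the selected component onto region space, where it is compared
with the healthy-brain distance models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA, FastICA

from .agenorm import CorrectedCohort
from .core import Cohort, EdgeIndexMap, edge_index_map, to_ipsi_contra
from .topology import TopologyModel, model_vector


@dataclass
class ICAConfig:
    n_runs: int = 40
    merge_r_threshold: float = 0.8
    pca_variance: float = 0.90
    fc_threshold: float = 0.55
    sc_threshold: float = 0.175
    max_sc_missing_fraction: float = 0.10
    selection_alpha: float = 0.05
    selection_correction: str = "bonferroni"   # or "none"
    degree_mode: str = "threshold"             # or "density"
    target_density: float = 0.20
    degree_kind: str = "net"                   # signed sum; "abs" available
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pca_variance <= 1.0:
            raise ValueError("pca_variance must be in (0, 1]")
        if self.fc_threshold < 0 or self.sc_threshold < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class JointMatrix:
    """Patients-by-edges hybrid matrix with column provenance."""

    X: np.ndarray                  # (n_patients, n_fc + n_sc)
    patient_ids: list[str]
    emap: EdgeIndexMap             # full upper-triangle edge map (one block)
    fc_cols: np.ndarray            # edge indices (into emap) of FC columns
    sc_cols: np.ndarray            # edge indices of retained SC columns

    @property
    def n_fc(self) -> int:
        return len(self.fc_cols)

    def split(self, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a joint column vector into full FC / SC edge vectors
        (dropped SC columns filled with 0)."""
        fc = np.zeros(len(self.emap))
        fc[self.fc_cols] = v[:self.n_fc]
        sc = np.zeros(len(self.emap))
        sc[self.sc_cols] = v[self.n_fc:]
        return fc, sc


def build_joint_matrix(cohort: Cohort, corrected: CorrectedCohort,
                       max_sc_missing_fraction: float = 0.10) -> JointMatrix:
    """Concatenate FC_corr and SC_corr rows per patient, ipsi/contra frame.

    SC edges missing in more than ``max_sc_missing_fraction`` of patients
    are dropped; remaining missing entries are imputed as 0 (the
    age-expected control level).
    """
    patients = cohort.patients()
    if not patients:
        raise ValueError("cohort has no patients")
    atlas = cohort.atlas
    emap = edge_index_map(atlas.n_regions)
    fc_rows, sc_rows, sc_miss = [], [], []
    for p in patients:
        fc = to_ipsi_contra(corrected.corr[(p.subject_id, "FC")],
                            p.focus_side, atlas)
        sc = to_ipsi_contra(corrected.corr[(p.subject_id, "SC")],
                            p.focus_side, atlas)
        fc_rows.append(fc.matrix[emap.row, emap.col])
        sc_rows.append(sc.matrix[emap.row, emap.col])
        sc_miss.append(sc.missing_mask[emap.row, emap.col])
    fc_rows = np.asarray(fc_rows)
    sc_rows = np.asarray(sc_rows)
    sc_miss = np.asarray(sc_miss)
    keep = sc_miss.mean(axis=0) <= max_sc_missing_fraction
    sc_block = np.where(sc_miss[:, keep], 0.0, sc_rows[:, keep])
    X = np.concatenate([fc_rows, sc_block], axis=1)
    return JointMatrix(X=X, patient_ids=[p.subject_id for p in patients],
                       emap=emap, fc_cols=np.arange(len(emap)),
                       sc_cols=np.flatnonzero(keep))


@dataclass
class ICARuns:
    components: np.ndarray         # (n_components_total, n_cols), z-scored
    weights: np.ndarray            # (n_components_total, n_patients)
    run_index: np.ndarray          # run of origin per component
    n_runs_requested: int
    n_runs_converged: int
    n_pca_components: int


def pca_component_count(X: np.ndarray, pca_variance: float) -> int:
    """Smallest number of principal components reaching the variance goal."""
    n_max = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_max, svd_solver="full" if min(X.shape) < 500
              else "randomized", random_state=0)
    pca.fit(X - X.mean(axis=0))
    cum = np.cumsum(pca.explained_variance_ratio_)
    if pca_variance >= cum[-1]:
        return n_max
    return int(np.searchsorted(cum, pca_variance) + 1)


def run_hybrid_ica(joint: JointMatrix, config: ICAConfig) -> ICARuns:
    """Repeated FastICA in edge space.

    The patients-by-edges matrix is column-centred; the number of sources
    equals the number of principal components needed for
    ``config.pca_variance`` of the variance. Each run is seeded from
    (config.seed, run index); a run that fails to converge is dropped and
    counted. Components are returned z-scored over edges (so thresholds
    are in component-SD units) with per-patient mixing weights.
    """
    X = joint.X
    if X.shape[0] < 3:
        raise ValueError("need at least 3 patients for the hybrid ICA")
    Xc = X - X.mean(axis=0)
    q = pca_component_count(X, config.pca_variance)
    comps, weights, run_idx = [], [], []
    n_converged = 0
    for run in range(config.n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, run]))
        ica = FastICA(n_components=q, whiten="unit-variance",
                      max_iter=500, tol=1e-4,
                      random_state=np.random.RandomState(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S = ica.fit_transform(Xc.T)        # (n_edges, q) sources
        if ica.n_iter_ >= 500:
            warnings.warn(f"ICA run {run} did not converge; dropped")
            continue
        n_converged += 1
        A = ica.mixing_                        # (n_patients, q)
        sd = S.std(axis=0)
        sd[sd == 0] = 1.0
        comps.append((S / sd).T)
        weights.append((A * sd).T)
        run_idx.extend([run] * q)
    if not comps:
        raise RuntimeError("no ICA run converged")
    return ICARuns(components=np.concatenate(comps),
                   weights=np.concatenate(weights),
                   run_index=np.asarray(run_idx),
                   n_runs_requested=config.n_runs,
                   n_runs_converged=n_converged,
                   n_pca_components=q)


@dataclass
class MergedComponents:
    components: np.ndarray         # (n_merged, n_cols)
    weights: np.ndarray            # (n_merged, n_patients)
    frequencies: np.ndarray        # distinct contributing runs / runs used
    n_members: np.ndarray
    # filled by select_duration_component
    duration_rho: np.ndarray | None = None
    duration_p: np.ndarray | None = None
    significant: np.ndarray | None = None
    selected: int | None = None


def merge_components(runs: ICARuns, r_threshold: float = 0.8) -> MergedComponents:
    """Merge near-duplicate components across runs.

    Components are grouped by connected components of the graph with an
    edge wherever |Pearson r| exceeds the threshold (sign-aligned before
    averaging, order-independent); component vectors and patient weights
    are averaged within a group. The pass repeats on the merged set until
    every pair sits below the threshold.
    """
    comps = runs.components.copy()
    weights = runs.weights.copy()
    members = [np.array([i]) for i in range(len(comps))]
    for _ in range(20):
        if len(comps) < 2:
            break
        R = np.corrcoef(comps)
        np.fill_diagonal(R, 0.0)
        adj = np.abs(R) > r_threshold
        if not adj.any():
            break
        n_groups, labels = connected_components(csr_matrix(adj), directed=False)
        new_c, new_w, new_m = [], [], []
        for g in range(n_groups):
            idx = np.flatnonzero(labels == g)
            ref = idx[0]
            signs = np.sign(R[ref, idx])
            signs[idx == ref] = 1.0
            signs[signs == 0] = 1.0
            new_c.append((comps[idx] * signs[:, None]).mean(axis=0))
            new_w.append((weights[idx] * signs[:, None]).mean(axis=0))
            new_m.append(np.concatenate([members[i] for i in idx]))
        comps = np.asarray(new_c)
        weights = np.asarray(new_w)
        members = new_m
    n_runs_used = max(runs.n_runs_converged, 1)
    freq = np.array([len(set(runs.run_index[m])) / n_runs_used
                     for m in members])
    return MergedComponents(components=comps, weights=weights,
                            frequencies=freq,
                            n_members=np.array([len(m) for m in members]))


def select_duration_component(merged: MergedComponents,
                              durations: np.ndarray,
                              alpha: float = 0.05,
                              correction: str = "bonferroni"
                              ) -> MergedComponents:
    """Spearman-correlate component weights with duration of disease.

    Components (and weights) are sign-flipped so that rho >= 0. Selection
    keeps components significant at ``alpha`` — Bonferroni-corrected
    across the merged set by default — and resolves ties by largest rho;
    an empty selection is reported, not an error.
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) < 5:
        raise ValueError("need at least 5 patients with durations")
    m = len(merged.components)
    rho = np.empty(m)
    pval = np.empty(m)
    for i in range(m):
        r = stats.spearmanr(merged.weights[i], durations)
        if r.statistic < 0:
            merged.components[i] *= -1.0
            merged.weights[i] *= -1.0
        rho[i] = abs(r.statistic)
        pval[i] = r.pvalue
    if correction == "bonferroni":
        threshold = alpha / m
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    significant = pval < threshold
    merged.duration_rho = rho
    merged.duration_p = pval
    merged.significant = significant
    if significant.any():
        cand = np.flatnonzero(significant)
        merged.selected = int(cand[np.argmax(rho[cand])])
    else:
        merged.selected = None
    return merged


@dataclass
class DegreeProjection:
    fc_degree: np.ndarray
    sc_degree: np.ndarray
    fc_density: float
    sc_density: float
    fc_threshold: float
    sc_threshold: float


def _threshold_degree(edge_values: np.ndarray, cols: np.ndarray,
                      emap: EdgeIndexMap, threshold: float,
                      mode: str, target_density: float,
                      degree_kind: str) -> tuple[np.ndarray, float, float]:
    v = edge_values.copy()
    active = np.abs(v[cols])
    if mode == "density":
        if target_density >= 1.0:
            threshold = 0.0
        else:
            threshold = float(np.quantile(active, 1.0 - target_density))
    v[np.abs(v) < threshold] = 0.0
    density = float((np.abs(v[cols]) > 0).mean()) if len(cols) else 0.0
    matrix = emap.to_matrix(v)
    if degree_kind == "abs":
        matrix = np.abs(matrix)
    return matrix.sum(axis=1), density, threshold


def degree_projection(component: np.ndarray, joint: JointMatrix,
                      config: ICAConfig) -> DegreeProjection:
    """Thresholded weighted degree ("net connectivity") per region.

    Edges below the FC/SC magnitude thresholds are zeroed; the degree of a
    region is the signed sum of its surviving incident edge values. In
    ``density`` mode the threshold is instead solved per block so that
    approximately ``target_density`` of the retained edges survive.
    """
    fc_edges, sc_edges = joint.split(component)
    fc_deg, fc_den, fc_t = _threshold_degree(
        fc_edges, joint.fc_cols, joint.emap, config.fc_threshold,
        config.degree_mode, config.target_density, config.degree_kind)
    sc_deg, sc_den, sc_t = _threshold_degree(
        sc_edges, joint.sc_cols, joint.emap, config.sc_threshold,
        config.degree_mode, config.target_density, config.degree_kind)
    return DegreeProjection(fc_degree=fc_deg, sc_degree=sc_deg,
                            fc_density=fc_den, sc_density=sc_den,
                            fc_threshold=fc_t, sc_threshold=sc_t)


@dataclass
class ModelCorrelation:
    kind: str
    r: float
    p: float
    n: int
    method: str
    significant: bool


def averaged_model_distances(model: TopologyModel) -> np.ndarray:
    """Left/right-averaged model distance from the anterior hippocampus.

    Returns one value per atlas region (NaN where undefined): each region
    of a homotopic pair receives the mean of the left- and right-
    hemisphere distances from the respective anterior hippocampus; for the
    RSN model the network label itself (NaN for unlabelled regions).
    """
    atlas = model.atlas
    n = atlas.n_regions
    out = np.full(n, np.nan)
    if model.kind == "RSN":
        labels = model.membership.astype(float)
        out = np.where(labels > 0, labels, np.nan)
        for side in ("left", "right"):
            out[atlas.anterior_hippocampus(side)] = np.nan
        return out
    dist = {}
    for side in ("left", "right"):
        seed = atlas.anterior_hippocampus(side)
        v = model_vector(model, seed, side=side)
        dist[side] = dict(zip(v.regions.tolist(), v.values))
    pairs = atlas.homotopic_pairs()
    seed_l = atlas.anterior_hippocampus("left")
    seed_r = atlas.anterior_hippocampus("right")
    for left_i, right_i in pairs:
        if left_i == seed_l or right_i == seed_r:
            continue
        vals = [dist["left"].get(int(left_i), np.nan),
                dist["right"].get(int(right_i), np.nan)]
        avg = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
        out[left_i] = out[right_i] = avg
    for b in atlas.indices("bilateral"):
        vals = [dist["left"].get(int(b), np.nan),
                dist["right"].get(int(b), np.nan)]
        out[b] = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
    return out


def correlate_with_models(degree: np.ndarray,
                          models: dict[str, TopologyModel],
                          alpha: float = 0.0125) -> dict[str, ModelCorrelation]:
    """Correlate a regional degree vector with each distance model.

    Pearson for the LEN/SC/FC models, Spearman for the ordinal RSN model;
    regions with undefined model distance are excluded pairwise. The
    significance threshold defaults to 0.0125 (Bonferroni over the
    four-model family). A constant degree vector yields r = NaN.
    """
    out = {}
    for kind, model in models.items():
        d = averaged_model_distances(model)
        ok = np.isfinite(d) & np.isfinite(degree)
        if ok.sum() < 5:
            raise ValueError(f"{kind}: fewer than 5 paired regions")
        x, y = degree[ok], d[ok]
        method = "spearman" if kind == "RSN" else "pearson"
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = float("nan"), float("nan")
        elif method == "spearman":
            res = stats.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        out[kind] = ModelCorrelation(kind=kind, r=r, p=p, n=int(ok.sum()),
                                     method=method,
                                     significant=bool(np.isfinite(p) and p < alpha))
    return out


@dataclass
class WholeBrainResult:
    joint: JointMatrix
    runs: ICARuns
    merged: MergedComponents
    degree: DegreeProjection | None
    model_correlations: dict[str, dict[str, ModelCorrelation]] | None


def analyze_wholebrain(cohort: Cohort, corrected: CorrectedCohort,
                       config: ICAConfig,
                       models: dict[str, TopologyModel] | None = None
                       ) -> WholeBrainResult:
    """Full whole-brain stage: joint matrix, repeated ICA, merge, select,
    degree projection and model correlations for the selected component."""
    joint = build_joint_matrix(cohort, corrected,
                               config.max_sc_missing_fraction)
    runs = run_hybrid_ica(joint, config)
    merged = merge_components(runs, config.merge_r_threshold)
    durations = np.array([s.duration for s in cohort.patients()])
    merged = select_duration_component(merged, durations,
                                       alpha=config.selection_alpha,
                                       correction=config.selection_correction)
    degree = None
    correlations = None
    if merged.selected is not None:
        degree = degree_projection(merged.components[merged.selected],
                                   joint, config)
        if models:
            correlations = {
                "FC": correlate_with_models(degree.fc_degree, models),
                "SC": correlate_with_models(degree.sc_degree, models),
            }
    return WholeBrainResult(joint=joint, runs=runs, merged=merged,
                            degree=degree, model_correlations=correlations)
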