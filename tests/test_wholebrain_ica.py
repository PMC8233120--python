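"""Hybrid FC/SC connectome ICA, merging, selection and degree projection."""

import warnings

import numpy as np
import pytest
from scipy import stats

from netprog import (ICAConfig, SimulationConfig, build_joint_matrix,
                     correlate_with_models, degree_projection,
                     merge_components, normalize_cohort, run_hybrid_ica,
                     select_duration_component, simulate_cohort,
                     build_topology)
from netprog.ica import ICARuns, JointMatrix, MergedComponents
from netprog.core import edge_index_map


@pytest.fixture(scope="module")
def complete_cohort():
    """Default-size cohort with no undetected SC edges."""
    cfg = SimulationConfig(effect_profile=(0.0,) * 5, seed=77,
                           missing_fraction_cross_hemisphere=0.0,
                           missing_fraction_within_hemisphere=0.0)
    cohort, _ = simulate_cohort(cfg)
    return cohort, normalize_cohort(cohort)


class TestJointMatrix:
    def test_full_data_column_count(self, complete_cohort):
        cohort, corrected = complete_cohort
        joint = build_joint_matrix(cohort, corrected)
        assert joint.X.shape == (40, 2 * 5886)
        assert len(joint.sc_cols) == 5886    # nothing dropped

    def test_unreliable_sc_columns_dropped(self, null_cohort, null_corrected):
        cohort, _ = null_cohort
        joint = build_joint_matrix(cohort, null_corrected,
                                   max_sc_missing_fraction=0.10)
        assert joint.n_fc == 5886
        assert 0 < len(joint.sc_cols) < 5886
        # remaining missing entries imputed at the age-expected level (0)
        assert np.isfinite(joint.X).all()

    def test_split_round_trip(self, complete_cohort):
        cohort, corrected = complete_cohort
        joint = build_joint_matrix(cohort, corrected)
        v = np.arange(joint.X.shape[1], dtype=float)
        fc, sc = joint.split(v)
        assert np.array_equal(fc[joint.fc_cols], v[:joint.n_fc])
        assert np.array_equal(sc[joint.sc_cols], v[joint.n_fc:])


def _rank2_joint(n_pat=24, n_edges=600, seed=0):
    rng = np.random.default_rng(seed)
    s1 = rng.uniform(-1, 1, n_edges) ** 3
    s2 = rng.laplace(size=n_edges)
    S = np.vstack([s1 / s1.std(), s2 / s2.std()])
    W, _ = np.linalg.qr(rng.normal(size=(n_pat, 2)))  # balanced mixing
    X = W @ S + 1e-6 * rng.normal(size=(n_pat, n_edges))
    emap = edge_index_map(int((1 + np.sqrt(1 + 8 * n_edges)) / 2) + 1)
    return JointMatrix(X=X, patient_ids=[f"p{i}" for i in range(n_pat)],
                       emap=emap, fc_cols=np.arange(n_edges),
                       sc_cols=np.array([], dtype=int)), (s1, s2)


class TestHybridICA:
    def test_rank2_sources_recovered(self):
        joint, (s1, s2) = _rank2_joint()
        runs = run_hybrid_ica(joint, ICAConfig(n_runs=3, seed=0))
        assert runs.n_pca_components == 2
        for src in (s1, s2):
            best = max(abs(np.corrcoef(src, c)[0, 1])
                       for c in runs.components[:2])
            assert best > 0.99

    def test_full_variance_retains_max_components(self):
        from netprog.ica import pca_component_count
        rng = np.random.default_rng(1)
        joint, _ = _rank2_joint()
        X = joint.X + rng.normal(size=joint.X.shape)   # full rank
        assert pca_component_count(X, 1.0) == X.shape[0] - 1

    def test_same_seed_is_deterministic(self):
        joint, _ = _rank2_joint(seed=2)
        a = run_hybrid_ica(joint, ICAConfig(n_runs=2, seed=9))
        b = run_hybrid_ica(joint, ICAConfig(n_runs=2, seed=9))
        assert np.array_equal(a.components, b.components)
        assert np.array_equal(a.weights, b.weights)


class TestMerging:
    def _runs(self, comps, weights, run_index, n_runs):
        return ICARuns(components=np.asarray(comps, dtype=float),
                       weights=np.asarray(weights, dtype=float),
                       run_index=np.asarray(run_index),
                       n_runs_requested=n_runs, n_runs_converged=n_runs,
                       n_pca_components=len(comps))

    def test_identical_components_merge(self):
        rng = np.random.default_rng(0)
        c = rng.normal(size=50)
        w = rng.normal(size=4)
        runs = self._runs([c, c], [w, w], [0, 1], n_runs=4)
        merged = merge_components(runs, 0.8)
        assert len(merged.components) == 1
        assert merged.frequencies[0] == pytest.approx(2 / 4)
        assert np.allclose(merged.components[0], c)

    def test_negated_component_merges_after_sign_alignment(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=50)
        w = rng.normal(size=4)
        runs = self._runs([c, -c], [w, -w], [0, 1], n_runs=2)
        merged = merge_components(runs, 0.8)
        assert len(merged.components) == 1
        assert np.allclose(np.abs(merged.components[0]), np.abs(c))

    def test_merged_set_pairwise_below_threshold(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(3, 80))
        comps = np.vstack([base + 0.05 * rng.normal(size=(3, 80))
                           for _ in range(4)])
        weights = rng.normal(size=(12, 5))
        runs = self._runs(comps, weights, np.repeat(np.arange(4), 3), 4)
        merged = merge_components(runs, 0.8)
        R = np.corrcoef(merged.components)
        np.fill_diagonal(R, 0.0)
        assert np.abs(R).max() <= 0.8


class TestSelection:
    def _merged(self, weights):
        w = np.asarray(weights, dtype=float)
        comps = np.tile(np.arange(30.0), (len(w), 1))
        return MergedComponents(components=comps.copy(), weights=w.copy(),
                                frequencies=np.ones(len(w)),
                                n_members=np.ones(len(w), dtype=int))

    def test_weights_equal_to_duration_ranks_give_rho_one(self):
        durations = np.array([3.0, 11.0, 7.0, 25.0, 40.0, 18.0])
        merged = self._merged([stats.rankdata(durations)])
        merged = select_duration_component(merged, durations)
        assert merged.duration_rho[0] == pytest.approx(1.0)
        assert merged.selected == 0

    def test_sign_flipped_to_non_negative_rho(self):
        durations = np.array([3.0, 11.0, 7.0, 25.0, 40.0, 18.0])
        merged = self._merged([-stats.rankdata(durations)])
        merged = select_duration_component(merged, durations)
        assert merged.duration_rho[0] == pytest.approx(1.0)
        assert merged.weights[0][np.argmax(durations)] == max(merged.weights[0])

    def test_unrelated_weights_select_nothing(self):
        rng = np.random.default_rng(3)
        durations = rng.uniform(2, 45, 20)
        merged = self._merged(rng.normal(size=(5, 20)))
        merged = select_duration_component(merged, durations)
        assert merged.selected is None


class TestDegreeProjection:
    def _joint(self, n=3):
        emap = edge_index_map(n)
        return JointMatrix(X=np.zeros((2, 2 * len(emap))), patient_ids=["a", "b"],
                           emap=emap, fc_cols=np.arange(len(emap)),
                           sc_cols=np.arange(len(emap)))

    def test_hand_computed_example(self):
        joint = self._joint()
        comp = np.array([0.6, -0.6, 0.1] * 2)   # edges (0,1),(0,2),(1,2)
        cfg = ICAConfig(fc_threshold=0.55, sc_threshold=0.55)
        deg = degree_projection(comp, joint, cfg)
        assert np.allclose(deg.fc_degree, [0.0, 0.6, -0.6])
        assert deg.fc_density == pytest.approx(2 / 3)

    def test_zero_threshold_is_plain_weighted_degree(self):
        joint = self._joint()
        comp = np.array([0.6, -0.6, 0.1] * 2)
        cfg = ICAConfig(fc_threshold=0.0, sc_threshold=0.0)
        deg = degree_projection(comp, joint, cfg)
        assert np.allclose(deg.fc_degree, [0.0, 0.7, -0.5])

    def test_threshold_above_max_zeroes_everything(self):
        joint = self._joint()
        comp = np.array([0.6, -0.6, 0.1] * 2)
        cfg = ICAConfig(fc_threshold=5.0, sc_threshold=5.0)
        deg = degree_projection(comp, joint, cfg)
        assert np.allclose(deg.fc_degree, 0.0)
        assert deg.fc_density == 0.0

    def test_density_mode_hits_target(self):
        rng = np.random.default_rng(0)
        joint = self._joint(n=30)
        comp = rng.normal(size=2 * len(joint.emap))
        cfg = ICAConfig(degree_mode="density", target_density=0.2)
        deg = degree_projection(comp, joint, cfg)
        assert deg.fc_density == pytest.approx(0.2, abs=0.01)

    def test_density_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        joint = self._joint(n=20)
        comp = rng.normal(size=2 * len(joint.emap))
        dens = []
        for t in (0.0, 0.5, 1.0, 2.0):
            cfg = ICAConfig(fc_threshold=t, sc_threshold=t)
            dens.append(degree_projection(comp, joint, cfg).fc_density)
        assert all(a >= b for a, b in zip(dens, dens[1:]))


class TestModelCorrelations:
    def test_degree_proportional_to_model_gives_r_one(self, null_cohort):
        cohort, _ = null_cohort
        model = build_topology(cohort, "LEN")
        from netprog.ica import averaged_model_distances
        d = averaged_model_distances(model)
        degree = np.where(np.isfinite(d), 2.0 * d, 0.0)
        res = correlate_with_models(degree, {"LEN": model})
        assert res["LEN"].r == pytest.approx(1.0)
        assert res["LEN"].significant

    def test_zero_degree_reported_as_undefined(self, null_cohort):
        cohort, _ = null_cohort
        model = build_topology(cohort, "LEN")
        res = correlate_with_models(np.zeros(109), {"LEN": model})
        assert not np.isfinite(res["LEN"].r)
        assert not res["LEN"].significant
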