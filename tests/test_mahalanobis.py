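"""The multivariate deviation statistic and its subsampling scheme."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.covariance import ledoit_wolf

from netprog import (Connectome, MahalanobisConfig, bin_mahalanobis,
                     ledoit_wolf_covariance_batch, mahalanobis)
from netprog.topology import EdgeBinning


def test_patient_at_control_mean_is_zero():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 5))
    assert mahalanobis(X.mean(0), X) == pytest.approx(0.0, abs=1e-20)


def test_identity_covariance_unit_offset():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(30, 4))
    s = X.mean(0) + np.array([1.0, 0, 0, 0])
    assert mahalanobis(s, X, covariance=np.eye(4)) == pytest.approx(1.0)


def test_two_by_two_closed_form():
    C = np.array([[1.0, 0.74], [0.74, 1.0]])
    M = mahalanobis(np.array([2.0, -1.0]), np.zeros((10, 2)), covariance=C)
    expected = (4 + 2 * 0.74 * 2 + 1) / (1 - 0.74 ** 2)
    assert M == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_matches_brute_force_inverse(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 8))
    X = rng.normal(size=(50, k)) @ rng.normal(size=(k, k))
    s = rng.normal(size=k)
    C, _ = ledoit_wolf(X)
    mu = X.mean(0)
    brute = (s - mu) @ np.linalg.inv(C) @ (s - mu)
    assert mahalanobis(s, X) == pytest.approx(brute, abs=1e-10)


def test_batched_shrinkage_matches_sklearn():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(25, 50, 7)) * rng.uniform(0.5, 3.0, size=7)
    cov_b, mean_b, shr_b = ledoit_wolf_covariance_batch(X)
    for i in range(len(X)):
        cov_sk, shr_sk = ledoit_wolf(X[i])
        assert np.allclose(cov_b[i], cov_sk, atol=1e-12)
        assert shr_b[i] == pytest.approx(shr_sk, abs=1e-12)


def test_shrunk_covariance_positive_definite_at_study_size():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 50, 7))
    cov, _, _ = ledoit_wolf_covariance_batch(X)
    assert np.linalg.eigvalsh(cov).min() > 0


def test_invariance_to_edge_permutation_and_constant_shift():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 6))
    s = rng.normal(size=6)
    m0 = mahalanobis(s, X)
    perm = rng.permutation(6)
    assert mahalanobis(s[perm], X[:, perm]) == pytest.approx(m0, rel=1e-12)
    shift = np.zeros(6)
    shift[2] = 17.0
    assert mahalanobis(s + shift, X + shift) == pytest.approx(m0, rel=1e-9)


def test_identity_covariance_equals_euclidean():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 3))
    s = rng.normal(size=3)
    d = s - X.mean(0)
    assert mahalanobis(s, X, covariance=np.eye(3)) == pytest.approx(d @ d)
    assert mahalanobis(s, X, covariance=np.eye(3),
                       squared=False) == pytest.approx(np.sqrt(d @ d))


def _toy_bin_setup(rng, n_ctrl=20, n_regions=12, k_bin=8):
    """Controls + binning over one seed's edges, no missing data."""
    def sym(m):
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        return m
    controls = [Connectome(f"c{i}", "FC",
                           sym(rng.normal(size=(n_regions, n_regions))))
                for i in range(n_ctrl)]
    binning = EdgeBinning("LEN", seed=0,
                          bins=[np.arange(1, 1 + k_bin // 2),
                                np.arange(1 + k_bin // 2, 1 + k_bin)],
                          rule="test")
    return controls, binning


class TestBinMahalanobis:
    def test_patient_at_control_means_gives_zero_everywhere(self):
        """s = mu makes every quadratic form vanish, whatever edge subset
        is drawn (control draws cover the full set so mu is exact)."""
        rng = np.random.default_rng(6)
        controls, binning = _toy_bin_setup(rng)
        mean = np.mean([c.matrix for c in controls], axis=0)
        patient = Connectome("p", "FC", mean)
        for seed in (0, 99):
            cfg = MahalanobisConfig(k_subset=3, n_edge_permutations=20,
                                    n_control_permutations=20,
                                    n_controls_drawn=len(controls),
                                    min_controls_complete=len(controls),
                                    seed=seed)
            prof = bin_mahalanobis(patient, controls, binning, cfg)
            assert np.allclose(prof.M, 0.0, atol=1e-18)

    def test_full_retention_without_missing_edges(self):
        rng = np.random.default_rng(7)
        controls, binning = _toy_bin_setup(rng)
        patient = Connectome("p", "FC", controls[0].matrix.copy())
        cfg = MahalanobisConfig(k_subset=3, n_edge_permutations=50,
                                n_control_permutations=50,
                                n_controls_drawn=15, min_controls_complete=12)
        prof = bin_mahalanobis(patient, controls, binning, cfg)
        for b in prof.bins:
            assert b.retained_pairs == 2500
            assert b.retained_outer == 50
            assert b.discarded_outer_patient_missing == 0
            assert b.discarded_inner_incomplete == 0

    def test_patient_missing_edges_discard_outer_draws(self):
        rng = np.random.default_rng(8)
        controls, binning = _toy_bin_setup(rng)
        m = controls[0].matrix.copy()
        miss = np.zeros_like(m, dtype=bool)
        miss[0, 1] = miss[1, 0] = True     # first edge of bin 1 missing
        patient = Connectome("p", "FC", m, miss)
        cfg = MahalanobisConfig(k_subset=3, n_edge_permutations=80,
                                n_control_permutations=10,
                                n_controls_drawn=15, min_controls_complete=12)
        prof = bin_mahalanobis(patient, controls, binning, cfg)
        assert prof.bins[0].discarded_outer_patient_missing > 0
        assert prof.bins[1].discarded_outer_patient_missing == 0

    def test_monte_carlo_error_shrinks_with_more_permutations(self):
        rng = np.random.default_rng(9)
        controls, binning = _toy_bin_setup(rng)
        patient = Connectome("p", "FC",
                             controls[0].matrix * 0.5 + controls[1].matrix)
        def spread(n_perm):
            vals = []
            for seed in range(8):
                cfg = MahalanobisConfig(k_subset=3, n_edge_permutations=n_perm,
                                        n_control_permutations=n_perm,
                                        n_controls_drawn=15,
                                        min_controls_complete=12, seed=seed)
                vals.append(bin_mahalanobis(patient, controls, binning,
                                            cfg).M[0])
            return np.std(vals)
        assert spread(40) < spread(8)

    def test_rng_streams_reproducible(self):
        rng = np.random.default_rng(10)
        controls, binning = _toy_bin_setup(rng)
        patient = Connectome("p", "FC", controls[0].matrix + 0.3)
        cfg = MahalanobisConfig(k_subset=3, n_edge_permutations=30,
                                n_control_permutations=30,
                                n_controls_drawn=15, min_controls_complete=12,
                                seed=5)
        a = bin_mahalanobis(patient, controls, binning, cfg)
        b = bin_mahalanobis(patient, controls, binning, cfg)
        assert np.array_equal(a.M, b.M)
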