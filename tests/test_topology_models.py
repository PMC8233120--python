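"""Healthy-brain topologies, model vectors and edge binning."""

import numpy as np
import pytest

from netprog import (Connectome, SubjectRecord, bin_edges, build_topology,
                     contiguous_bin_sizes, model_vector)
from netprog.core import Cohort
from netprog.topology import ModelVector, TopologyModel


def _toy_cohort(toy_atlas, values):
    subjects, connectomes = [], {}
    for i, val in enumerate(values):
        sid = f"c{i}"
        subjects.append(SubjectRecord(sid, "control", 30.0 + i))
        m = np.zeros((5, 5))
        m[0, 1] = m[1, 0] = val
        m[0, 4] = m[4, 0] = 2 * val
        connectomes[(sid, "FC")] = Connectome(sid, "FC", m)
        connectomes[(sid, "SC")] = Connectome(sid, "SC", np.abs(m))
    return Cohort(toy_atlas, subjects, connectomes)


def test_topology_is_control_mean(toy_atlas):
    cohort = _toy_cohort(toy_atlas, [0.2, 0.4])
    T = build_topology(cohort, "FC")
    # left block is (hip_ant_L, cortex_L, brainstem); edge 0-1 averaged
    assert T.matrices["left"][0, 1] == pytest.approx(0.3)


def test_sc_edge_absent_in_every_control_is_absent_in_topology(toy_atlas):
    cohort = _toy_cohort(toy_atlas, [0.2, 0.4])
    T = build_topology(cohort, "SC")
    # cortex_L-brainstem never detected
    assert np.isnan(T.matrices["left"][1, 2])


def test_topology_tracks_latent_length(small_cohort):
    cohort, truth = small_cohort
    T = build_topology(cohort, "LEN")
    block = T.regions["left"]
    latent = truth.latent_len[np.ix_(block, block)]
    iu = np.triu_indices(len(block), 1)
    est, ref = T.matrices["left"][iu], latent[iu]
    ok = np.isfinite(est)
    r = np.corrcoef(est[ok], ref[ok])[0, 1]
    assert r > 0.9


def test_left_right_topologies_agree_on_symmetric_generator(small_cohort):
    cohort, _ = small_cohort
    T = build_topology(cohort, "LEN")
    iu = np.triu_indices(55, 1)
    a, b = T.matrices["left"][iu], T.matrices["right"][iu]
    ok = np.isfinite(a) & np.isfinite(b)
    assert np.corrcoef(a[ok], b[ok])[0, 1] > 0.9


def test_model_vector_reads_seed_row():
    n = 6
    mat = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    T = TopologyModel(kind="LEN", atlas=None, matrices={"left": mat},
                      regions={"left": np.arange(n)})
    v = model_vector(T, 2, side="left")
    assert np.array_equal(v.values, [2, 1, 1, 2, 3])
    assert np.array_equal(v.regions, [0, 1, 3, 4, 5])


def test_rsn_model_vector_independent_of_seed(null_cohort):
    cohort, _ = null_cohort
    T = build_topology(cohort, "RSN")
    v1 = model_vector(T, 0)
    v2 = model_vector(T, 5)
    common = np.intersect1d(v1.regions, v2.regions)
    lut1 = dict(zip(v1.regions, v1.values))
    lut2 = dict(zip(v2.regions, v2.values))
    assert all(lut1[r] == lut2[r] for r in common)


def test_seed_nearest_neighbour_matches_generator(small_cohort):
    cohort, truth = small_cohort
    T = build_topology(cohort, "LEN")
    seed = truth.seed_region["left"]
    v = model_vector(T, seed, side="left")
    nearest = v.regions[np.nanargmin(v.values)]
    latent = truth.latent_len[seed].copy()
    latent[seed] = np.inf
    block = set(cohort.atlas.hemisphere_block("left").tolist())
    latent[[r for r in range(len(latent)) if r not in block]] = np.inf
    assert nearest == np.argmin(latent)


class TestBinning:
    def test_chunk_sizes(self):
        assert contiguous_bin_sizes(54, 5) == [11, 11, 11, 11, 10]
        assert contiguous_bin_sizes(54, 4) == [14, 14, 13, 13]
        with pytest.raises(ValueError):
            contiguous_bin_sizes(3, 5)

    def test_fc_ranks_by_absolute_value(self):
        v = ModelVector("FC", seed=9, regions=np.array([0, 1, 2, 3]),
                        values=np.array([-0.9, 0.5, -0.1, 0.05]))
        binning = bin_edges(v, 2)
        assert set(binning.bins[0]) == {0, 1}
        assert set(binning.bins[1]) == {2, 3}

    def test_rsn_bins_have_ten_bilateral_edges(self, null_cohort):
        cohort, _ = null_cohort
        T = build_topology(cohort, "RSN")
        seed = cohort.atlas.anterior_hippocampus("left")
        binning = bin_edges(model_vector(T, seed), 4)
        assert [len(b) for b in binning.bins] == [10, 10, 10, 10]

    def test_binning_partitions_eligible_edges(self, small_cohort):
        cohort, _ = small_cohort
        for kind, n_bins in (("LEN", 5), ("SC", 4), ("FC", 5)):
            T = build_topology(cohort, kind)
            seed = cohort.atlas.anterior_hippocampus("left")
            v = model_vector(T, seed, side="left")
            binning = bin_edges(v, n_bins)
            all_regions = np.concatenate(binning.bins)
            assert len(all_regions) == len(set(all_regions.tolist()))
            eligible = v.regions[np.isfinite(v.values)]
            assert set(all_regions.tolist()) == set(eligible.tolist())
            sizes = [len(b) for b in binning.bins]
            assert max(sizes) - min(sizes) <= 1

    def test_ranks_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1.0, 50.0, 20)
        v1 = ModelVector("LEN", 99, np.arange(20), vals)
        v2 = ModelVector("LEN", 99, np.arange(20), np.log(vals))
        b1, b2 = bin_edges(v1, 4), bin_edges(v2, 4)
        for x, y in zip(b1.bins, b2.bins):
            assert np.array_equal(x, y)

    def test_too_many_bins_rejected(self):
        v = ModelVector("LEN", 0, np.arange(3), np.arange(3.0))
        with pytest.raises(ValueError):
            bin_edges(v, 5)
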