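"""Generator determinism, null exchangeability and planted structure."""

import numpy as np
import pytest
from scipy import stats

from netprog import (SimulationConfig, normalize_cohort, plant_ica_component,
                     simulate_cohort)


def test_same_seed_bitwise_identical():
    cfg = SimulationConfig(n_controls=6, n_patients=4, n_right_focus=2, seed=7)
    a, _ = simulate_cohort(cfg)
    b, _ = simulate_cohort(cfg)
    for key, c in a.connectomes.items():
        assert np.array_equal(c.matrix, b.connectomes[key].matrix)
    assert [s.age for s in a.subjects] == [s.age for s in b.subjects]


def test_null_patients_exchangeable_with_controls():
    """With a zero effect profile, pooled patient and control FC edges are
    indistinguishable (median KS p over 20 seeds)."""
    pvals = []
    for seed in range(20):
        cfg = SimulationConfig(effect_profile=(0.0,) * 5, seed=seed)
        cohort, _ = simulate_cohort(cfg)
        iu = np.triu_indices(cohort.atlas.n_regions, 1)
        ctrl = np.concatenate([cohort.get(s.subject_id, "FC").matrix[iu]
                               for s in cohort.controls()[:10]])
        pat = np.concatenate([cohort.get(s.subject_id, "FC").matrix[iu]
                              for s in cohort.patients()[:10]])
        pvals.append(stats.ks_2samp(ctrl, pat).pvalue)
    assert np.median(pvals) > 0.01


def test_planted_gradient_decreases_across_bins():
    cfg = SimulationConfig(seed=5, fixed_duration=30.0)
    cohort, truth = simulate_cohort(cfg)
    corrected = normalize_cohort(cohort, modalities=("FC",))
    means = []
    for b in range(5):
        vals = []
        for p in cohort.patients():
            seed_r = truth.seed_region[p.focus_side]
            regs = truth.planted_bins[p.focus_side][b]
            corr = corrected.corr[(p.subject_id, "FC")]
            vals.append(np.abs(corr.matrix[seed_r, regs]).mean())
        means.append(np.mean(vals))
    assert np.all(np.diff(means) < 0)


def test_planted_effect_sizes_recovered_within_15_percent():
    """(patient mean - control mean) / control SD at duration 30 matches
    the configured per-bin effect magnitudes."""
    cfg = SimulationConfig(n_controls=150, n_patients=150, n_right_focus=150,
                           fixed_duration=30.0, seed=9)
    cohort, truth = simulate_cohort(cfg)
    seed_r = truth.seed_region["right"]
    ctrl = np.stack([cohort.get(s.subject_id, "FC").matrix[seed_r]
                     for s in cohort.controls()])
    pat = np.stack([cohort.get(s.subject_id, "FC").matrix[seed_r]
                    for s in cohort.patients()])
    est = (pat.mean(0) - ctrl.mean(0)) / ctrl.std(0)
    for b, expected in enumerate(cfg.effect_profile):
        if expected == 0:
            continue
        got = np.abs(est[truth.planted_bins["right"][b]]).mean()
        assert got == pytest.approx(expected, rel=0.15)


def test_latent_length_is_nearly_metric():
    cfg = SimulationConfig(n_controls=4, n_patients=2, n_right_focus=1, seed=3)
    _, truth = simulate_cohort(cfg)
    L = truth.latent_len
    rng = np.random.default_rng(0)
    n = L.shape[0]
    viol = 0
    trials = 3000
    for _ in range(trials):
        i, j, k = rng.choice(n, 3, replace=False)
        viol += L[i, j] > L[i, k] + L[k, j] + 1e-9
    assert viol / trials < 0.01


class TestPlantedICAComponent:
    @pytest.fixture(scope="class")
    def patient_cohort(self):
        cfg = SimulationConfig(n_controls=2, n_patients=40, n_right_focus=29,
                               effect_profile=(0.0,) * 5, seed=21)
        return simulate_cohort(cfg)

    def test_amplitude_zero_is_noop(self, patient_cohort):
        cohort, _ = patient_cohort
        out, _ = plant_ica_component(cohort, amplitude=0.0, seed=1)
        for p in cohort.patients():
            assert np.array_equal(out.get(p.subject_id, "FC").matrix,
                                  cohort.get(p.subject_id, "FC").matrix)

    def test_negative_amplitude_rejected(self, patient_cohort):
        cohort, _ = patient_cohort
        with pytest.raises(ValueError):
            plant_ica_component(cohort, amplitude=-1.0, seed=1)

    def test_rho_one_is_exact(self, patient_cohort):
        cohort, _ = patient_cohort
        _, truth = plant_ica_component(cohort, loading_vs_duration_rho=1.0,
                                       amplitude=1.0, seed=2)
        durations = [p.duration for p in cohort.patients()]
        rho = stats.spearmanr(truth.ica_loading, durations).statistic
        assert rho == pytest.approx(1.0)

    def test_target_rho_realized_within_tenth(self, patient_cohort):
        cohort, _ = patient_cohort
        realized = []
        for seed in range(20):
            _, truth = plant_ica_component(cohort, loading_vs_duration_rho=0.6,
                                           amplitude=1.0, seed=seed)
            realized.append(truth.ica_realized_rho)
        assert abs(np.median(realized) - 0.6) < 0.1
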