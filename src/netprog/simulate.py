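"""Synthetic connectome cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes in a
resting-state fMRI + diffusion MRI cohort, without simulating any imaging:

* a mirrored 3-D geometry gives a latent streamline-length (LEN) structure;
* control functional connectivity (Fisher-z) decays exponentially with LEN;
* control structural connectivity is log-normal with a log-mean linear in
  LEN; undetected edges (mostly cross-hemisphere) are exactly zero/missing;
* every edge carries an independent linear age trend;
* patients follow the control generative model plus a focal alteration:
  edges between the ipsilateral anterior hippocampus and other same-
  hemisphere regions are shifted by a per-bin magnitude (in control-SD
  units) that grows with duration of disease, where the bins rank those
  edges by the latent LEN distance from the seed.

Ages are sampled identically for controls and patients, and durations are
resampled to respect duration < age, so that with an all-zero effect
profile patients and controls are exchangeable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .core import (Cohort, Connectome, RegionAtlas, SubjectRecord,
                   ipsi_contra_permutation, make_default_atlas)
from .topology import contiguous_bin_sizes

REFERENCE_DURATION = 30.0  # years; effect_profile is stated at this duration


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters.

    Defaults reproduce the study conditions the analysis is designed for:
    70 controls and 40 unilateral patients (29 right-sided foci), ages
    18-71, duration of disease ~ Normal(21, 15) truncated to [2, 50] years.
    """

    n_controls: int = 70
    n_patients: int = 40
    n_right_focus: int = 29
    age_range: tuple[float, float] = (18.0, 71.0)
    duration_mean: float = 21.0
    duration_sd: float = 15.0
    duration_range: tuple[float, float] = (2.0, 50.0)
    fixed_duration: float | None = None   # set to pin all patients to one duration

    # control generative model
    fc_base_amplitude: float = 0.7        # Fisher-z at zero distance
    fc_decay_length: float = 60.0         # mm, exponential FC-vs-LEN decay
    fc_noise_sd: float = 0.2              # Fisher-z units, between-subject
    sc_log_intercept: float = 3.0         # log volume-scaled streamline count
    sc_log_slope: float = -0.04           # per mm of LEN
    sc_dispersion: float = 0.5            # log-scale between-subject SD
    age_slope_sd: float = 0.004           # FC z-units per year, per-edge scale
    sc_age_slope_sd: float = 0.008        # log-SC units per year
    len_jitter_sd: float = 0.03           # relative per-subject LEN jitter
    tortuosity: float = 1.2               # streamline length vs Euclidean

    # missingness (undetected SC/LEN edges)
    missing_fraction_cross_hemisphere: float = 0.30
    missing_fraction_within_hemisphere: float = 0.02

    # planted focal effect
    effect_profile: tuple[float, ...] = (3.0, 2.25, 1.5, 0.75, 0.0)
    effect_duration_exponent: float = 1.0
    effect_direction: float = -1.0        # sign of the alteration
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_controls, self.n_patients) <= 0:
            raise ValueError("cohort counts must be positive")
        if not 0 <= self.n_right_focus <= self.n_patients:
            raise ValueError("n_right_focus out of range")
        if any(e < 0 for e in self.effect_profile):
            raise ValueError("effect_profile must be non-negative")
        for p in (self.missing_fraction_cross_hemisphere,
                  self.missing_fraction_within_hemisphere):
            if not 0.0 <= p <= 1.0:
                raise ValueError("missing fractions must be probabilities")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("age_range", "duration_range", "effect_profile"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    coords: np.ndarray                    # (N, 3) region coordinates, mm
    latent_len: np.ndarray                # (N, N) noise-free streamline length
    fc_age_slopes: np.ndarray             # (N, N) z-units / year
    sc_age_slopes: np.ndarray             # (N, N) log-units / year
    effect_fc_sd: np.ndarray              # (N, N) planted FC effect size in
                                          # control-SD units at 30 y duration
    effect_sc_sd: np.ndarray              # same for log-SC
    seed_region: dict[str, int]           # side -> anterior hippocampus index
    planted_bins: dict[str, list[np.ndarray]]  # side -> bin -> region indices
    ica_pattern_fc: np.ndarray | None = None   # (N, N), ipsi/contra frame
    ica_pattern_sc: np.ndarray | None = None
    ica_loading: np.ndarray | None = None      # per patient, standardised
    ica_realized_rho: float | None = None


def _sym_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    m = np.zeros((n, n))
    m[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return m + m.T


def _region_coordinates(rng: np.random.Generator,
                        atlas: RegionAtlas) -> np.ndarray:
    """Mirror-symmetric 3-D coordinates (x flips sign across the midline)."""
    coords = np.zeros((atlas.n_regions, 3))
    pairs = atlas.homotopic_pairs()
    base = np.column_stack([
        rng.uniform(12.0, 65.0, size=len(pairs)),    # |x|, lateral offset
        rng.uniform(-95.0, 65.0, size=len(pairs)),   # y
        rng.uniform(-45.0, 70.0, size=len(pairs)),   # z
    ])
    coords[pairs[:, 0]] = base * np.array([-1.0, 1.0, 1.0])
    coords[pairs[:, 1]] = base
    for b in atlas.indices("bilateral"):
        coords[b] = np.array([0.0, -35.0 + 5.0 * rng.standard_normal(),
                              -40.0 + 5.0 * rng.standard_normal()])
    return coords


def _cross_hemisphere_mask(atlas: RegionAtlas) -> np.ndarray:
    hemi = atlas.table["hemisphere"].to_numpy()
    left = hemi == "left"
    right = hemi == "right"
    cross = np.logical_or(np.outer(left, right), np.outer(right, left))
    return cross


def _sample_durations(rng, cfg: SimulationConfig, ages: np.ndarray) -> np.ndarray:
    if cfg.fixed_duration is not None:
        return np.full(len(ages), float(cfg.fixed_duration))
    lo, hi = cfg.duration_range
    a = (lo - cfg.duration_mean) / cfg.duration_sd
    b = (hi - cfg.duration_mean) / cfg.duration_sd
    out = np.empty(len(ages))
    for i, age in enumerate(ages):
        # rejection keeps the age marginal identical to controls'
        for _ in range(1000):
            d = stats.truncnorm.rvs(a, b, loc=cfg.duration_mean,
                                    scale=cfg.duration_sd, random_state=rng)
            if d <= age - 1.0:
                out[i] = d
                break
        else:
            out[i] = max(lo, age - 1.0)
    return out


def _planted_bins(latent_len: np.ndarray, atlas: RegionAtlas, side: str,
                  n_bins: int) -> tuple[int, list[np.ndarray]]:
    """Rank seed edges by latent LEN, chunk into near-equal contiguous bins."""
    seed = atlas.anterior_hippocampus(side)
    block = atlas.hemisphere_block(side)
    others = block[block != seed]
    order = others[np.argsort(latent_len[seed, others], kind="stable")]
    sizes = contiguous_bin_sizes(len(order), n_bins)
    bins, start = [], 0
    for s in sizes:
        bins.append(order[start:start + s])
        start += s
    return seed, bins


def simulate_cohort(config: SimulationConfig,
                    atlas: RegionAtlas | None = None
                    ) -> tuple[Cohort, GroundTruth]:
    """Generate a control + patient cohort with planted ground truth.

    Fully deterministic given ``config.seed``.
    """
    atlas = atlas or make_default_atlas()
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))
    n = atlas.n_regions

    coords = _region_coordinates(rng, atlas)
    diff = coords[:, None, :] - coords[None, :, :]
    latent_len = cfg.tortuosity * np.sqrt((diff ** 2).sum(-1))
    np.fill_diagonal(latent_len, 0.0)

    fc_mean = cfg.fc_base_amplitude * np.exp(-latent_len / cfg.fc_decay_length)
    np.fill_diagonal(fc_mean, 0.0)
    sc_log_mean = cfg.sc_log_intercept + cfg.sc_log_slope * latent_len
    fc_slopes = _sym_noise(rng, n, cfg.age_slope_sd)
    sc_slopes = _sym_noise(rng, n, cfg.sc_age_slope_sd)
    age_ref = 0.5 * (cfg.age_range[0] + cfg.age_range[1])

    cross = _cross_hemisphere_mask(atlas)
    iu = np.triu_indices(n, k=1)
    miss_prob = np.where(cross, cfg.missing_fraction_cross_hemisphere,
                         cfg.missing_fraction_within_hemisphere)

    n_bins = len(cfg.effect_profile)
    seed_region, planted = {}, {}
    effect_bin_sd = {}
    for side in ("left", "right"):
        seed_idx, bins = _planted_bins(latent_len, atlas, side, n_bins)
        seed_region[side] = seed_idx
        planted[side] = bins
        m = np.zeros((n, n))
        for b, regions in enumerate(bins):
            m[seed_idx, regions] = cfg.effect_profile[b]
            m[regions, seed_idx] = cfg.effect_profile[b]
        effect_bin_sd[side] = m
    effect_fc_sd = np.maximum(effect_bin_sd["left"], effect_bin_sd["right"])
    effect_sc_sd = effect_fc_sd.copy()

    # demographics
    ages_c = rng.uniform(*cfg.age_range, size=cfg.n_controls)
    if cfg.fixed_duration is not None:
        # pinned duration: patient ages must stay above duration + 1
        lo = min(max(cfg.age_range[0], cfg.fixed_duration + 1.0),
                 cfg.age_range[1])
        ages_p = rng.uniform(lo, cfg.age_range[1], size=cfg.n_patients)
    else:
        ages_p = rng.uniform(*cfg.age_range, size=cfg.n_patients)
    durations = _sample_durations(rng, cfg, ages_p)
    sides = np.array(["right"] * cfg.n_right_focus
                     + ["left"] * (cfg.n_patients - cfg.n_right_focus))
    rng.shuffle(sides)

    subjects: list[SubjectRecord] = []
    connectomes: dict[tuple[str, str], Connectome] = {}

    def make_subject(sid: str, age: float, effect_scale: float,
                     focus: str | None) -> None:
        fc = fc_mean + fc_slopes * (age - age_ref) + _sym_noise(rng, n, cfg.fc_noise_sd)
        log_sc = (sc_log_mean + sc_slopes * (age - age_ref)
                  + _sym_noise(rng, n, cfg.sc_dispersion))
        if focus is not None and effect_scale != 0.0:
            shift = effect_bin_sd[focus] * effect_scale * cfg.effect_direction
            fc = fc + shift * cfg.fc_noise_sd
            log_sc = log_sc + shift * cfg.sc_dispersion
        # per-subject missingness for SC/LEN
        u = np.zeros((n, n))
        u[iu] = rng.random(len(iu[0]))
        u = u + u.T
        missing = u < miss_prob
        np.fill_diagonal(missing, False)
        sc = np.exp(log_sc)
        sc[missing] = 0.0
        np.fill_diagonal(sc, 0.0)
        length = latent_len * (1.0 + _sym_noise(rng, n, cfg.len_jitter_sd))
        length[missing] = 0.0
        np.fill_diagonal(fc, 0.0)
        connectomes[(sid, "FC")] = Connectome(sid, "FC", fc)
        connectomes[(sid, "SC")] = Connectome(sid, "SC", sc)
        connectomes[(sid, "LEN")] = Connectome(sid, "LEN", length)

    for i in range(cfg.n_controls):
        sid = f"con{i:03d}"
        subjects.append(SubjectRecord(sid, "control", float(ages_c[i])))
        make_subject(sid, ages_c[i], 0.0, None)
    for i in range(cfg.n_patients):
        sid = f"pat{i:03d}"
        subjects.append(SubjectRecord(sid, "patient", float(ages_p[i]),
                                      float(durations[i]), str(sides[i])))
        scale = (durations[i] / REFERENCE_DURATION) ** cfg.effect_duration_exponent
        make_subject(sid, ages_p[i], float(scale), str(sides[i]))

    cohort = Cohort(atlas=atlas, subjects=subjects, connectomes=connectomes)
    truth = GroundTruth(coords=coords, latent_len=latent_len,
                        fc_age_slopes=fc_slopes, sc_age_slopes=sc_slopes,
                        effect_fc_sd=effect_fc_sd, effect_sc_sd=effect_sc_sd,
                        seed_region=seed_region, planted_bins=planted)
    return cohort, truth


# ---------------------------------------------------------------------------
# planted whole-brain ICA component
# ---------------------------------------------------------------------------

def _loading_with_target_spearman(rng: np.random.Generator,
                                  durations: np.ndarray,
                                  target_rho: float) -> tuple[np.ndarray, float]:
    """Mix duration ranks with noise; pick the mixture whose realised
    Spearman correlation with duration is closest to the target."""
    r = stats.rankdata(durations)
    r = (r - r.mean()) / r.std()
    eps = rng.standard_normal(len(durations))
    eps = eps - eps.mean()
    eps = eps - r * (eps @ r) / (r @ r)       # orthogonalise
    eps = eps / eps.std()
    best, best_rho = None, None
    for c in np.linspace(0.0, 1.0, 401):
        x = c * r + math.sqrt(max(0.0, 1.0 - c * c)) * eps
        rho = stats.spearmanr(x, durations).statistic
        if best is None or abs(rho - target_rho) < abs(best_rho - target_rho):
            best, best_rho = x, rho
    return best, float(best_rho)


def plant_ica_component(cohort: Cohort,
                        pattern_sparsity: float = 0.10,
                        loading_vs_duration_rho: float = 0.6,
                        amplitude: float = 1.0,
                        seed: int = 0,
                        ground_truth: GroundTruth | None = None,
                        pattern_mode: str = "random",
                        fc_scale: float = 0.2,
                        sc_scale: float = 0.5,
                        ) -> tuple[Cohort, GroundTruth]:
    """Add a rank-1 duration-linked edge pattern to the patients.

    The spatial pattern lives in the ipsilateral/contralateral frame (it is
    mapped into each patient's native orientation through the focus-side
    permutation) and spans both the FC block (added on the Fisher-z scale,
    in units of ``fc_scale``) and the SC block (added on the log scale in
    units of ``sc_scale``, present edges only). The per-patient loading is
    constructed to realise approximately the requested Spearman correlation
    with duration of disease; ``amplitude`` scales the whole pattern in
    control-SD units. ``pattern_mode`` is ``"random"`` (sign-consistent
    random support) or ``"distance_decay"`` (magnitudes decay with latent
    streamline length from the anterior hippocampus; requires
    ``ground_truth``).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not 0 < pattern_sparsity <= 1:
        raise ValueError("pattern_sparsity must be in (0, 1]")
    patients = cohort.patients()
    if not patients:
        raise ValueError("cohort has no patients")

    atlas = cohort.atlas
    n = atlas.n_regions
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1CA]))
    iu = np.triu_indices(n, k=1)
    n_edges = len(iu[0])

    def sparse_random_pattern() -> np.ndarray:
        k = max(1, int(round(pattern_sparsity * n_edges)))
        support = rng.choice(n_edges, size=k, replace=False)
        vals = np.zeros(n_edges)
        vals[support] = (rng.choice([-1.0, 1.0], size=k)
                         * rng.uniform(0.5, 1.5, size=k))
        vals /= np.sqrt(np.mean(vals[support] ** 2))
        m = np.zeros((n, n))
        m[iu] = vals
        return m + m.T

    if pattern_mode == "random":
        pat_fc = sparse_random_pattern()
        pat_sc = sparse_random_pattern()
    elif pattern_mode == "distance_decay":
        if ground_truth is None:
            raise ValueError("distance_decay pattern needs the ground truth")
        seed_idx = ground_truth.seed_region["left"]  # ipsi slots = left slots
        w = np.exp(-ground_truth.latent_len[seed_idx] / 40.0)
        w[seed_idx] = 1.0
        outer = np.outer(w, w)
        np.fill_diagonal(outer, 0.0)
        thresh = np.quantile(outer[iu], 1.0 - pattern_sparsity)
        # positive support: connectivity change grows toward the focus, so
        # the (rho >= 0 aligned) degree decays with distance from it
        m = np.where(outer >= thresh, outer, 0.0)
        m /= np.sqrt(np.mean(m[iu][m[iu] != 0] ** 2))
        pat_fc = m
        pat_sc = m.copy()
    else:
        raise ValueError(f"unknown pattern_mode {pattern_mode!r}")

    durations = np.array([p.duration for p in patients])
    loading, realized = _loading_with_target_spearman(
        rng, durations, loading_vs_duration_rho)

    new_connectomes = dict(cohort.connectomes)
    if amplitude > 0:
        for p, load in zip(patients, loading):
            perm = ipsi_contra_permutation(atlas, p.focus_side)
            # additive pattern mapped back into the patient's native frame
            add_fc = (amplitude * load * fc_scale * pat_fc)[np.ix_(perm, perm)]
            fc = cohort.get(p.subject_id, "FC")
            new_connectomes[(p.subject_id, "FC")] = Connectome(
                p.subject_id, "FC", fc.matrix + add_fc)
            sc = cohort.get(p.subject_id, "SC")
            add_sc = (amplitude * load * sc_scale * pat_sc)[np.ix_(perm, perm)]
            present = ~sc.missing_mask
            np.fill_diagonal(present, False)
            new_sc = sc.matrix.copy()
            new_sc[present] = np.exp(np.log(new_sc[present]) + add_sc[present])
            new_connectomes[(p.subject_id, "SC")] = Connectome(
                p.subject_id, "SC", new_sc)

    new_cohort = Cohort(atlas=atlas, subjects=list(cohort.subjects),
                        connectomes=new_connectomes)
    if ground_truth is None:
        z = np.zeros((n, n))
        ground_truth = GroundTruth(
            coords=np.zeros((n, 3)), latent_len=z, fc_age_slopes=z,
            sc_age_slopes=z, effect_fc_sd=z, effect_sc_sd=z,
            seed_region={s: atlas.anterior_hippocampus(s) for s in ("left", "right")},
            planted_bins={})
    ground_truth.ica_pattern_fc = pat_fc
    ground_truth.ica_pattern_sc = pat_sc
    ground_truth.ica_loading = loading
    ground_truth.ica_realized_rho = realized
    return new_cohort, ground_truth
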