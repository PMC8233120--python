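"""Per-patient, per-bin multivariate deviation from the control population.

The deviation of a patient's bin of seed edges from the controls is the
(squared, by default) Mahalanobis distance

    M = (s - mu)^T C^{-1} (s - mu)

where ``s`` holds the patient's age-residualised edge values, ``mu`` the
control means and ``C`` the control covariance estimated with Ledoit-Wolf
shrinkage toward a scaled identity (positive definite even at 50 controls
by 7 edges). Because bins differ in size and some structural edges are
undetected in some subjects, M is averaged over a nested subsampling
scheme: random subsets of ``k_subset`` edges (outer loop; a draw is
discarded when the patient lacks a drawn edge) crossed with random subsets
of controls (inner loop; controls missing a drawn edge are excluded and
the draw is discarded when too few complete controls remain).

The shrinkage estimator is implemented here in batched form so that the
full permutation grid is evaluated as a handful of vectorised operations;
it matches ``sklearn.covariance.ledoit_wolf`` on a per-draw basis.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

from .core import Connectome
from .topology import EdgeBinning


# ---------------------------------------------------------------------------
# batched Ledoit-Wolf shrinkage
# ---------------------------------------------------------------------------

def ledoit_wolf_covariance_batch(X: np.ndarray,
                                 weights: np.ndarray | None = None
                                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ledoit-Wolf shrunk covariance for a batch of samples.

    Parameters
    ----------
    X : (B, n, k) array, B independent sample matrices.
    weights : optional (B, n) 0/1 array marking the rows actually used per
        batch element (rows with weight 0 are ignored, allowing a ragged
        batch with varying effective n).

    Returns
    -------
    cov : (B, k, k) shrunk covariance matrices
    mean : (B, k) sample means
    shrinkage : (B,) shrinkage intensities
    """
    X = np.asarray(X, dtype=float)
    B, n, k = X.shape
    if weights is None:
        nb = np.full(B, float(n))
        mean = X.mean(axis=1)
        Xc = X - mean[:, None, :]
    else:
        w = np.asarray(weights, dtype=float)
        nb = w.sum(axis=1)
        if np.any(nb < 2):
            raise ValueError("each batch element needs at least 2 samples")
        mean = np.matmul(w[:, None, :], X)[:, 0, :] / nb[:, None]
        Xc = (X - mean[:, None, :]) * w[:, :, None]

    S = np.matmul(Xc.transpose(0, 2, 1), Xc) / nb[:, None, None]
    trace = np.trace(S, axis1=1, axis2=2)
    mu = trace / k
    frob2 = (S * S).sum(axis=(1, 2))
    # sum over samples of (row sum of squares)^2
    row_sq = (Xc * Xc).sum(axis=2)
    beta_ = (row_sq * row_sq).sum(axis=1)
    beta = (beta_ / nb - frob2) / (k * nb)
    delta = (frob2 - 2.0 * mu * trace + k * mu ** 2) / k
    with np.errstate(divide="ignore", invalid="ignore"):
        shrinkage = np.where(delta > 0, np.minimum(beta, delta) / delta, 0.0)
    shrinkage = np.clip(np.where(np.isfinite(shrinkage), shrinkage, 0.0), 0.0, 1.0)
    eye = np.eye(k)
    cov = ((1.0 - shrinkage)[:, None, None] * S
           + (shrinkage * mu)[:, None, None] * eye[None])
    return cov, mean, shrinkage


def _shrunk_covariance(X: np.ndarray, shrinkage) -> tuple[np.ndarray, np.ndarray]:
    """Covariance + mean of one sample matrix under the named shrinkage."""
    X = np.asarray(X, dtype=float)
    if shrinkage == "ledoit_wolf":
        cov, mean, _ = ledoit_wolf_covariance_batch(X[None])
        return cov[0], mean[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    S = Xc.T @ Xc / X.shape[0]
    if shrinkage in (None, "none"):
        return S, mean
    if isinstance(shrinkage, (int, float)):
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("fixed shrinkage intensity must be in [0, 1]")
        mu = np.trace(S) / S.shape[0]
        return (1.0 - lam) * S + lam * mu * np.eye(S.shape[0]), mean
    raise ValueError(f"unknown shrinkage {shrinkage!r}")


def mahalanobis(s: np.ndarray, controls: np.ndarray,
                shrinkage="ledoit_wolf", covariance: np.ndarray | None = None,
                squared: bool = True) -> float:
    """Mahalanobis deviation of one vector from a control sample.

    ``covariance`` overrides the estimated (shrunk) covariance, e.g. to
    force an identity matrix. With ``squared=False`` the square root is
    returned (identity covariance then gives the Euclidean distance).
    """
    s = np.asarray(s, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if controls.ndim != 2 or s.shape != (controls.shape[1],):
        raise ValueError("shape mismatch between s and the control matrix")
    if np.isnan(s).any() or np.isnan(controls).any():
        raise ValueError("control rows and s must be complete (no NaN)")
    if covariance is not None:
        C = np.asarray(covariance, dtype=float)
        mean = controls.mean(axis=0)
    else:
        C, mean = _shrunk_covariance(controls, shrinkage)
    diff = s - mean
    try:
        sol = np.linalg.solve(C, diff)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular covariance: {e}") from e
    m = float(diff @ sol)
    return m if squared else math.sqrt(max(m, 0.0))


# ---------------------------------------------------------------------------
# nested permutation subsampling over a binning
# ---------------------------------------------------------------------------

@dataclass
class MahalanobisConfig:
    """Knobs of the nested subsampling scheme (defaults: full fidelity)."""

    k_subset: int = 7
    n_edge_permutations: int = 500
    n_control_permutations: int = 500
    n_controls_drawn: int = 50
    min_controls_complete: int = 45
    shrinkage: str = "ledoit_wolf"
    squared: bool = True
    seed: int = 0
    chunk_size: int = 4096

    def __post_init__(self) -> None:
        if self.min_controls_complete > self.n_controls_drawn:
            raise ValueError("min_controls_complete cannot exceed n_controls_drawn")
        if self.k_subset < 1:
            raise ValueError("k_subset must be >= 1")

    def reduced(self, n_outer: int = 100, n_inner: int = 100) -> "MahalanobisConfig":
        """Copy with fewer permutations (desk-scale profile)."""
        from dataclasses import replace
        return replace(self, n_edge_permutations=n_outer,
                       n_control_permutations=n_inner)


@dataclass
class BinResult:
    m_pooled: float                 # mean over all retained (edge, control) pairs
    m_nested: float                 # mean over outer draws of inner means
    retained_outer: int
    retained_pairs: int
    discarded_outer_patient_missing: int
    discarded_inner_incomplete: int
    discard_reason: str | None = None


@dataclass
class MahalanobisProfile:
    """Per-bin deviation statistics for one patient and one modality."""

    patient_id: str
    modality: str                   # "M_FC" | "M_SC"
    hemisphere: str                 # "ipsi" | "contra"
    topology: str
    bins: list[BinResult]

    @property
    def M(self) -> np.ndarray:
        return np.array([b.m_pooled for b in self.bins])

    @property
    def M_nested(self) -> np.ndarray:
        return np.array([b.m_nested for b in self.bins])

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.M).all())


def _stream_rng(seed: int, patient_id: str, bin_index: int,
                label: str) -> np.random.Generator:
    """Deterministic RNG stream keyed by (seed, patient, bin, label)."""
    digest = hashlib.sha256(f"{patient_id}|{label}".encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key, bin_index]))


def _subsets(rng: np.random.Generator, n_draws: int, pool: int,
             size: int) -> np.ndarray:
    """(n_draws, size) independent subsets without replacement."""
    keys = rng.random((n_draws, pool))
    return np.argsort(keys, axis=1)[:, :size]


def _draw_masks(rng: np.random.Generator, shape: tuple, pool: int,
                size: int) -> np.ndarray:
    """Boolean masks selecting ``size`` of ``pool`` items per draw."""
    keys = rng.random(shape + (pool,))
    kth = np.partition(keys, size - 1, axis=-1)[..., size - 1:size]
    return keys <= kth


def _bin_mahalanobis_one(pv: np.ndarray, pmiss: np.ndarray,
                         cv: np.ndarray, cmiss: np.ndarray,
                         cfg: MahalanobisConfig,
                         rng: np.random.Generator) -> BinResult:
    """Nested subsampled M for one bin.

    pv/pmiss: (k_bin,) patient edge values and missingness;
    cv/cmiss: (n_ctrl, k_bin) control edge values and missingness.

    The inner loop is evaluated as batched linear algebra: for each edge
    subset, per-control outer products are accumulated through a single
    matrix product with the 0/1 draw-indicator matrix, which yields every
    draw's mean, covariance and Ledoit-Wolf statistics at once.
    """
    k_bin = len(pv)
    n_ctrl = cv.shape[0]
    k = cfg.k_subset
    if k > k_bin:
        raise ValueError(f"k_subset={k} exceeds bin size {k_bin}")
    if cfg.n_controls_drawn > n_ctrl:
        raise ValueError("n_controls_drawn exceeds the number of controls")

    E = _subsets(rng, cfg.n_edge_permutations, k_bin, k)
    outer_ok = ~pmiss[E].any(axis=1)
    n_disc_outer = int((~outer_ok).sum())
    E = E[outer_ok]
    n_outer = len(E)
    if n_outer == 0:
        return BinResult(np.nan, np.nan, 0, 0, n_disc_outer, 0,
                         "patient missing edges in every edge subset")

    n_inner = cfg.n_control_permutations
    outer_sum = np.zeros(n_outer)
    outer_cnt = np.zeros(n_outer, dtype=int)
    n_disc_inner = 0
    cv_nan = np.where(cmiss, 0.0, cv)
    co = max(1, cfg.chunk_size // n_inner)      # outer subsets per chunk
    eye = np.eye(k)

    for start in range(0, n_outer, co):
        Eb = E[start:start + co]                              # (O, k)
        O = len(Eb)
        X = np.ascontiguousarray(cv_nan[:, Eb].transpose(1, 0, 2))  # (O, c, k)
        incomplete = cmiss[:, Eb].any(axis=2).T               # (O, c)
        drawn = _draw_masks(rng, (O, n_inner), n_ctrl, cfg.n_controls_drawn)
        used = drawn & ~incomplete[:, None, :]                # (O, I, c)
        nb = used.sum(axis=2)                                 # (O, I)
        ok = nb >= cfg.min_controls_complete
        n_disc_inner += int((~ok).sum())
        if not ok.any():
            continue
        W = used.astype(float)
        nbf = np.maximum(nb, 2).astype(float)
        mean = np.matmul(W, X) / nbf[..., None]               # (O, I, k)
        OP = (X[:, :, :, None] * X[:, :, None, :]).reshape(O, n_ctrl, k * k)
        S = (np.matmul(W, OP).reshape(O, n_inner, k, k) / nbf[..., None, None]
             - mean[..., :, None] * mean[..., None, :])
        trace = np.trace(S, axis1=2, axis2=3)
        mu = trace / k
        frob2 = (S * S).sum(axis=(2, 3))
        # Ledoit-Wolf beta via ||x_c - mean||^2 expansion
        q = (X * X).sum(axis=2)                               # (O, c)
        p = np.matmul(X, mean.transpose(0, 2, 1))             # (O, c, I)
        musq = (mean * mean).sum(axis=2)                      # (O, I)
        r2 = (q[:, :, None] - 2.0 * p + musq[:, None, :]) ** 2
        beta_ = (W.transpose(0, 2, 1) * r2).sum(axis=1)       # (O, I)
        beta = (beta_ / nbf - frob2) / (k * nbf)
        delta = (frob2 - 2.0 * mu * trace + k * mu ** 2) / k
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(delta > 0, np.minimum(beta, delta) / delta, 0.0)
        lam = np.clip(np.where(np.isfinite(lam), lam, 0.0), 0.0, 1.0)
        cov = ((1.0 - lam)[..., None, None] * S
               + (lam * mu)[..., None, None] * eye)
        diff = pv[Eb][:, None, :] - mean
        # keep only the retained draws for the solve
        oi, ii = np.nonzero(ok)
        sol = np.linalg.solve(cov[oi, ii], diff[oi, ii][..., None])[..., 0]
        m = (diff[oi, ii] * sol).sum(axis=1)
        if not cfg.squared:
            m = np.sqrt(np.maximum(m, 0.0))
        np.add.at(outer_sum, start + oi, m)
        np.add.at(outer_cnt, start + oi, 1)

    retained = outer_cnt > 0
    retained_pairs = int(outer_cnt.sum())
    if retained_pairs == 0:
        return BinResult(np.nan, np.nan, 0, 0, n_disc_outer, n_disc_inner,
                         "all inner draws short of complete controls")
    m_pooled = float(outer_sum.sum() / retained_pairs)
    m_nested = float(np.mean(outer_sum[retained] / outer_cnt[retained]))
    return BinResult(m_pooled, m_nested, int(retained.sum()), retained_pairs,
                     n_disc_outer, n_disc_inner)


def bin_mahalanobis(patient: Connectome, controls: list[Connectome],
                    binning: EdgeBinning, config: MahalanobisConfig,
                    modality_label: str = "M_FC",
                    hemisphere: str = "ipsi") -> MahalanobisProfile:
    """Subsampled Mahalanobis deviation of one patient across all bins.

    ``patient``/``controls`` hold age-residualised (res-scale) values. RNG
    streams derive deterministically from (config.seed, patient id, bin).
    """
    seed_region = binning.seed
    results = []
    for b, regions in enumerate(binning.bins):
        pv = patient.matrix[seed_region, regions]
        pmiss = patient.missing_mask[seed_region, regions]
        cv = np.stack([c.matrix[seed_region, regions] for c in controls])
        cmiss = np.stack([c.missing_mask[seed_region, regions] for c in controls])
        rng = _stream_rng(config.seed, patient.subject_id, b,
                          f"{modality_label}|{hemisphere}|{binning.kind}")
        results.append(_bin_mahalanobis_one(pv, pmiss, cv, cmiss, config, rng))
    return MahalanobisProfile(patient_id=patient.subject_id,
                              modality=modality_label, hemisphere=hemisphere,
                              topology=binning.kind, bins=results)
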