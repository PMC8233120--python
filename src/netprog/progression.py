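"""Gradient hypothesis tests on per-bin Mahalanobis profiles.

The hypothesis that network change decreases with healthy-brain distance
from the focus (M of bin 1 > bin 2 > ... ) is accepted only when three
criteria hold simultaneously:

1. a one-way repeated-measures ANOVA with bin as the within-subject
   factor is significant at the (Bonferroni-adjusted) alpha;
2. the group means decrease monotonically from bin 1 to the last bin;
3. uncorrected paired t-tests never show a higher-index bin significantly
   greater than a lower-index bin (two-sided p < 0.05 in the wrong
   direction).

The duration analysis splits patients into short (<= 10 y), medium
(11-30 y) and long (> 30 y) disease-duration groups, repeats the test per
group, and reports the bin-by-group interaction of a mixed ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .agenorm import normalize_cohort, CorrectedCohort
from .core import Cohort
from .mahalanobis import MahalanobisConfig, MahalanobisProfile, bin_mahalanobis
from .topology import (DEFAULT_N_BINS, EdgeBinning, TopologyModel, bin_edges,
                       build_topology, model_vector)


@dataclass
class GradientTestResult:
    F: float
    df1: float
    df2: float
    p: float
    bin_means: np.ndarray
    monotone_decrease: bool
    pairwise_p: np.ndarray          # (n_bins, n_bins), two-sided, uncorrected
    verdict: bool
    alpha: float
    n_patients: int


def _profile_matrix(profiles: list[MahalanobisProfile],
                    use_nested: bool = False) -> tuple[np.ndarray, list[str]]:
    rows, ids = [], []
    for p in profiles:
        m = p.M_nested if use_nested else p.M
        if not np.isfinite(m).all():
            warnings.warn(f"{p.patient_id}: undefined bin M, patient dropped")
            continue
        rows.append(m)
        ids.append(p.patient_id)
    if len(rows) < 3:
        raise ValueError("need at least 3 patients with all bins defined")
    return np.asarray(rows), ids


def _rm_anova(M: np.ndarray) -> tuple[float, float, float, float]:
    n, k = M.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "bin": np.tile(np.arange(k), n),
        "M": M.ravel(),
    })
    if np.allclose(M.var(axis=0), 0.0):
        return float("nan"), float(k - 1), float((k - 1) * (n - 1)), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(data=long, dv="M", within="bin", subject="subject",
                          detailed=False)
    row = aov.iloc[0]
    return (float(row["F"]), float(row["ddof1"]), float(row["ddof2"]),
            float(row["p_unc"]))


def gradient_test(profiles: list[MahalanobisProfile],
                  alpha: float = 0.0125,
                  use_nested: bool = False) -> GradientTestResult:
    """Apply the three-criterion decreasing-gradient test across bins."""
    M, _ = _profile_matrix(profiles, use_nested)
    n, k = M.shape
    F, df1, df2, p = _rm_anova(M)
    means = M.mean(axis=0)
    monotone = bool(np.all(np.diff(means) < 0))
    pw = np.full((k, k), np.nan)
    violation = False
    for i in range(k):
        for j in range(i + 1, k):
            t = stats.ttest_rel(M[:, i], M[:, j])
            pw[i, j] = pw[j, i] = t.pvalue
            if means[j] > means[i] and t.pvalue < 0.05:
                violation = True
    verdict = bool(np.isfinite(p) and p <= alpha and monotone and not violation)
    return GradientTestResult(F=F, df1=df1, df2=df2, p=p, bin_means=means,
                              monotone_decrease=monotone, pairwise_p=pw,
                              verdict=verdict, alpha=alpha, n_patients=n)


@dataclass
class DurationGroupResult:
    group_results: dict[str, GradientTestResult]
    group_sizes: dict[str, int]
    interaction_F: float
    interaction_df1: float
    interaction_df2: float
    interaction_p: float
    boundaries: tuple[float, float]


def assign_duration_group(duration: float,
                          boundaries: tuple[float, float] = (10.0, 30.0)) -> str:
    lo, hi = boundaries
    if duration <= lo:
        return "short"
    if duration <= hi:
        return "medium"
    return "long"


def duration_group_analysis(profiles: list[MahalanobisProfile],
                            durations: dict[str, float],
                            boundaries: tuple[float, float] = (10.0, 30.0),
                            alpha: float = 0.05,
                            use_nested: bool = False) -> DurationGroupResult:
    """Per-duration-group gradient tests plus the mixed-ANOVA interaction."""
    M, ids = _profile_matrix(profiles, use_nested)
    by_id = {p.patient_id: p for p in profiles}
    groups = np.array([assign_duration_group(durations[i], boundaries)
                       for i in ids])
    group_results, group_sizes = {}, {}
    for g in ("short", "medium", "long"):
        members = [by_id[i] for i, gi in zip(ids, groups) if gi == g]
        group_sizes[g] = len(members)
        if len(members) < 3:
            if members:
                warnings.warn(f"duration group {g!r} has <3 patients; skipped")
            continue
        group_results[g] = gradient_test(members, alpha=alpha,
                                         use_nested=use_nested)

    n, k = M.shape
    if len(set(groups)) < 2:
        f = df1 = df2 = p = float("nan")
    else:
        long = pd.DataFrame({
            "subject": np.repeat(ids, k),
            "bin": np.tile(np.arange(k), n),
            "group": np.repeat(groups, k),
            "M": M.ravel(),
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=long, dv="M", within="bin",
                                 subject="subject", between="group")
        row = aov.loc[aov["Source"] == "Interaction"].iloc[0]
        f, df1, df2, p = (float(row["F"]), float(row["DF1"]),
                          float(row["DF2"]), float(row["p_unc"]))
    return DurationGroupResult(group_results=group_results,
                               group_sizes=group_sizes, interaction_F=f,
                               interaction_df1=df1, interaction_df2=df2,
                               interaction_p=p, boundaries=boundaries)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def hippocampal_binnings(cohort: Cohort, kind: str,
                         n_bins: int | None = None) -> dict[str, EdgeBinning]:
    """Anterior-hippocampus edge binnings per hemisphere for one topology."""
    model = build_topology(cohort, kind)
    out = {}
    for side in ("left", "right"):
        seed = cohort.atlas.anterior_hippocampus(side)
        v = model_vector(model, seed, side=side if kind != "RSN" else None)
        out[side] = bin_edges(v, n_bins)
    return out


def hippocampal_profiles(cohort: Cohort, corrected: CorrectedCohort,
                         binnings: dict[str, EdgeBinning], modality: str,
                         config: MahalanobisConfig,
                         hemisphere: str = "ipsi"
                         ) -> list[MahalanobisProfile]:
    """Per-patient bin deviations with the seed ipsi- or contralateral.

    M is computed in native left/right space: for each patient the seed is
    the anterior hippocampus of the focus hemisphere (``ipsi``) or of the
    opposite one (``contra``), against the controls' native values on the
    same side; controls are never flipped.
    """
    opposite = {"left": "right", "right": "left"}
    controls = {side: None for side in ("left", "right")}
    label = f"M_{modality}"
    profiles = []
    ctrl_ids = [s.subject_id for s in cohort.controls()]
    ctrl_res = [corrected.res[(cid, modality)] for cid in ctrl_ids]
    for p in cohort.patients():
        side = p.focus_side if hemisphere == "ipsi" else opposite[p.focus_side]
        profiles.append(bin_mahalanobis(
            corrected.res[(p.subject_id, modality)], ctrl_res,
            binnings[side], config, modality_label=label,
            hemisphere=hemisphere))
    return profiles


def analyze_hippocampal(cohort: Cohort, kind: str, modality: str,
                        config: MahalanobisConfig,
                        corrected: CorrectedCohort | None = None,
                        n_bins: int | None = None,
                        hemisphere: str = "ipsi",
                        alpha: float = 0.0125
                        ) -> tuple[list[MahalanobisProfile], GradientTestResult]:
    """End-to-end: normalize, build topology bins, profile patients, test."""
    if corrected is None:
        corrected = normalize_cohort(cohort, modalities=(modality,))
    binnings = hippocampal_binnings(cohort, kind, n_bins)
    profiles = hippocampal_profiles(cohort, corrected, binnings, modality,
                                    config, hemisphere)
    return profiles, gradient_test(profiles, alpha=alpha)
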