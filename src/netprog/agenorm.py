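"""Edge-wise linear age correction fitted on healthy controls.

For every edge, an ordinary least-squares line of the control values
against age gives a slope, intercept and RMSE. Subject connectomes are
then expressed as

* ``res``  — residual from the control age fit (same units as the input:
  Fisher-z for FC, natural-log units for SC), and
* ``corr`` — residual divided by the control RMSE, i.e. the deviation in
  SD units from an age-matched control.

Structural connectivity is log-transformed before fitting; undetected
(zero) edges stay missing and never receive a pseudocount. The RMSE uses
the biased 1/n denominator by default (a 1/(n-2) option exists). Fits are
done in native left/right space; any ipsi/contra flip happens downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Cohort, Connectome

MIN_CONTROLS_PER_EDGE = 3


@dataclass
class EdgeAgeModel:
    """Per-edge control age fit for one modality."""

    modality: str
    slope: np.ndarray          # value units per year
    intercept: np.ndarray      # value units at age 0
    rmse: np.ndarray           # root mean squared residual of the fit
    n_controls: np.ndarray     # controls contributing per edge
    unfittable: np.ndarray     # fewer than MIN_CONTROLS_PER_EDGE controls
    degenerate: np.ndarray     # fit exists but rmse == 0
    rmse_denominator: str = "n"

    @property
    def n_regions(self) -> int:
        return self.slope.shape[0]


def _edge_values(connectome: Connectome, modality: str) -> np.ndarray:
    """Fit-scale values: identity for FC, natural log for SC (present only)."""
    if modality == "SC":
        with np.errstate(divide="ignore"):
            v = np.where(connectome.missing_mask, np.nan,
                         np.log(np.where(connectome.matrix > 0,
                                         connectome.matrix, np.nan)))
        np.fill_diagonal(v, 0.0)
        return v
    return np.where(connectome.missing_mask, np.nan, connectome.matrix)


def fit_age_model(connectomes: Sequence[Connectome], ages: Sequence[float],
                  modality: str, rmse_denominator: str = "n") -> EdgeAgeModel:
    """Edge-wise OLS of control values on age.

    Edges present in fewer than 3 controls are flagged unfittable. A zero
    overall age variance is an error; per-edge zero age variance (possible
    with missing data) flags the edge unfittable.
    """
    if rmse_denominator not in ("n", "n-2"):
        raise ValueError("rmse_denominator must be 'n' or 'n-2'")
    ages = np.asarray(ages, dtype=float)
    if len(ages) != len(connectomes):
        raise ValueError("ages and connectomes length mismatch")
    if np.var(ages) == 0.0:
        raise ValueError("zero age variance among controls")

    Y = np.stack([_edge_values(c, modality) for c in connectomes])  # (n, N, N)
    present = np.isfinite(Y)
    Yz = np.where(present, Y, 0.0)
    a = ages[:, None, None]

    w = present.astype(float)
    sw = w.sum(0)
    sx = (w * a).sum(0)
    sy = Yz.sum(0)
    sxx = (w * a * a).sum(0)
    sxy = (a * Yz).sum(0)
    denom = sw * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / sw
        resid = np.where(present, Y - (slope * a + intercept), 0.0)
        dof = sw if rmse_denominator == "n" else sw - 2
        mse = (resid ** 2).sum(0) / dof

    unfittable = (sw < MIN_CONTROLS_PER_EDGE) | ~np.isfinite(slope)
    slope = np.where(unfittable, np.nan, slope)
    intercept = np.where(unfittable, np.nan, intercept)
    rmse = np.where(unfittable, np.nan, np.sqrt(np.maximum(mse, 0.0)))
    degenerate = ~unfittable & (rmse == 0.0)
    n = Y.shape[1]
    for m in (slope, intercept, rmse):
        np.fill_diagonal(m, 0.0)
    np.fill_diagonal(unfittable, False)
    np.fill_diagonal(degenerate, False)
    return EdgeAgeModel(modality=modality, slope=slope, intercept=intercept,
                        rmse=rmse, n_controls=sw.astype(int),
                        unfittable=unfittable, degenerate=degenerate,
                        rmse_denominator=rmse_denominator)


def apply_age_correction(connectome: Connectome, age: float,
                         model: EdgeAgeModel) -> tuple[Connectome, Connectome]:
    """Residualise one subject against the control age fit.

    Returns ``(res, corr)`` connectomes. Edges missing in the subject, or
    unfittable in the model, propagate as missing; a degenerate edge
    (rmse == 0) is additionally missing in ``corr``.
    """
    if model.n_regions != connectome.n_regions:
        raise ValueError("model and connectome dimension mismatch")
    if model.modality != connectome.modality:
        raise ValueError(f"model fitted for {model.modality}, "
                         f"got {connectome.modality}")
    v = _edge_values(connectome, model.modality)
    fit = model.slope * age + model.intercept
    res = v - fit
    missing = ~np.isfinite(res) | model.unfittable
    res_vals = np.where(missing, 0.0, res)
    np.fill_diagonal(res_vals, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = res / model.rmse
    corr_missing = missing | model.degenerate
    corr_vals = np.where(corr_missing, 0.0, corr)
    np.fill_diagonal(corr_vals, 0.0)
    sid = connectome.subject_id
    return (Connectome(sid, connectome.modality, res_vals, missing),
            Connectome(sid, connectome.modality, corr_vals, corr_missing))


@dataclass
class CorrectedCohort:
    """Age-corrected connectomes for every subject of a cohort."""

    models: dict[str, EdgeAgeModel]                      # modality -> fit
    res: dict[tuple[str, str], Connectome]               # (subject, modality)
    corr: dict[tuple[str, str], Connectome]


def normalize_cohort(cohort: Cohort, modalities: Sequence[str] = ("FC", "SC"),
                     rmse_denominator: str = "n") -> CorrectedCohort:
    """Fit control age models per modality and correct every subject.

    Controls are corrected with the model fitted on all controls (no
    leave-one-out).
    """
    controls = cohort.controls()
    models: dict[str, EdgeAgeModel] = {}
    res: dict[tuple[str, str], Connectome] = {}
    corr: dict[tuple[str, str], Connectome] = {}
    for modality in modalities:
        ctrl_conn = [cohort.get(s.subject_id, modality) for s in controls]
        ages = [s.age for s in controls]
        model = fit_age_model(ctrl_conn, ages, modality, rmse_denominator)
        models[modality] = model
        for s in cohort.subjects:
            if not cohort.has(s.subject_id, modality):
                warnings.warn(f"{s.subject_id} lacks {modality}; skipped")
                continue
            r, c = apply_age_correction(cohort.get(s.subject_id, modality),
                                        s.age, model)
            res[(s.subject_id, modality)] = r
            corr[(s.subject_id, modality)] = c
    return CorrectedCohort(models=models, res=res, corr=corr)
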