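"""Plain-text cohort I/O.

Formats:

* connectome matrices — one TSV per subject per modality, named
  ``<subject_id>.<modality>.tsv``; first row and first column carry the
  0-based region ids; values printed with 17 significant digits so that a
  save/load round trip is bit exact.
* manifest — CSV with header ``subject_id,group,age,duration,focus_side``
  (duration/focus_side empty for controls).
* atlas — CSV with header
  ``region_id,name,hemisphere,rsn_label,is_anterior_hippocampus``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (Cohort, CohortError, Connectome, MODALITIES, RegionAtlas,
                   SubjectRecord, SYMMETRY_TOL)

MATRIX_FLOAT_FMT = "%.17g"


def save_matrix(matrix: np.ndarray, path) -> None:
    n = matrix.shape[0]
    df = pd.DataFrame(matrix, index=np.arange(n), columns=np.arange(n))
    df.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FMT)


def load_matrix(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise CohortError(f"{path}: matrix is not square")
    return df.to_numpy(dtype=float)


def _subject_to_row(s: SubjectRecord) -> dict:
    return {"subject_id": s.subject_id, "group": s.group, "age": s.age,
            "duration": "" if s.duration is None else s.duration,
            "focus_side": "" if s.focus_side is None else s.focus_side}


def _row_to_subject(row) -> SubjectRecord:
    duration = row.get("duration")
    focus = row.get("focus_side")
    duration = None if pd.isna(duration) or duration == "" else float(duration)
    focus = None if pd.isna(focus) or focus == "" else str(focus)
    return SubjectRecord(subject_id=str(row["subject_id"]), group=str(row["group"]),
                         age=float(row["age"]), duration=duration, focus_side=focus)


def save_cohort(cohort: Cohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.atlas.to_csv(out / "atlas.csv")
    pd.DataFrame([_subject_to_row(s) for s in cohort.subjects]).to_csv(
        out / "manifest.csv", index=False)
    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for (sid, modality), c in cohort.connectomes.items():
        save_matrix(c.matrix, mat_dir / f"{sid}.{modality}.tsv")


def load_cohort(manifest_path, atlas_path, matrix_dir) -> Cohort:
    """Load and validate a cohort from its on-disk layout.

    SC/LEN zeros become missing-mask entries; small numerical asymmetry
    (below 1e-8) is repaired by averaging with a warning, larger asymmetry
    is a hard error (raised by :class:`Connectome`).
    """
    atlas = RegionAtlas.from_csv(atlas_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "group", "age", "duration", "focus_side"}
    if not required <= set(manifest.columns):
        raise CohortError(f"manifest missing columns: "
                          f"{sorted(required - set(manifest.columns))}")
    subjects = [_row_to_subject(row) for _, row in manifest.iterrows()]

    matrix_dir = Path(matrix_dir)
    connectomes = {}
    for s in subjects:
        for modality in MODALITIES:
            path = matrix_dir / f"{s.subject_id}.{modality}.tsv"
            if not path.exists():
                continue
            m = load_matrix(path)
            if m.shape[0] != atlas.n_regions:
                raise CohortError(
                    f"{path}: dimension {m.shape[0]} != atlas {atlas.n_regions}")
            asym = np.abs(m - m.T).max()
            if asym > SYMMETRY_TOL:
                raise CohortError(f"{path}: asymmetry {asym:g} exceeds tolerance")
            if asym > 0:
                warnings.warn(f"{path}: symmetrised (max asymmetry {asym:g})")
                m = 0.5 * (m + m.T)
            connectomes[(s.subject_id, modality)] = Connectome(
                s.subject_id, modality, m)
    return Cohort(atlas=atlas, subjects=subjects, connectomes=connectomes)


def load_cohort_dir(cohort_dir) -> Cohort:
    """Load a cohort saved by :func:`save_cohort` from a single directory."""
    d = Path(cohort_dir)
    return load_cohort(d / "manifest.csv", d / "atlas.csv", d / "matrices")
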