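"""Core domain types for connectome-based network progression analysis.

The package analyses cohorts of per-subject brain connectomes in three
modalities:

* ``FC``  — functional connectivity, Fisher-z transformed correlations
  (unbounded reals, every edge present),
* ``SC``  — structural connectivity, volume-scaled streamline counts
  (non-negative; a count of exactly zero means the edge was not detected
  and is treated as *missing*, not small),
* ``LEN`` — mean streamline length (positive where present; shares the
  missing-edge semantics of SC).

Matrices are symmetric with an undefined (stored-as-zero) diagonal.
Patients carry a seizure-focus side and are mapped into a common
ipsilateral/contralateral frame by :func:`to_ipsi_contra`; controls are
always kept in native left/right space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MODALITIES = ("FC", "SC", "LEN")
HEMISPHERES = ("left", "right", "bilateral")

#: resting-state network labels along the transmodal -> unimodal gradient
RSN_NAMES = {0: "none", 1: "default_mode", 2: "attention", 3: "visual", 4: "motor"}

SYMMETRY_TOL = 1e-8


class AtlasError(ValueError):
    pass


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class RegionAtlas:
    """Region parcellation with hemisphere, RSN membership and seed flags.

    Backed by a DataFrame with columns ``region_id`` (0-based, equal to the
    row position), ``name``, ``hemisphere`` (left/right/bilateral),
    ``rsn_label`` (0-4, 0 = no network) and ``is_anterior_hippocampus``.
    Left/right homologues are matched by name: ``<base>_L`` pairs with
    ``<base>_R``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"region_id", "name", "hemisphere", "rsn_label",
                    "is_anterior_hippocampus"}
        missing = required - set(t.columns)
        if missing:
            raise AtlasError(f"atlas missing columns: {sorted(missing)}")
        if not np.array_equal(t["region_id"].to_numpy(), np.arange(len(t))):
            raise AtlasError("region_id must equal 0-based row position")
        bad = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad:
            raise AtlasError(f"unknown hemisphere labels: {sorted(bad)}")
        if not t["rsn_label"].isin(range(5)).all():
            raise AtlasError("rsn_label must be in 0..4")
        for side in ("left", "right"):
            n_hip = int(t.loc[t.hemisphere == side, "is_anterior_hippocampus"].sum())
            if n_hip != 1:
                raise AtlasError(
                    f"exactly one anterior hippocampus required per hemisphere, "
                    f"found {n_hip} on {side}")
        if t.loc[t.hemisphere == "bilateral", "is_anterior_hippocampus"].any():
            raise AtlasError("bilateral regions cannot be the anterior hippocampus")
        # left/right name pairing must be a bijection
        self._pairing()  # raises on mismatch

    # -- basic geometry -------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def indices(self, hemisphere: str) -> np.ndarray:
        """Region indices belonging to one hemisphere label."""
        return np.flatnonzero((self.table["hemisphere"] == hemisphere).to_numpy())

    def hemisphere_block(self, side: str) -> np.ndarray:
        """Indices of one hemisphere plus bilateral regions (brainstem).

        For the default 109-region atlas this has length 55.
        """
        if side not in ("left", "right"):
            raise AtlasError(f"side must be left or right, got {side!r}")
        return np.sort(np.concatenate([self.indices(side), self.indices("bilateral")]))

    def anterior_hippocampus(self, side: str) -> int:
        mask = ((self.table["hemisphere"] == side)
                & self.table["is_anterior_hippocampus"]).to_numpy()
        return int(np.flatnonzero(mask)[0])

    def _pairing(self) -> dict[int, int]:
        """Map left region index -> homotopic right region index (by name)."""
        t = self.table

        def base(name: str, side: str) -> str:
            suffix = "_L" if side == "left" else "_R"
            if not name.endswith(suffix):
                raise AtlasError(
                    f"{side} region {name!r} does not follow the <base>{suffix} "
                    f"naming convention needed for homotopic pairing")
            return name[: -len(suffix)]

        left = {base(n, "left"): i
                for i, n in zip(self.indices("left"), t["name"].iloc[self.indices("left")])}
        right = {base(n, "right"): i
                 for i, n in zip(self.indices("right"), t["name"].iloc[self.indices("right")])}
        if set(left) != set(right):
            odd = sorted(set(left) ^ set(right))
            raise AtlasError(f"unmatched left/right region names: {odd}")
        return {left[b]: right[b] for b in left}

    def homotopic_pairs(self) -> np.ndarray:
        """(n_pairs, 2) array of (left_index, right_index) homologues."""
        pairing = self._pairing()
        return np.array(sorted(pairing.items()), dtype=int)

    def rsn_labels(self) -> np.ndarray:
        return self.table["rsn_label"].to_numpy(dtype=int)

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "RegionAtlas":
        t = pd.read_csv(path)
        t["is_anterior_hippocampus"] = t["is_anterior_hippocampus"].astype(bool)
        return cls(t)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class Connectome:
    """One subject's symmetric region-by-region matrix for one modality."""

    subject_id: str
    modality: str
    matrix: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise CohortError(f"unknown modality {self.modality!r}")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise CohortError("connectome matrix must be square")
        if not np.allclose(m, m.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise CohortError(
                f"matrix for {self.subject_id}/{self.modality} is asymmetric "
                f"beyond tolerance {SYMMETRY_TOL}")
        np.fill_diagonal(m, 0.0)
        self.matrix = m
        if self.missing_mask is None:
            if self.modality == "FC":
                mask = np.zeros(m.shape, dtype=bool)
            else:  # SC/LEN: undetected edges are exactly zero
                mask = m == 0.0
                np.fill_diagonal(mask, False)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            if mask.shape != m.shape:
                raise CohortError("missing_mask shape mismatch")
            if not np.array_equal(mask, mask.T):
                raise CohortError("missing_mask must be symmetric")
            mask = mask.copy()
            np.fill_diagonal(mask, False)
        self.missing_mask = mask

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def copy(self) -> "Connectome":
        return Connectome(self.subject_id, self.modality,
                          self.matrix.copy(), self.missing_mask.copy())


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str                      # "control" | "patient"
    age: float                      # years
    duration: float | None = None   # years since onset, patients only
    focus_side: str | None = None   # "left" | "right", patients only

    def __post_init__(self) -> None:
        if self.group not in ("control", "patient"):
            raise CohortError(f"unknown group {self.group!r}")
        if self.group == "patient":
            if self.duration is None or not np.isfinite(self.duration):
                raise CohortError(f"patient {self.subject_id} missing duration")
            if self.focus_side not in ("left", "right"):
                raise CohortError(f"patient {self.subject_id} missing focus_side")
            if self.duration < 0:
                raise CohortError("duration must be >= 0")
            if self.duration > self.age:
                raise CohortError("duration cannot exceed age")
        else:
            if self.focus_side is not None:
                raise CohortError("controls must not carry a focus_side")


@dataclass
class Cohort:
    """Atlas + subject demographics + per-subject per-modality connectomes."""

    atlas: RegionAtlas
    subjects: list[SubjectRecord]
    connectomes: dict[tuple[str, str], Connectome]

    def __post_init__(self) -> None:
        n = self.atlas.n_regions
        ids = {s.subject_id for s in self.subjects}
        if len(ids) != len(self.subjects):
            raise CohortError("duplicate subject ids")
        for (sid, modality), c in self.connectomes.items():
            if sid not in ids:
                raise CohortError(f"connectome for unknown subject {sid!r}")
            if c.n_regions != n:
                raise CohortError(
                    f"{sid}/{modality}: matrix dimension {c.n_regions} != atlas {n}")

    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "patient"]

    def get(self, subject_id: str, modality: str) -> Connectome:
        return self.connectomes[(subject_id, modality)]

    def has(self, subject_id: str, modality: str) -> bool:
        return (subject_id, modality) in self.connectomes


# ---------------------------------------------------------------------------
# ipsilateral / contralateral transform
# ---------------------------------------------------------------------------

def ipsi_contra_permutation(atlas: RegionAtlas, focus_side: str) -> np.ndarray:
    """Row/column permutation placing the focus hemisphere in the left slots.

    Identity for a left-sided focus (the canonical frame keeps ipsilateral
    regions in the left-hemisphere positions); for a right focus each region
    is swapped with its homotopic partner. Bilateral regions are fixed.
    """
    if focus_side == "left":
        return np.arange(atlas.n_regions)
    if focus_side != "right":
        raise CohortError(f"focus_side must be left or right, got {focus_side!r}")
    perm = np.arange(atlas.n_regions)
    pairs = atlas.homotopic_pairs()
    perm[pairs[:, 0]] = pairs[:, 1]
    perm[pairs[:, 1]] = pairs[:, 0]
    return perm


def to_ipsi_contra(connectome: Connectome, focus_side: str,
                   atlas: RegionAtlas) -> Connectome:
    """Re-index a patient connectome into the ipsi/contra canonical frame.

    Involution: applying the transform twice with the same side restores the
    original matrix. Values and the number of missing edges are preserved.
    """
    perm = ipsi_contra_permutation(atlas, focus_side)
    return Connectome(
        connectome.subject_id, connectome.modality,
        connectome.matrix[np.ix_(perm, perm)],
        connectome.missing_mask[np.ix_(perm, perm)],
    )


# ---------------------------------------------------------------------------
# edge vectorisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeIndexMap:
    """Invertible map between upper-triangle edges and vector positions.

    ``row`` / ``col`` hold full-atlas region indices (row < col) in row-major
    upper-triangle order over the selected region subset.
    """

    n_regions: int
    regions: np.ndarray   # region indices included, ascending
    row: np.ndarray
    col: np.ndarray

    def __len__(self) -> int:
        return len(self.row)

    def to_matrix(self, values: np.ndarray,
                  fill: float = 0.0) -> np.ndarray:
        """Scatter an edge vector back into a full symmetric N x N matrix."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.row.shape:
            raise ValueError("edge vector length mismatch")
        m = np.full((self.n_regions, self.n_regions), fill, dtype=float)
        m[self.row, self.col] = values
        m[self.col, self.row] = values
        np.fill_diagonal(m, 0.0)
        return m


def edge_index_map(n_regions: int, regions: np.ndarray | None = None) -> EdgeIndexMap:
    regions = np.arange(n_regions) if regions is None else np.sort(np.asarray(regions))
    k = len(regions)
    iu = np.triu_indices(k, k=1)
    return EdgeIndexMap(n_regions=n_regions, regions=regions,
                        row=regions[iu[0]], col=regions[iu[1]])


def edge_vector(connectome: Connectome, atlas: RegionAtlas | None = None,
                within_hemisphere: str | None = None
                ) -> tuple[np.ndarray, EdgeIndexMap]:
    """Vectorise the upper triangle (i < j, row-major) of a connectome.

    With ``within_hemisphere`` given, the vector is restricted to the regions
    of that hemisphere plus bilateral regions (55 regions, 1485 edges on the
    default atlas); the atlas is then required.
    """
    if within_hemisphere is not None:
        if atlas is None:
            raise ValueError("atlas required for a within-hemisphere restriction")
        regions = atlas.hemisphere_block(within_hemisphere)
    else:
        regions = None
    emap = edge_index_map(connectome.n_regions, regions)
    return connectome.matrix[emap.row, emap.col], emap


# ---------------------------------------------------------------------------
# default atlas
# ---------------------------------------------------------------------------

_DMN = ["medial_prefrontal", "posterior_cingulate", "precuneus",
        "angular_gyrus", "lateral_temporal"]
_ATT = ["intraparietal_sulcus", "frontal_eye_field", "anterior_insula",
        "dorsolateral_prefrontal", "supramarginal_gyrus"]
_VIS = ["calcarine", "cuneus", "lingual", "lateral_occipital", "occipital_pole"]
_MOT = ["precentral", "postcentral", "paracentral", "supplementary_motor",
        "central_operculum"]
_OTHER = [
    "hippocampus_anterior", "hippocampus_posterior", "amygdala", "thalamus",
    "caudate", "putamen", "pallidum", "accumbens", "posterior_insula",
    "superior_frontal", "middle_frontal", "inferior_frontal", "orbitofrontal",
    "gyrus_rectus", "anterior_cingulate", "middle_cingulate",
    "parahippocampal", "entorhinal", "temporal_pole", "superior_temporal",
    "middle_temporal", "inferior_temporal", "fusiform", "transverse_temporal",
    "planum_temporale", "planum_polare", "superior_parietal",
    "parietal_operculum", "frontal_operculum", "frontal_pole",
    "subcallosal", "superior_occipital", "middle_occipital", "ventral_dc",
]

assert len(_DMN + _ATT + _VIS + _MOT + _OTHER) == 54


def make_default_atlas() -> RegionAtlas:
    """109-region atlas: 54 homotopic pairs plus the bilateral brainstem.

    Four resting-state networks of five bilateral regions each are labelled
    along the transmodal-to-unimodal gradient (1 = default mode,
    2 = attention, 3 = primary visual, 4 = motor/sensorimotor); the anterior
    hippocampus is flagged in each hemisphere.
    """
    bases = _DMN + _ATT + _VIS + _MOT + _OTHER
    rsn = [1] * 5 + [2] * 5 + [3] * 5 + [4] * 5 + [0] * len(_OTHER)
    rows = []
    for side, suffix in (("left", "_L"), ("right", "_R")):
        for b, label in zip(bases, rsn):
            rows.append((f"{b}{suffix}", side, label, b == "hippocampus_anterior"))
    rows.append(("brainstem", "bilateral", 0, False))
    t = pd.DataFrame(rows, columns=["name", "hemisphere", "rsn_label",
                                    "is_anterior_hippocampus"])
    t.insert(0, "region_id", np.arange(len(t)))
    return RegionAtlas(t)
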