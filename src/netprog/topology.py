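"""Healthy-brain distance models and seed-edge binning.

Four topologies describe "distance" from a seed region (the anterior
hippocampus) in the healthy brain:

* ``LEN`` — control-averaged mean streamline length (shorter = closer);
* ``SC``  — control-averaged structural connectivity (stronger = closer);
* ``FC``  — control-averaged functional connectivity (higher |z| = closer);
* ``RSN`` — membership in four resting-state networks ordered along the
  transmodal-to-unimodal gradient (default mode > attention > primary
  visual > motor/sensorimotor).

Matrix topologies are built within hemisphere (the 54 hemisphere regions
plus the brainstem; cross-hemisphere structural edges are unreliable and
excluded), one matrix per hemisphere. A model vector is a row of the
topology from the seed region; its entries are ranked and chunked into
near-equal contiguous bins of seed edges, bin 1 being the "closest".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Cohort, RegionAtlas

TOPOLOGY_KINDS = ("LEN", "SC", "FC", "RSN")

#: Default number of bins per topology. LEN/FC rank all 54 seed edges into
#: five bins; SC (edges can be absent from the control average) and the
#: four-network RSN model use four.
DEFAULT_N_BINS = {"LEN": 5, "FC": 5, "SC": 4, "RSN": 4}


def contiguous_bin_sizes(n_edges: int, n_bins: int) -> list[int]:
    """Near-equal contiguous chunk sizes; earlier bins take the remainder.

    54 edges in 5 bins -> (11, 11, 11, 11, 10).
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if n_bins > n_edges:
        raise ValueError(f"cannot split {n_edges} edges into {n_bins} bins")
    base, extra = divmod(n_edges, n_bins)
    return [base + 1 if b < extra else base for b in range(n_bins)]


@dataclass
class TopologyModel:
    """A healthy-brain distance structure.

    For matrix kinds, ``matrices[side]`` is the control-averaged
    within-hemisphere matrix over ``regions[side]`` (hemisphere block plus
    brainstem); entries that are missing in every control are NaN. For the
    RSN kind only ``membership`` is set (one label 0-4 per atlas region).
    """

    kind: str
    atlas: RegionAtlas
    matrices: dict[str, np.ndarray] | None = None
    regions: dict[str, np.ndarray] | None = None
    membership: np.ndarray | None = None
    control_ids: tuple[str, ...] = ()


def build_topology(controls: Cohort, kind: str) -> TopologyModel:
    """Average the designated connectome over all controls, per hemisphere.

    The mean at each edge runs over the controls in which the edge is
    present; an edge present in no control is NaN in the topology.
    """
    if kind not in TOPOLOGY_KINDS:
        raise ValueError(f"unknown topology kind {kind!r}")
    atlas = controls.atlas
    if kind == "RSN":
        labels = atlas.rsn_labels()
        if not (labels > 0).any():
            raise ValueError("atlas carries no resting-state network labels")
        return TopologyModel(kind=kind, atlas=atlas, membership=labels)

    ctrl = controls.controls()
    if len(ctrl) < 2:
        raise ValueError("need at least 2 controls to build a topology")
    matrices, regions = {}, {}
    for side in ("left", "right"):
        block = atlas.hemisphere_block(side)
        total = np.zeros((len(block), len(block)))
        count = np.zeros((len(block), len(block)))
        for s in ctrl:
            c = controls.get(s.subject_id, kind)
            sub = c.matrix[np.ix_(block, block)]
            present = ~c.missing_mask[np.ix_(block, block)]
            total += np.where(present, sub, 0.0)
            count += present
        with np.errstate(invalid="ignore"):
            t = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        np.fill_diagonal(t, 0.0)
        matrices[side] = t
        regions[side] = block
    return TopologyModel(kind=kind, atlas=atlas, matrices=matrices,
                         regions=regions,
                         control_ids=tuple(s.subject_id for s in ctrl))


@dataclass
class ModelVector:
    """Modeled distance from a seed region to each other eligible region."""

    kind: str
    seed: int                 # full-atlas region index
    regions: np.ndarray       # full-atlas indices, seed excluded
    values: np.ndarray        # distances (matrix kinds) or RSN labels

    def __len__(self) -> int:
        return len(self.regions)


def model_vector(model: TopologyModel, seed: int,
                 side: str | None = None) -> ModelVector:
    """Read the seed row of a topology (or the membership vector for RSN)."""
    atlas = model.atlas
    if model.kind == "RSN":
        regions = np.array([r for r in range(atlas.n_regions) if r != seed])
        return ModelVector("RSN", seed, regions,
                           model.membership[regions].astype(float))
    if side is None:
        hemi = atlas.table["hemisphere"].iloc[seed]
        if hemi == "bilateral":
            raise ValueError("side is required for a bilateral seed region")
        side = hemi
    block = model.regions[side]
    pos = np.flatnonzero(block == seed)
    if len(pos) == 0:
        raise ValueError(f"seed region {seed} not in the {side} hemisphere block")
    row = model.matrices[side][pos[0]]
    keep = block != seed
    return ModelVector(model.kind, seed, block[keep], row[keep])


@dataclass
class EdgeBinning:
    """Ordered partition of seed edges into distance-ranked bins.

    Each seed edge is identified by the non-seed region; ``bins[0]`` is the
    "closest" bin under the ranking rule of the topology.
    """

    kind: str
    seed: int
    bins: list[np.ndarray]    # region indices per bin
    rule: str

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def all_regions(self) -> np.ndarray:
        return np.concatenate(self.bins)


def bin_edges(v: ModelVector, n_bins: int | None = None) -> EdgeBinning:
    """Partition the seed edges of a model vector into ranked bins.

    LEN ranks ascending (shortest first); FC descending by absolute value;
    SC descending, after excluding edges absent from the control-average
    topology; RSN bins are the four network classes in gradient order.
    Ranking ties are broken by region index (stable sort).
    """
    if n_bins is None:
        n_bins = DEFAULT_N_BINS[v.kind]
    if v.kind == "RSN":
        if n_bins != 4:
            raise ValueError("the RSN model defines exactly 4 bins")
        labels = v.values.astype(int)
        bins = [v.regions[labels == b] for b in range(1, 5)]
        if any(len(b) == 0 for b in bins):
            raise ValueError("an RSN class has no member regions")
        return EdgeBinning("RSN", v.seed, bins, rule="network gradient 1-4")
    eligible = np.isfinite(v.values)
    regions = v.regions[eligible]
    values = v.values[eligible]
    if n_bins > len(regions):
        raise ValueError(f"n_bins={n_bins} exceeds {len(regions)} eligible edges")
    if v.kind == "LEN":
        key, rule = values, "ascending length"
    elif v.kind == "FC":
        key, rule = -np.abs(values), "descending |z|"
    elif v.kind == "SC":
        key, rule = -values, "descending connectivity"
    else:
        raise ValueError(f"unknown kind {v.kind!r}")
    order = np.argsort(key, kind="stable")
    ranked = regions[order]
    sizes = contiguous_bin_sizes(len(ranked), n_bins)
    bins, start = [], 0
    for s in sizes:
        bins.append(ranked[start:start + s])
        start += s
    return EdgeBinning(v.kind, v.seed, bins, rule=rule)
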