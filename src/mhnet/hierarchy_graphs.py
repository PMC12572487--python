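"""Hierarchical brain-graph construction (whole-brain / cluster / region
levels).

Each subject yields three graphs sharing one hierarchy:

* WAN — nodes are functional networks, one block (every network pair is an
  edge candidate);
* MAN — nodes are clusters, blocks are networks (edges only within a
  network);
* LAN — nodes are atlas regions, blocks are clusters.

Node signals at a level are the column-wise concatenation of the member
regions' voxel matrices, so the RV coefficient applies unchanged at every
level.  Within-block RV matrices are thresholded and assembled
block-diagonally; cross-block entries are structural zeros.  Node features
are the rows of the pre-threshold RV-profile matrix (connectivity
profiles), giving a fixed feature dimension equal to the node count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .connectivity import pearson_fc, rv_coefficient, threshold_adjacency
from .data_model import (
    BrainGraphLevel,
    HierarchyMap,
    MultiViewGraphSet,
    RegionVoxelSignals,
    region_mean_series,
)
from .errors import DataValidationError, DegenerateInputError

__all__ = [
    "LevelSpec",
    "level_specs",
    "pool_node_signals",
    "block_diagonal",
    "build_level",
    "build_multiview",
]


@dataclass
class LevelSpec:
    """Node grouping and block partition for one hierarchy level."""

    level_tag: str
    grouping: dict[str, list[str]]  # node_id -> member region_ids
    blocks: dict[str, str]  # node_id -> block_id

    def __post_init__(self):
        seen: set[str] = set()
        for node, members in self.grouping.items():
            if node not in self.blocks:
                raise DataValidationError(f"node '{node}' has no block assignment")
            for r in members:
                if r in seen:
                    raise DataValidationError(
                        f"region '{r}' assigned to more than one node"
                    )
                seen.add(r)

    @property
    def node_ids(self) -> list[str]:
        return list(self.grouping)

    def block_members(self) -> dict[str, list[str]]:
        """Block id -> ordered node ids (first-appearance order)."""
        out: dict[str, list[str]] = {}
        for node, block in self.blocks.items():
            out.setdefault(block, []).append(node)
        return out


def level_specs(hierarchy: HierarchyMap) -> dict[str, LevelSpec]:
    """The three level specifications induced by a hierarchy map."""
    wan = LevelSpec(
        level_tag="WAN",
        grouping={n: hierarchy.regions_in_network(n) for n in hierarchy.networks},
        blocks={n: "brain" for n in hierarchy.networks},
    )
    man = LevelSpec(
        level_tag="MAN",
        grouping={c: hierarchy.regions_in_cluster(c) for c in hierarchy.clusters},
        blocks={c: hierarchy.network_of_cluster(c) for c in hierarchy.clusters},
    )
    lan = LevelSpec(
        level_tag="LAN",
        grouping={r: [r] for r in hierarchy.regions},
        blocks={r: hierarchy.cluster_of(r) for r in hierarchy.regions},
    )
    return {"WAN": wan, "MAN": man, "LAN": lan}


def pool_node_signals(
    subject: RegionVoxelSignals, spec: LevelSpec
) -> dict[str, np.ndarray]:
    """Column-wise concatenation of member regions' voxel matrices per
    node."""
    pooled: dict[str, np.ndarray] = {}
    for node, members in spec.grouping.items():
        mats = []
        for r in members:
            if r not in subject.region_signals:
                raise DataValidationError(
                    f"region '{r}' (node '{node}') missing from subject "
                    f"'{subject.subject_id}'"
                )
            mats.append(subject.region_signals[r])
        pooled[node] = np.concatenate(mats, axis=1)
    return pooled


def block_diagonal(blocks: list[np.ndarray]) -> np.ndarray:
    """Assemble square blocks along the diagonal; off-block entries 0."""
    arrs = []
    for i, b in enumerate(blocks):
        b = np.asarray(b, dtype=float)
        if b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise DataValidationError(f"block {i} is not square: shape {b.shape}")
        arrs.append(b)
    return scipy.linalg.block_diag(*arrs)


def _rv_profile_matrix(
    pooled: dict[str, np.ndarray], spec: LevelSpec
) -> np.ndarray:
    """Block-structured RV matrix: computed within blocks, structural zeros
    across; unit diagonal."""
    node_ids = spec.node_ids
    index = {n: i for i, n in enumerate(node_ids)}
    R = np.zeros((len(node_ids), len(node_ids)))
    np.fill_diagonal(R, 1.0)
    for block_nodes in spec.block_members().values():
        for a in range(len(block_nodes)):
            for b in range(a + 1, len(block_nodes)):
                ia, ib = index[block_nodes[a]], index[block_nodes[b]]
                try:
                    val = rv_coefficient(
                        pooled[block_nodes[a]], pooled[block_nodes[b]]
                    )
                except DegenerateInputError as exc:
                    raise DegenerateInputError(
                        f"degenerate node '{block_nodes[a]}' or "
                        f"'{block_nodes[b]}' at level {spec.level_tag}: {exc}"
                    ) from exc
                R[ia, ib] = R[ib, ia] = val
    # degenerate singleton blocks still need a defined self-signal
    for node, mat in pooled.items():
        centered = mat - mat.mean(axis=0, keepdims=True)
        if not np.any(centered):
            raise DegenerateInputError(
                f"node '{node}' has an all-constant signal at level "
                f"{spec.level_tag}"
            )
    return R


def build_level(
    subject: RegionVoxelSignals, spec: LevelSpec, gamma: float
) -> BrainGraphLevel:
    """Build one graph level: per-block thresholded RV adjacency assembled
    block-diagonally, RV-profile node features (pre-threshold)."""
    pooled = pool_node_signals(subject, spec)
    R = _rv_profile_matrix(pooled, spec)
    node_ids = spec.node_ids
    index = {n: i for i, n in enumerate(node_ids)}
    adjacency = np.zeros_like(R)
    for block_nodes in spec.block_members().values():
        idx = np.array([index[n] for n in block_nodes])
        sub = R[np.ix_(idx, idx)]
        adjacency[np.ix_(idx, idx)] = threshold_adjacency(sub, gamma)
    return BrainGraphLevel(
        node_ids=node_ids,
        adjacency=adjacency,
        node_features=R,
        level_tag=spec.level_tag,
    )


def build_multiview(
    subject: RegionVoxelSignals,
    hierarchy: HierarchyMap,
    gammas: float | dict[str, float],
) -> MultiViewGraphSet:
    """Build WAN/MAN/LAN graphs plus the Pearson FC matrix for one subject.

    ``gammas`` is a single shared cutoff or a per-level mapping with keys
    WAN/MAN/LAN.
    """
    if not isinstance(gammas, dict):
        gammas = {tag: float(gammas) for tag in ("WAN", "MAN", "LAN")}
    missing = set(hierarchy.regions) - set(subject.region_ids)
    if missing:
        raise DataValidationError(
            f"hierarchy regions missing from subject: {sorted(missing)}"
        )
    specs = level_specs(hierarchy)
    levels = {
        tag: build_level(subject, specs[tag], gammas[tag])
        for tag in ("WAN", "MAN", "LAN")
    }
    # FC over hierarchy-ordered regions
    means = region_mean_series(subject)
    order = [means.region_ids.index(r) for r in hierarchy.regions]
    ordered = type(means)(
        subject_id=means.subject_id,
        series=means.series[:, order],
        region_ids=hierarchy.regions,
    )
    fc = pearson_fc(ordered)
    return MultiViewGraphSet(
        wan=levels["WAN"], man=levels["MAN"], lan=levels["LAN"], fc_matrix=fc
    )
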