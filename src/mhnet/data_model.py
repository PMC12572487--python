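"""Core domain types and text-based readers/writers.

All on-disk formats are plain delimited text (``.csv`` comma, ``.tsv`` tab,
UTF-8, decimal point), chosen so that fixtures are diff-able:

* per-region time series: one numeric table per region (rows = time points,
  columns = voxels) plus a manifest table ``region_id <tab> relative_path``;
* hierarchy map: three columns ``region_id, cluster_id, network_id``;
* matrices: dense tables with node ids as header row and index column;
* graphs: edge-list TSV ``(i, j, weight)`` + node-feature table + JSON
  sidecar recording the level tag and node ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = [
    "RegionVoxelSignals",
    "RegionMeanSeries",
    "HierarchyMap",
    "BrainGraphLevel",
    "MultiViewGraphSet",
    "SubjectCohort",
    "read_region_signals",
    "write_region_signals",
    "read_hierarchy",
    "write_hierarchy",
    "read_matrix",
    "write_matrix",
    "read_graph_level",
    "write_graph_level",
    "region_mean_series",
]

LEVEL_TAGS = ("WAN", "MAN", "LAN")


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def _check_finite(arr: np.ndarray, what: str):
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.asarray(arr)))
        loc = tuple(int(i) for i in bad[0])
        raise DataValidationError(f"non-finite value in {what} at index {loc}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RegionVoxelSignals:
    """One subject's per-region voxel-level BOLD-like signals.

    ``region_signals`` maps region id to a (n_time, n_voxels) matrix; all
    regions share the same number of time points.
    """

    subject_id: str
    region_signals: dict[str, np.ndarray]

    def __post_init__(self):
        if not self.region_signals:
            raise DataValidationError("subject has no regions")
        n_time = None
        for rid, mat in self.region_signals.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] < 1:
                raise DataValidationError(
                    f"region '{rid}' must be a 2-D time x voxel matrix with >= 1 voxel"
                )
            _check_finite(mat, f"region '{rid}' of subject '{self.subject_id}'")
            if n_time is None:
                n_time = mat.shape[0]
            elif mat.shape[0] != n_time:
                raise DataValidationError(
                    f"region '{rid}' has {mat.shape[0]} time points, expected {n_time}"
                )
            self.region_signals[rid] = mat

    @property
    def n_time(self) -> int:
        return next(iter(self.region_signals.values())).shape[0]

    @property
    def region_ids(self) -> list[str]:
        return list(self.region_signals)


@dataclass
class RegionMeanSeries:
    """Region-mean time series: (n_time, n_regions) matrix."""

    subject_id: str
    series: np.ndarray
    region_ids: list[str]

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[1] != len(self.region_ids):
            raise DataValidationError(
                "series column count must equal number of region ids"
            )
        _check_finite(self.series, f"mean series of subject '{self.subject_id}'")

    def zero_variance_regions(self) -> list[str]:
        sd = self.series.std(axis=0)
        return [rid for rid, s in zip(self.region_ids, sd) if s == 0.0]


@dataclass
class HierarchyMap:
    """Region -> (cluster, network) assignments defining the three graph
    levels (whole-brain networks / clusters / regions).

    Node order at every level is first appearance in the table.
    """

    rows: list[tuple[str, str, str]]

    def __post_init__(self):
        seen_regions: dict[str, None] = {}
        cluster_net: dict[str, str] = {}
        networks: dict[str, None] = {}
        clusters: dict[str, None] = {}
        for region, cluster, network in self.rows:
            if region in seen_regions:
                raise DataValidationError(f"duplicate region_id '{region}'")
            seen_regions[region] = None
            if cluster in cluster_net and cluster_net[cluster] != network:
                raise DataValidationError(
                    f"cluster '{cluster}' mapped to two networks "
                    f"('{cluster_net[cluster]}' and '{network}')"
                )
            cluster_net[cluster] = network
            networks[network] = None
            clusters[cluster] = None
        if len(networks) < 2:
            raise DataValidationError("hierarchy needs at least 2 networks")
        self._networks = list(networks)
        self._clusters = list(clusters)
        self._regions = list(seen_regions)
        self._cluster_net = cluster_net
        self._region_cluster = {r: c for r, c, _ in self.rows}

    @property
    def networks(self) -> list[str]:
        return list(self._networks)

    @property
    def clusters(self) -> list[str]:
        return list(self._clusters)

    @property
    def regions(self) -> list[str]:
        return list(self._regions)

    def cluster_of(self, region: str) -> str:
        return self._region_cluster[region]

    def network_of_cluster(self, cluster: str) -> str:
        return self._cluster_net[cluster]

    def network_of(self, region: str) -> str:
        return self._cluster_net[self._region_cluster[region]]

    def regions_in_cluster(self, cluster: str) -> list[str]:
        return [r for r in self._regions if self._region_cluster[r] == cluster]

    def regions_in_network(self, network: str) -> list[str]:
        return [r for r in self._regions if self.network_of(r) == network]

    def clusters_in_network(self, network: str) -> list[str]:
        return [c for c in self._clusters if self._cluster_net[c] == network]


@dataclass
class BrainGraphLevel:
    """One level of the hierarchical brain graph: symmetric sparse-by-
    construction adjacency (unit diagonal) plus connectivity-profile node
    features."""

    node_ids: list[str]
    adjacency: np.ndarray
    node_features: np.ndarray
    level_tag: str

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.node_features = np.asarray(self.node_features, dtype=float)
        n = len(self.node_ids)
        if self.level_tag not in LEVEL_TAGS:
            raise DataValidationError(f"unknown level tag '{self.level_tag}'")
        if self.adjacency.shape != (n, n):
            raise DataValidationError("adjacency shape does not match node count")
        if not np.allclose(self.adjacency, self.adjacency.T):
            raise DataValidationError("adjacency must be symmetric")
        if not np.allclose(np.diag(self.adjacency), 1.0):
            raise DataValidationError("adjacency must have unit diagonal")
        if self.node_features.shape[0] != n:
            raise DataValidationError("node_features row count must equal node count")
        _check_finite(self.adjacency, f"{self.level_tag} adjacency")
        _check_finite(self.node_features, f"{self.level_tag} node features")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


@dataclass
class MultiViewGraphSet:
    """Per-subject multi-view input: the three hierarchy levels plus the
    region-level Pearson FC matrix."""

    wan: BrainGraphLevel
    man: BrainGraphLevel
    lan: BrainGraphLevel
    fc_matrix: np.ndarray

    def __post_init__(self):
        self.fc_matrix = np.asarray(self.fc_matrix, dtype=float)
        n = self.fc_matrix.shape[0]
        if self.fc_matrix.shape != (n, n):
            raise DataValidationError("fc_matrix must be square")
        if self.lan.n_nodes != n:
            raise DataValidationError(
                "LAN node count must equal FC matrix dimension"
            )


@dataclass
class SubjectCohort:
    """Labeled subject collection; the unit consumed by training, CV and the
    population graph.  Labels are binary with the disorder as class 1."""

    subjects: list[tuple[MultiViewGraphSet, int]]
    phenotypes: pd.DataFrame | None = None
    label_names: tuple[str, str] = ("control", "patient")
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        for _, label in self.subjects:
            if label not in (0, 1):
                raise DataValidationError("labels must be binary 0/1")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:04d}" for i in range(len(self.subjects))]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.subjects], dtype=int)

    def __len__(self) -> int:
        return len(self.subjects)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path: Path, sep: str) -> np.ndarray:
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=float,
                         float_precision="round_trip")
    except ValueError:
        # locate the first offending cell for the error message
        raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    float(raw.iat[i, j])
                except (TypeError, ValueError):
                    raise DataValidationError(
                        f"non-numeric cell at row {i}, column {j} of {path}"
                    ) from None
        raise
    return df.to_numpy(dtype=float)


def read_region_signals(
    directory_path: str | Path,
    manifest: pd.DataFrame | str | Path,
    subject_id: str | None = None,
) -> RegionVoxelSignals:
    """Load one subject's per-region voxel tables listed in a manifest.

    The manifest has columns ``region_id`` and ``relative_path``; region
    order follows manifest order.
    """
    directory_path = Path(directory_path)
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        manifest = pd.read_csv(mpath, sep=_sep_for(mpath))
    if not {"region_id", "relative_path"} <= set(manifest.columns):
        raise DataValidationError(
            "manifest must have columns 'region_id' and 'relative_path'"
        )
    signals: dict[str, np.ndarray] = {}
    n_time = None
    for _, row in manifest.iterrows():
        rid = str(row["region_id"])
        fpath = directory_path / str(row["relative_path"])
        mat = _read_numeric_table(fpath, _sep_for(fpath))
        if n_time is None:
            n_time = mat.shape[0]
        elif mat.shape[0] != n_time:
            raise DataValidationError(
                f"region '{rid}' has {mat.shape[0]} time points, expected {n_time}"
            )
        signals[rid] = mat
    if subject_id is None:
        subject_id = directory_path.name
    return RegionVoxelSignals(subject_id=subject_id, region_signals=signals)


def write_region_signals(
    signals: RegionVoxelSignals, directory_path: str | Path, fmt: str = "tsv"
) -> Path:
    """Write one table per region plus a manifest; inverse of
    :func:`read_region_signals`."""
    directory_path = Path(directory_path)
    directory_path.mkdir(parents=True, exist_ok=True)
    sep = "," if fmt == "csv" else "\t"
    rows = []
    for rid, mat in signals.region_signals.items():
        fname = f"{rid}.{fmt}"
        np.savetxt(directory_path / fname, mat, delimiter=sep, fmt="%.17g")
        rows.append({"region_id": rid, "relative_path": fname})
    manifest = pd.DataFrame(rows)
    mpath = directory_path / "manifest.tsv"
    manifest.to_csv(mpath, sep="\t", index=False)
    return mpath


def read_hierarchy(path: str | Path) -> HierarchyMap:
    """Read a 3-column delimited hierarchy table
    (``region_id, cluster_id, network_id``)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ["region_id", "cluster_id", "network_id"]
    if list(df.columns[:3]) != required:
        raise DataValidationError(
            f"hierarchy table must have header {required}, got {list(df.columns)}"
        )
    rows = [
        (str(r), str(c), str(n))
        for r, c, n in df[required].itertuples(index=False, name=None)
    ]
    return HierarchyMap(rows=rows)


def write_hierarchy(hierarchy: HierarchyMap, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        hierarchy.rows, columns=["region_id", "cluster_id", "network_id"]
    )
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Dense delimited matrix with node ids as header row and index column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    ids = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    _check_finite(mat, str(path))
    return mat, ids


def write_matrix(mat: np.ndarray, ids: list[str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(mat, index=ids, columns=ids).to_csv(
        path, sep=_sep_for(path), float_format="%.17g"
    )
    return path


def write_graph_level(level: BrainGraphLevel, directory: str | Path) -> None:
    """Serialize one graph level: edge list + node features + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = level.level_tag.lower()
    iu = np.triu_indices(level.n_nodes, k=1)
    mask = level.adjacency[iu] != 0.0
    edges = pd.DataFrame(
        {
            "i": iu[0][mask],
            "j": iu[1][mask],
            "weight": level.adjacency[iu][mask],
        }
    )
    edges.to_csv(directory / f"{tag}_edges.tsv", sep="\t", index=False,
                 float_format="%.17g")
    np.savetxt(
        directory / f"{tag}_features.tsv", level.node_features, delimiter="\t",
        fmt="%.17g"
    )
    sidecar = {"level_tag": level.level_tag, "node_ids": level.node_ids}
    (directory / f"{tag}_meta.json").write_text(json.dumps(sidecar, indent=1))


def read_graph_level(directory: str | Path, level_tag: str) -> BrainGraphLevel:
    directory = Path(directory)
    tag = level_tag.lower()
    meta = json.loads((directory / f"{tag}_meta.json").read_text())
    node_ids = [str(i) for i in meta["node_ids"]]
    n = len(node_ids)
    adjacency = np.eye(n)
    edges = pd.read_csv(directory / f"{tag}_edges.tsv", sep="\t")
    for i, j, w in edges.itertuples(index=False, name=None):
        adjacency[int(i), int(j)] = w
        adjacency[int(j), int(i)] = w
    features = np.loadtxt(directory / f"{tag}_features.tsv", delimiter="\t", ndmin=2)
    return BrainGraphLevel(
        node_ids=node_ids,
        adjacency=adjacency,
        node_features=features,
        level_tag=meta["level_tag"],
    )


def region_mean_series(signals: RegionVoxelSignals) -> RegionMeanSeries:
    """Reduce voxel matrices to the per-time-point mean over voxels — the
    standard ROI signal."""
    series = np.column_stack(
        [mat.mean(axis=1) for mat in signals.region_signals.values()]
    )
    return RegionMeanSeries(
        subject_id=signals.subject_id,
        series=series,
        region_ids=signals.region_ids,
    )
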