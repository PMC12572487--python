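"""Synthetic cohort generator: hierarchically correlated voxel signals with
planted group differences in inter-network coupling.

Signals follow a latent Gaussian factor cascade, i.i.d. over time points:

* network factors drawn jointly with baseline correlation ρ_x (planted
  network pairs get ρ_x + δ for class 1);
* cluster factor  = √ρ_n · f_network + √(1−ρ_n) · ξ;
* region factor   = √ρ_c · f_cluster + √(1−ρ_c) · ξ;
* voxel signal    = √ρ_r · f_region  + √(1−ρ_r) · noise_sd · ε.

With noise_sd = 1 the implied correlations have closed forms: voxels in one
region correlate at ρ_r, across regions of a cluster at ρ_r·ρ_c, across
clusters of a network at ρ_r·ρ_c·ρ_n, across networks at ρ_r·ρ_c·ρ_n·ρ_x
(plus δ on planted pairs).  A self-pair effect ("netX", "netX") instead
raises the within-cluster region coupling ρ_c by δ for class 1 in that
network's clusters only, confining the group difference to that network's
regions (and keeping it visible at the region level, where graph blocks
are clusters).

An optional AR(1) temporal option adds autocorrelation for realism; it
defaults off (i.i.d. time points are sufficient to exercise every
operator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import retained_edge_curve, select_cutoff
from .data_model import HierarchyMap, RegionVoxelSignals, SubjectCohort
from .errors import ConfigError, NoKneeError
from .hierarchy_graphs import build_multiview, level_specs, pool_node_signals
from .hierarchy_graphs import _rv_profile_matrix

__all__ = [
    "SimConfig",
    "generate_hierarchy",
    "generate_subject",
    "generate_signal_cohort",
    "generate_cohort",
    "mean_lan_rv",
]


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults: 60 subjects per class; 4 networks x 2 clusters x 3 regions x
    20 voxels; 150 time points; correlation cascade ρ_r=0.8 > ρ_c=0.6 >
    ρ_n=0.4 > ρ_x=0.1; a +0.4 coupling shift between net1 and net2 for
    class 1.
    """

    n_subjects_per_class: int = 60
    n_networks: int = 4
    clusters_per_network: int = 2
    regions_per_cluster: int = 3
    voxels_per_region: int = 20
    n_time: int = 150
    rho_r: float = 0.8
    rho_c: float = 0.6
    rho_n: float = 0.4
    rho_x: float = 0.1
    effect: list[tuple[tuple[str, str], float]] = field(
        default_factory=lambda: [(("net1", "net2"), 0.4)]
    )
    noise_sd: float = 1.0
    ar1: float = 0.0  # temporal autocorrelation of latent factors/noise
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho_x < self.rho_n < self.rho_c < self.rho_r <= 1.0):
            raise ConfigError("require 0 <= rho_x < rho_n < rho_c < rho_r <= 1")
        if min(self.n_networks, self.clusters_per_network,
               self.regions_per_cluster, self.voxels_per_region) < 1:
            raise ConfigError("all hierarchy dims must be >= 1")
        if not 0.0 <= self.ar1 < 1.0:
            raise ConfigError("ar1 must be in [0, 1)")
        nets = [f"net{i + 1}" for i in range(self.n_networks)]
        for (a, b), delta in self.effect:
            if a not in nets or b not in nets:
                raise ConfigError(f"effect names unknown network: ({a}, {b})")
            if a != b and not 0.0 <= self.rho_x + delta <= 1.0:
                raise ConfigError(
                    f"planted coupling rho_x + {delta} outside [0, 1]"
                )
            if a == b and not 0.0 <= self.rho_c + delta <= 1.0:
                raise ConfigError(
                    f"planted within-cluster coupling rho_c + {delta} outside [0, 1]"
                )
        # network-factor correlation matrices must be PSD for both classes
        for label in (0, 1):
            sigma = self._network_corr(label)
            if np.linalg.eigvalsh(sigma)[0] < -1e-10:
                raise ConfigError(
                    "infeasible correlation cascade: network correlation "
                    "matrix not positive semi-definite"
                )

    @property
    def network_names(self) -> list[str]:
        return [f"net{i + 1}" for i in range(self.n_networks)]

    def _network_corr(self, class_label: int) -> np.ndarray:
        n = self.n_networks
        sigma = np.full((n, n), self.rho_x)
        np.fill_diagonal(sigma, 1.0)
        if class_label == 1:
            names = self.network_names
            for (a, b), delta in self.effect:
                if a == b:
                    continue
                ia, ib = names.index(a), names.index(b)
                sigma[ia, ib] = sigma[ib, ia] = self.rho_x + delta
        return sigma

    def _rho_c_for(self, network: str, class_label: int) -> float:
        rho = self.rho_c
        if class_label == 1:
            for (a, b), delta in self.effect:
                if a == b == network:
                    rho = min(self.rho_c + delta, 1.0)
        return rho


def generate_hierarchy(config: SimConfig) -> HierarchyMap:
    """Deterministic naming: net1, net1.c1, net1.c1.r1, ..."""
    rows = []
    for i in range(config.n_networks):
        net = f"net{i + 1}"
        for j in range(config.clusters_per_network):
            cluster = f"{net}.c{j + 1}"
            for k in range(config.regions_per_cluster):
                rows.append((f"{cluster}.r{k + 1}", cluster, net))
    return HierarchyMap(rows=rows)


def _draw(rng: np.random.Generator, config: SimConfig, shape) -> np.ndarray:
    """Standard-normal draws, optionally AR(1) over the time axis (axis 0)
    with stationary unit variance."""
    x = rng.standard_normal(shape)
    phi = config.ar1
    if phi > 0:
        scale = np.sqrt(1 - phi**2)
        for t in range(1, shape[0]):
            x[t] = phi * x[t - 1] + scale * x[t]
    return x


def generate_subject(
    config: SimConfig, class_label: int, rng: np.random.Generator,
    subject_id: str = "sub",
) -> RegionVoxelSignals:
    """One subject's voxel signals from the latent factor cascade."""
    T = config.n_time
    sigma = config._network_corr(class_label)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(config.n_networks))
    f_net = _draw(rng, config, (T, config.n_networks)) @ chol.T
    signals: dict[str, np.ndarray] = {}
    for i, net in enumerate(config.network_names):
        rho_c = config._rho_c_for(net, class_label)
        for j in range(config.clusters_per_network):
            f_cluster = np.sqrt(config.rho_n) * f_net[:, i] + np.sqrt(
                1 - config.rho_n
            ) * _draw(rng, config, (T,))
            for k in range(config.regions_per_cluster):
                f_region = np.sqrt(rho_c) * f_cluster + np.sqrt(
                    1 - rho_c
                ) * _draw(rng, config, (T,))
                noise = config.noise_sd * _draw(
                    rng, config, (T, config.voxels_per_region)
                )
                voxels = (
                    np.sqrt(config.rho_r) * f_region[:, None]
                    + np.sqrt(1 - config.rho_r) * noise
                )
                signals[f"{net}.c{j + 1}.r{k + 1}"] = voxels
    return RegionVoxelSignals(subject_id=subject_id, region_signals=signals)


def generate_signal_cohort(
    config: SimConfig,
) -> tuple[list[RegionVoxelSignals], np.ndarray, pd.DataFrame]:
    """Balanced labeled signal-level cohort with phenotypes (sex ~
    Bernoulli(0.5), age ~ Uniform(8, 20) years, 3 sites)."""
    if config.n_subjects_per_class < 2:
        raise ConfigError("need at least 2 subjects per class")
    rng = np.random.default_rng(config.seed)
    subjects, labels = [], []
    idx = 0
    for label in (0, 1):
        for _ in range(config.n_subjects_per_class):
            subjects.append(
                generate_subject(config, label, rng, subject_id=f"sub{idx:04d}")
            )
            labels.append(label)
            idx += 1
    labels = np.array(labels, dtype=int)
    m = len(labels)
    phenotypes = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": rng.choice(["M", "F"], size=m),
            "age": rng.uniform(8.0, 20.0, size=m),
            "site": rng.choice(["siteA", "siteB", "siteC"], size=m),
        }
    )
    return subjects, labels, phenotypes


def mean_lan_rv(
    signal_subjects: list[RegionVoxelSignals], hierarchy: HierarchyMap
) -> np.ndarray:
    """Region-level RV-profile matrix averaged over subjects (used for
    cutoff selection)."""
    spec = level_specs(hierarchy)["LAN"]
    mats = []
    for subject in signal_subjects:
        pooled = pool_node_signals(subject, spec)
        mats.append(_rv_profile_matrix(pooled, spec))
    return np.mean(mats, axis=0)


def generate_cohort(
    config: SimConfig, gamma: float | None = None
) -> tuple[SubjectCohort, HierarchyMap]:
    """Full cohort of multi-view graph sets.

    One shared cutoff is used for all levels; when ``gamma`` is None it is
    knee-selected on the cohort-mean LAN RV matrix (falling back to 0.1 if
    the curve has no knee).
    """
    hierarchy = generate_hierarchy(config)
    subjects, labels, phenotypes = generate_signal_cohort(config)
    if gamma is None:
        mean_rv = mean_lan_rv(subjects, hierarchy)
        try:
            gamma = select_cutoff(retained_edge_curve(mean_rv))
        except NoKneeError:
            gamma = 0.1
    views = [build_multiview(s, hierarchy, gamma) for s in subjects]
    cohort = SubjectCohort(
        subjects=list(zip(views, (int(x) for x in labels))),
        phenotypes=phenotypes,
        label_names=("control", "patient"),
        subject_ids=[s.subject_id for s in subjects],
    )
    return cohort, hierarchy
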