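"""Fusion classifier, loss, training loop, cross-validation harness,
metrics, ablation variants and node-saliency ranking.

The full model concatenates the non-Euclidean branch output (three fused
level embeddings, 6*d_h) with the Euclidean branch output (2*d) and
classifies with an MLP + softmax head, trained with binary cross-entropy
and Adam.  The ablation lattice (graph branch with/without GHOP and all
three levels vs. LAN only; CNN branch with/without HOP; their
combinations) is expressed purely as configuration switches.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .autodiff import Tensor, concat
from .data_model import HierarchyMap, SubjectCohort
from .errors import ConfigError, DataValidationError, MHNetError
from .esfe import ESFEBranch, upper_tri_vector
from .hgnn import HGNNBranch, scaled_laplacian
from .nn import MLP, Adam, Module

__all__ = [
    "ModelConfig",
    "MetricsReport",
    "MHNet",
    "CohortTensors",
    "tensorize_cohort",
    "ffc_forward",
    "cross_entropy",
    "train",
    "TrainResult",
    "predict",
    "evaluate",
    "cross_validate",
    "CVReport",
    "node_saliency",
    "paired_permutation_test",
    "VARIANTS",
]

ALL_LEVELS = ("WAN", "MAN", "LAN")

#: Ablation lattice: (graph levels, use_ghop, use_esfe, use_hop)
VARIANTS: dict[str, dict] = {
    "gnn_lan": dict(levels=("LAN",), use_ghop=False, use_esfe=False, use_hop=False),
    "gnn": dict(levels=ALL_LEVELS, use_ghop=False, use_esfe=False, use_hop=False),
    "cnn": dict(levels=(), use_ghop=False, use_esfe=True, use_hop=False),
    "hgnn": dict(levels=ALL_LEVELS, use_ghop=True, use_esfe=False, use_hop=False),
    "hcnn": dict(levels=(), use_ghop=False, use_esfe=True, use_hop=True),
    "hcnn+gnn": dict(levels=ALL_LEVELS, use_ghop=False, use_esfe=True, use_hop=True),
    "hgnn+cnn": dict(levels=ALL_LEVELS, use_ghop=True, use_esfe=True, use_hop=False),
    "hgnn+hcnn": dict(levels=ALL_LEVELS, use_ghop=True, use_esfe=True, use_hop=True),
}


@dataclass
class ModelConfig:
    """Hyper-parameters of the two branches and the fusion head.

    Defaults follow the reference setting: Chebyshev order K=3, three
    ChebConv blocks, dropout 0.3, learning rate 1e-4, Adam.
    """

    d_h: int = 64
    d: int = 64
    K: int = 3
    n_blocks: int = 3
    dropout: float = 0.3
    learning_rate: float = 1e-4
    max_epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    gamma: float | None = None  # None -> knee-selected during graph building
    levels: tuple[str, ...] = ALL_LEVELS
    use_ghop: bool = True
    use_esfe: bool = True
    use_hop: bool = True
    hop_mode: str = "outer"
    residual: bool = True
    head_hidden: tuple[int, int] = (128, 32)

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.K < 1 or self.n_blocks < 1:
            raise ConfigError("K and n_blocks must be >= 1")
        if not self.levels and not self.use_esfe:
            raise ConfigError("model needs at least one branch")

    @classmethod
    def for_variant(cls, name: str, **overrides) -> "ModelConfig":
        if name not in VARIANTS:
            raise ConfigError(
                f"unknown variant '{name}'; known: {sorted(VARIANTS)}"
            )
        return cls(**{**VARIANTS[name], **overrides})


@dataclass
class MetricsReport:
    """ACC/SEN/SPEC from the 0.5-threshold confusion matrix (positive class
    = patient), rank-based AUC, and their arithmetic mean."""

    acc: float
    sen: float
    spec: float
    auc: float
    avg: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spec": self.spec,
            "auc": self.auc,
            "avg": self.avg,
        }


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MHNet(Module):
    """Multi-view high-order network: graph branch + CNN branch + fusion
    head, any subset enabled per the ablation config."""

    def __init__(
        self,
        level_dims: dict[str, int],
        n_regions: int,
        config: ModelConfig,
        rng: np.random.Generator,
    ):
        super().__init__()
        self.config = config
        self._level_dims = dict(level_dims)
        self._n_regions = n_regions
        self.hgnn = None
        self.esfe = None
        in_dim = 0
        if config.levels:
            self.hgnn = HGNNBranch(
                level_dims,
                config.d_h,
                config.K,
                config.n_blocks,
                config.dropout,
                rng,
                levels=config.levels,
                use_ghop=config.use_ghop,
                residual=config.residual,
            )
            per_level = 2 * config.d_h if config.use_ghop else config.d_h
            in_dim += per_level * len(config.levels)
        if config.use_esfe:
            self.esfe = ESFEBranch(
                n_regions,
                rng,
                d=config.d,
                dropout=config.dropout,
                use_hop=config.use_hop,
                hop_mode=config.hop_mode,
            )
            in_dim += 2 * config.d if config.use_hop else config.d
        self.head = MLP(
            [in_dim, *config.head_hidden, 2], rng, dropout=config.dropout
        )

    def features(self, batch: "BatchTensors") -> Tensor:
        parts = []
        if self.hgnn is not None:
            parts.append(self.hgnn(batch.levels))
        if self.esfe is not None:
            parts.append(self.esfe(batch.fc))
        return concat(parts, axis=-1) if len(parts) > 1 else parts[0]

    def logits(self, batch: "BatchTensors") -> Tensor:
        return self.head(self.features(batch))

    def __call__(self, batch: "BatchTensors") -> Tensor:
        return self.logits(batch).softmax(axis=-1)


def ffc_forward(z_ghop, z_hop, head: MLP) -> Tensor:
    """Fusion head on the two branch outputs: softmax(MLP(concat))."""
    z_ghop = z_ghop if isinstance(z_ghop, Tensor) else Tensor(z_ghop)
    z_hop = z_hop if isinstance(z_hop, Tensor) else Tensor(z_hop)
    for name, z in (("z_ghop", z_ghop), ("z_hop", z_hop)):
        if not np.all(np.isfinite(z.data)):
            raise MHNetError(f"non-finite activations in {name}")
    probs = head(concat([z_ghop, z_hop], axis=-1)).softmax(axis=-1)
    if not np.all(np.isfinite(probs.data)):
        raise MHNetError("non-finite activations in fusion head")
    return probs


def cross_entropy(y, p, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy −mean[y log p + (1−y) log(1−p)] with p clamped
    to [eps, 1−eps]; ``p`` is the predicted patient-class probability."""
    y = np.asarray(y, dtype=float)
    p = p if isinstance(p, Tensor) else Tensor(p)
    if y.shape != p.shape:
        raise DataValidationError(f"shape mismatch: y {y.shape} vs p {p.shape}")
    clamped = Tensor(np.clip(p.data, eps, 1 - eps))
    clamped.requires_grad = p.requires_grad
    clamped._parents = (p,)

    def backward(g, out):  # straight-through clamp
        p._accum(g)

    clamped._backward = backward
    loss = -(
        Tensor(y) * clamped.log() + Tensor(1.0 - y) * (1.0 - clamped).log()
    ).mean()
    return loss


def _logit_cross_entropy(y: np.ndarray, logits: Tensor) -> Tensor:
    """Cross-entropy from the two-class logits via log-softmax; identical
    in value to :func:`cross_entropy` on the softmax probabilities but
    stable (and informative in gradient) under saturation."""
    y_onehot = np.eye(2)[np.asarray(y, dtype=int)]
    shifted = logits - np.max(logits.data, axis=-1, keepdims=True)
    log_probs = shifted - shifted.exp().sum(axis=-1, keepdims=True).log()
    return -(Tensor(y_onehot) * log_probs).sum(axis=-1).mean()


# ---------------------------------------------------------------------------
# cohort tensorization
# ---------------------------------------------------------------------------


@dataclass
class BatchTensors:
    levels: dict[str, tuple[Tensor, np.ndarray]]
    fc: Tensor


@dataclass
class CohortTensors:
    """Stacked per-subject inputs: node features and rescaled Laplacians per
    level, FC upper-triangle vectors, labels."""

    level_feats: dict[str, np.ndarray]  # (B, n, d_in)
    level_laps: dict[str, np.ndarray]  # (B, n, n)
    fc_vecs: np.ndarray  # (B, k)
    labels: np.ndarray  # (B,)
    level_dims: dict[str, int] = field(default_factory=dict)
    n_regions: int = 0

    def batch(self, idx: np.ndarray) -> BatchTensors:
        levels = {
            tag: (Tensor(self.level_feats[tag][idx]), self.level_laps[tag][idx])
            for tag in self.level_feats
        }
        return BatchTensors(levels=levels, fc=Tensor(self.fc_vecs[idx]))

    def __len__(self) -> int:
        return len(self.labels)


def tensorize_cohort(cohort: SubjectCohort) -> CohortTensors:
    feats: dict[str, list] = {tag: [] for tag in ALL_LEVELS}
    laps: dict[str, list] = {tag: [] for tag in ALL_LEVELS}
    fcs = []
    for views, _ in cohort.subjects:
        for tag, level in (("WAN", views.wan), ("MAN", views.man), ("LAN", views.lan)):
            feats[tag].append(level.node_features)
            laps[tag].append(scaled_laplacian(level.adjacency).L_tilde)
        fcs.append(upper_tri_vector(views.fc_matrix))
    level_feats = {t: np.stack(v) for t, v in feats.items()}
    return CohortTensors(
        level_feats=level_feats,
        level_laps={t: np.stack(v) for t, v in laps.items()},
        fc_vecs=np.stack(fcs),
        labels=cohort.labels,
        level_dims={t: level_feats[t].shape[2] for t in level_feats},
        n_regions=cohort.subjects[0][0].fc_matrix.shape[0],
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: MHNet
    loss_trace: list[float]
    val_trace: list[float]
    best_epoch: int


def _snapshot(model: MHNet) -> list[np.ndarray]:
    return [a.copy() for a in model.state_arrays()]


def _restore(model: MHNet, snap: list[np.ndarray]):
    for a, s in zip(model.state_arrays(), snap):
        a[...] = s


def train(
    tensors: CohortTensors | SubjectCohort,
    config: ModelConfig,
    train_idx: np.ndarray | None = None,
    val_idx: np.ndarray | None = None,
) -> TrainResult:
    """Adam training with per-epoch loss trace; if a validation split is
    given the returned model is the checkpoint with lowest validation
    loss."""
    if isinstance(tensors, SubjectCohort):
        tensors = tensorize_cohort(tensors)
    if train_idx is None:
        train_idx = np.arange(len(tensors))
    train_idx = np.asarray(train_idx)
    y_train = tensors.labels[train_idx]
    if len(np.unique(y_train)) < 2:
        raise DataValidationError("both classes required in the training split")
    rng = np.random.default_rng(config.seed)
    model = MHNet(tensors.level_dims, tensors.n_regions, config, rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    loss_trace: list[float] = []
    val_trace: list[float] = []
    best_val = np.inf
    best_epoch = -1
    best_snap = _snapshot(model)
    for epoch in range(config.max_epochs):
        model.train()
        perm = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss = _logit_cross_entropy(
                tensors.labels[idx], model.logits(tensors.batch(idx))
            )
            if not np.isfinite(loss.data):
                raise MHNetError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        loss_trace.append(epoch_loss / len(perm))
        if val_idx is not None and len(val_idx) > 0:
            model.eval()
            vloss = float(
                _logit_cross_entropy(
                    tensors.labels[val_idx],
                    model.logits(tensors.batch(np.asarray(val_idx))),
                ).data
            )
            val_trace.append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_epoch = epoch
                best_snap = _snapshot(model)
    if val_idx is not None and best_epoch >= 0:
        _restore(model, best_snap)
    else:
        best_epoch = config.max_epochs - 1
    model.eval()
    return TrainResult(
        model=model, loss_trace=loss_trace, val_trace=val_trace,
        best_epoch=best_epoch,
    )


def predict(
    model: MHNet, tensors: CohortTensors, idx: np.ndarray | None = None
) -> np.ndarray:
    """Patient-class probabilities in eval mode."""
    if idx is None:
        idx = np.arange(len(tensors))
    model.eval()
    return model(tensors.batch(np.asarray(idx))).data[:, 1]


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(preds: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Confusion-matrix metrics at threshold 0.5 plus rank-based AUC."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise DataValidationError("preds and labels must align")
    hard = (preds > 0.5).astype(int)
    pos = labels == 1
    neg = labels == 0
    undefined = []
    acc = float(np.mean(hard == labels))
    if pos.any():
        sen = float(np.mean(hard[pos] == 1))
    else:
        sen, undefined = np.nan, undefined + ["sen"]
    if neg.any():
        spec = float(np.mean(hard[neg] == 0))
    else:
        spec, undefined = np.nan, undefined + ["spec"]
    if pos.any() and neg.any():
        auc = float(roc_auc_score(labels, preds))
    else:
        auc, undefined = np.nan, undefined + ["auc"]
    avg = float(np.mean([acc, sen, spec, auc]))
    return MetricsReport(
        acc=acc, sen=sen, spec=spec, auc=auc, avg=avg,
        undefined=tuple(undefined),
    )


def stratified_split(
    labels: np.ndarray, seed: int, fractions=(0.7, 0.1, 0.2)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/validation/test split (default 70/10/20)."""
    idx = np.arange(len(labels))
    f_train, f_val, f_test = fractions
    n = len(labels)
    n_test = int(round(f_test * n))
    n_val = int(round(f_val * n))
    trainval, test = train_test_split(
        idx, test_size=n_test, stratify=labels, random_state=seed
    )
    train_, val = train_test_split(
        trainval,
        test_size=n_val,
        stratify=labels[trainval],
        random_state=seed + 1,
    )
    return np.sort(train_), np.sort(val), np.sort(test)


@dataclass
class CVReport:
    per_fold: list[MetricsReport]
    mean: dict[str, float]
    std: dict[str, float]


def cross_validate(
    cohort: SubjectCohort | CohortTensors,
    config: ModelConfig,
    n_repeats: int = 10,
) -> CVReport:
    """Repeated stratified random 70/10/20 splits; the validation split
    drives checkpoint selection; metrics aggregated as mean ± std over
    repeats."""
    tensors = (
        tensorize_cohort(cohort) if isinstance(cohort, SubjectCohort) else cohort
    )
    if len(tensors) < 20:
        raise DataValidationError("cross-validation needs at least 20 subjects")
    reports = []
    for rep in range(n_repeats):
        tr, va, te = stratified_split(tensors.labels, seed=config.seed * 1000 + rep)
        result = train(tensors, replace(config, seed=config.seed * 1000 + rep),
                       train_idx=tr, val_idx=va)
        reports.append(evaluate(predict(result.model, tensors, te),
                                tensors.labels[te]))
    keys = ["acc", "sen", "spec", "auc", "avg"]
    table = {k: np.array([r.as_dict()[k] for r in reports]) for k in keys}
    return CVReport(
        per_fold=reports,
        mean={k: float(np.nanmean(v)) for k, v in table.items()},
        std={k: float(np.nanstd(v)) for k, v in table.items()},
    )


# ---------------------------------------------------------------------------
# interpretability & statistics
# ---------------------------------------------------------------------------


def node_saliency(
    model: MHNet,
    tensors: CohortTensors,
    hierarchy: HierarchyMap,
    idx: np.ndarray | None = None,
    top_k: int = 10,
) -> tuple[list[str], np.ndarray]:
    """Region saliency ranking.

    Graph side: mean over subjects of |d logit_patient / d LAN-feature| x
    |feature| per LAN node.  CNN side: first-conv activation magnitude
    attributed back through the receptive field to FC-vector positions and
    thence to the two regions of each FC entry.  The two scores are min-max
    normalized and averaged; returns (ranked region ids, full score
    vector in hierarchy region order).
    """
    if idx is None:
        idx = np.arange(len(tensors))
    idx = np.asarray(idx)
    model.eval()
    n_regions = len(hierarchy.regions)
    scores = []
    if model.hgnn is not None and "LAN" in model.config.levels:
        levels = {
            tag: (Tensor(tensors.level_feats[tag][idx]), tensors.level_laps[tag][idx])
            for tag in ALL_LEVELS
        }
        lan_feat = levels["LAN"][0]
        lan_feat.requires_grad = True
        batch = BatchTensors(levels=levels, fc=Tensor(tensors.fc_vecs[idx]))
        logits = model.logits(batch)
        logits[:, 1].sum().backward()
        sal = np.abs(lan_feat.grad * lan_feat.data).mean(axis=(0, 2))
        scores.append(sal)
    if model.esfe is not None:
        model(tensors.batch(idx))
        act = np.abs(model.esfe._last_conv1_activation).mean(axis=(0, 1))
        stride = model.esfe.conv1.stride
        kernel = model.esfe.conv1.weight.shape[2]
        k = tensors.fc_vecs.shape[1]
        pos_weight = np.zeros(k)
        for p, a in enumerate(act):
            pos_weight[p * stride : p * stride + kernel] += a
        region_score = np.zeros(n_regions)
        iu = np.triu_indices(n_regions, k=1)
        np.add.at(region_score, iu[0], pos_weight)
        np.add.at(region_score, iu[1], pos_weight)
        scores.append(region_score)
    if not scores:
        raise MHNetError("model has no branch to derive saliency from")

    def norm(v):
        rng_ = np.ptp(v)
        return (v - v.min()) / rng_ if rng_ > 0 else np.zeros_like(v)

    combined = np.mean([norm(s) for s in scores], axis=0)
    order = np.argsort(-combined, kind="stable")
    ranked = [hierarchy.regions[i] for i in order[:top_k]]
    return ranked, combined


def save_model(model: MHNet, path) -> None:
    """Serialize parameters, buffers and config to an .npz checkpoint."""
    import dataclasses
    import json

    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "config": dataclasses.asdict(model.config),
        "level_dims": getattr(model, "_level_dims", {}),
        "n_regions": getattr(model, "_n_regions", 0),
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> MHNet:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"a{i}"] for i in range(len(data.files) - 1)]
    cfg = meta["config"]
    for key in ("levels", "head_hidden"):
        cfg[key] = tuple(cfg[key])
    config = ModelConfig(**cfg)
    rng = np.random.default_rng(config.seed)
    model = MHNet(
        {k: int(v) for k, v in meta["level_dims"].items()},
        int(meta["n_regions"]), config, rng,
    )
    for target, source in zip(model.state_arrays(), arrays):
        target[...] = source
    model.eval()
    return model


def paired_permutation_test(
    x: np.ndarray, y: np.ndarray, n_samples: int = 100_000, seed: int = 0
) -> float:
    """One-sided paired sign-flip permutation test of mean(x − y) > 0.

    Exact enumeration up to 20 pairs, Monte Carlo beyond.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n == 0:
        raise DataValidationError("no pairs")
    observed = d.mean()
    if n <= 20:
        count = 0
        total = 2**n
        for signs in itertools.product((1.0, -1.0), repeat=n):
            if np.mean(d * signs) >= observed - 1e-15:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_samples, n))
    stats = (signs * d).mean(axis=1)
    return float((np.sum(stats >= observed - 1e-15) + 1) / (n_samples + 1))
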