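"""Population-graph extension: subject-level graph from model embeddings
plus phenotypes, with transductive semi-supervised node classification.

Nodes are subjects.  An embedding-similarity kernel
M1 = exp(−ρ²/(2σ²)) with ρ the correlation distance between embeddings and
σ the mean squared distance, is combined elementwise with a phenotype
agreement score M2 (sex match, site match, age within a window).  The
binarized support C = 1{M1∘M2 ≥ mean} is weighted by a cosine similarity
W of a shared-weight MLP encoding of the phenotype vectors, giving
A' = C ∘ W.  A one-layer symmetric-normalized graph convolution over A'
followed by an MLP classifies every subject from the labeled subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .errors import ConfigError, DataValidationError, DegenerateInputError
from .nn import MLP, Adam, Linear, Module

__all__ = [
    "PopulationGraphConfig",
    "PopulationGraph",
    "embedding_similarity",
    "encode_phenotypes",
    "phenotype_weight",
    "phenotype_match",
    "build_population_graph",
    "population_classify",
]


@dataclass
class PopulationGraphConfig:
    age_window: float = 2.0  # years
    phenotype_hidden: int = 16
    phenotype_out: int = 8
    gcn_hidden: int = 32
    mlp_hidden: int = 16
    learning_rate: float = 1e-2
    max_epochs: int = 200
    seed: int = 0
    use_phenotypes: bool = True  # False degrades to embedding similarity only


@dataclass
class PopulationGraph:
    M1: np.ndarray
    M2: np.ndarray
    C_prime: np.ndarray
    C: np.ndarray
    W: np.ndarray
    A_prime: np.ndarray
    Y: np.ndarray
    eta: np.ndarray


def embedding_similarity(Y: np.ndarray) -> np.ndarray:
    """Gaussian kernel on squared correlation distances between embedding
    rows; sigma is the mean squared distance over subject pairs."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise DataValidationError("need a (subjects x features) matrix, m >= 2")
    sd = Y.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        raise DegenerateInputError(f"constant embedding for subject {bad}")
    rho = 1.0 - np.corrcoef(Y)
    np.fill_diagonal(rho, 0.0)
    iu = np.triu_indices(Y.shape[0], k=1)
    sigma = float(np.mean(rho[iu] ** 2))
    if sigma == 0:
        sigma = 1.0  # all embeddings identical: kernel is all-ones anyway
    M1 = np.exp(-(rho**2) / (2 * sigma**2))
    return 0.5 * (M1 + M1.T)


def encode_phenotypes(phenotypes: pd.DataFrame) -> np.ndarray:
    """One-hot categorical channels (sex, site) + z-scored age."""
    cols = []
    if "sex" in phenotypes:
        cols.append(pd.get_dummies(phenotypes["sex"], prefix="sex").to_numpy(float))
    if "site" in phenotypes:
        cols.append(pd.get_dummies(phenotypes["site"], prefix="site").to_numpy(float))
    if "age" in phenotypes:
        age = phenotypes["age"].to_numpy(float)
        sd = age.std()
        cols.append(((age - age.mean()) / sd if sd > 0 else age * 0.0)[:, None])
    if not cols:
        raise DataValidationError("no usable phenotype channels")
    return np.column_stack(cols)


def phenotype_weight(eta_i: np.ndarray, eta_j: np.ndarray, mlp: MLP) -> float:
    """W_ij = (cos(MLP(η_i), MLP(η_j)) + 1)/2 with a shared-weight MLP;
    zero-norm outputs fall back to 0.5 (orthogonality convention)."""
    out = mlp(Tensor(np.stack([eta_i, eta_j]))).data
    ni, nj = np.linalg.norm(out[0]), np.linalg.norm(out[1])
    if ni == 0 or nj == 0:
        warnings.warn("zero-norm phenotype MLP output; using W=0.5")
        return 0.5
    cos = float(out[0] @ out[1] / (ni * nj))
    return (np.clip(cos, -1.0, 1.0) + 1.0) / 2.0


def phenotype_match(
    phenotypes: pd.DataFrame, age_window: float = 2.0
) -> np.ndarray:
    """M2(i,j): mean of indicator channels — sex match, site match,
    |age_i − age_j| <= age_window."""
    m = len(phenotypes)
    channels = []
    for col in ("sex", "site"):
        if col in phenotypes:
            v = phenotypes[col].to_numpy()
            channels.append((v[:, None] == v[None, :]).astype(float))
    if "age" in phenotypes:
        a = phenotypes["age"].to_numpy(float)
        channels.append((np.abs(a[:, None] - a[None, :]) <= age_window).astype(float))
    if not channels:
        return np.ones((m, m))
    return np.mean(channels, axis=0)


def _phenotype_mlp(eta_dim: int, config: PopulationGraphConfig) -> MLP:
    rng = np.random.default_rng(config.seed + 7)
    return MLP([eta_dim, config.phenotype_hidden, config.phenotype_out], rng)


def build_population_graph(
    Y: np.ndarray,
    phenotypes: pd.DataFrame | None,
    config: PopulationGraphConfig | None = None,
) -> PopulationGraph:
    """Assemble M1, M2, C' = M1∘M2, C = 1{C' >= mean off-diagonal},
    W (phenotype MLP cosine) and A' = C ∘ W; self-edges weight 1."""
    config = config or PopulationGraphConfig()
    Y = np.asarray(Y, dtype=float)
    m = Y.shape[0]
    M1 = embedding_similarity(Y)
    if phenotypes is not None and config.use_phenotypes:
        missing = [c for c in ("sex", "age", "site") if c not in phenotypes]
        if missing:
            warnings.warn(f"phenotype channel(s) skipped: {missing}")
        M2 = phenotype_match(phenotypes, config.age_window)
        eta = encode_phenotypes(phenotypes)
        mlp = _phenotype_mlp(eta.shape[1], config)
        out = mlp(Tensor(eta)).data
        norms = np.linalg.norm(out, axis=1)
        safe = np.where(norms == 0, 1.0, norms)
        unit = out / safe[:, None]
        cos = np.clip(unit @ unit.T, -1.0, 1.0)
        W = (cos + 1.0) / 2.0
        W[norms == 0, :] = 0.5
        W[:, norms == 0] = 0.5
    else:
        M2 = np.ones((m, m))
        eta = np.zeros((m, 0))
        W = np.ones((m, m))
    C_prime = M1 * M2
    iu = np.triu_indices(m, k=1)
    thresh = float(C_prime[iu].mean())
    C = (C_prime >= thresh).astype(float)
    np.fill_diagonal(C, 1.0)
    A_prime = C * W
    np.fill_diagonal(A_prime, 1.0)
    return PopulationGraph(
        M1=M1, M2=M2, C_prime=C_prime, C=C, W=W, A_prime=A_prime, Y=Y, eta=eta
    )


class _PopulationGCN(Module):
    """One first-order graph convolution with symmetric normalization,
    ReLU, then an MLP classifier."""

    def __init__(self, d_in: int, config: PopulationGraphConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.gc = Linear(d_in, config.gcn_hidden, rng)
        self.mlp = MLP([config.gcn_hidden, config.mlp_hidden, 2], rng)

    def __call__(self, S: np.ndarray, Y: Tensor) -> Tensor:
        return self.mlp((Tensor(S) @ self.gc(Y)).relu())


def population_classify(
    graph: PopulationGraph,
    labels: np.ndarray,
    train_idx: np.ndarray,
    config: PopulationGraphConfig | None = None,
) -> np.ndarray:
    """Transductive node classification: train GCN+MLP on the labeled
    subset, return patient-class probabilities for every subject."""
    config = config or PopulationGraphConfig()
    labels = np.asarray(labels, dtype=int)
    train_idx = np.asarray(train_idx)
    if len(np.unique(labels[train_idx])) < 2:
        raise ConfigError("need at least one labeled subject per class")
    A = graph.A_prime
    deg = A.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    S = d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    rng = np.random.default_rng(config.seed)
    model = _PopulationGCN(graph.Y.shape[1], config, rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    Yt = Tensor(graph.Y)
    y_onehot = np.eye(2)[labels[train_idx]]
    for _ in range(config.max_epochs):
        logits = model(S, Yt)[train_idx]
        shifted = logits - np.max(logits.data, axis=-1, keepdims=True)
        log_probs = shifted - shifted.exp().sum(axis=-1, keepdims=True).log()
        loss = -(Tensor(y_onehot) * log_probs).sum(axis=1).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    model.eval()
    return model(S, Yt).softmax(axis=-1).data[:, 1]
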