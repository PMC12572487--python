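"""Non-Euclidean branch: residual Chebyshev graph convolutions, adaptive
feature maps (AFM), graph high-order pooling (GHOP) and per-level fusion.

The spectral convolution of node features H on a graph with rescaled
Laplacian L̃ is the K-order Chebyshev expansion

    sum_{k=0}^{K-1} T_k(L̃) H θ_k,   T_0 = I, T_1 = L̃,
    T_k = 2 L̃ T_{k-1} − T_{k-2},

a polynomial approximation of filtering in the Laplacian eigenbasis.  Each
ChebConv block applies convolution, batch norm, ReLU and dropout, with a
residual connection guarding against over-smoothing.  AFM combines block
outputs with softmax-distributed learned weights.  GHOP forms the Gram
matrix ZᵀZ of node embeddings — second-order statistics of the learned
representation — whose upper triangle feeds an MLP; the level embedding is
the concatenation of a mean-over-nodes readout with that high-order term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .data_model import BrainGraphLevel, MultiViewGraphSet
from .errors import DataValidationError
from .nn import MLP, BatchNorm, Dropout, Linear, Module, glorot_uniform

__all__ = [
    "GraphLaplacian",
    "scaled_laplacian",
    "cheb_conv",
    "ChebBlock",
    "afm_aggregate",
    "ghop",
    "upper_tri_flatten",
    "LevelNet",
    "LevelEmbedding",
    "HGNNBranch",
    "level_forward",
    "hgnn_forward",
]


@dataclass
class GraphLaplacian:
    """Symmetric normalized Laplacian and its [-1, 1]-rescaled form."""

    L: np.ndarray
    L_tilde: np.ndarray
    lambda_max: float


def scaled_laplacian(A: np.ndarray) -> GraphLaplacian:
    """L = I − D^{−1/2} A D^{−1/2} with degree from row sums (self-loops
    included); L̃ = 2L/λ_max − I with λ_max computed per graph."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataValidationError("adjacency must be square")
    if not np.allclose(A, A.T):
        raise DataValidationError("adjacency must be symmetric")
    deg = A.sum(axis=1)
    if np.any(deg <= 0):
        raise DataValidationError("non-positive degree (unit diagonal required)")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(A.shape[0]) - (d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :])
    L = 0.5 * (L + L.T)
    try:
        lambda_max = float(np.linalg.eigvalsh(L)[-1])
    except np.linalg.LinAlgError:  # pragma: no cover - eigensolver fallback
        lambda_max = 2.0
    if lambda_max <= 0:
        # edgeless graph: L = 0, any rescaling works; use the spectral bound
        lambda_max = 2.0
    L_tilde = 2.0 * L / lambda_max - np.eye(A.shape[0])
    return GraphLaplacian(L=L, L_tilde=L_tilde, lambda_max=lambda_max)


def cheb_conv(H, lap, thetas: list[Tensor], K: int | None = None) -> Tensor:
    """K-order Chebyshev spectral convolution.

    ``H`` is (n, d_in) or batched (B, n, d_in); ``lap`` a
    :class:`GraphLaplacian` or an (optionally batched) rescaled-Laplacian
    array aligned with H.
    """
    if K is None:
        K = len(thetas)
    if K < 1 or K > len(thetas):
        raise DataValidationError(f"K={K} incompatible with {len(thetas)} thetas")
    L = lap.L_tilde if isinstance(lap, GraphLaplacian) else np.asarray(lap)
    Lt = Tensor(L)
    H = H if isinstance(H, Tensor) else Tensor(H)
    if H.shape[-1] != thetas[0].shape[0]:
        raise DataValidationError(
            f"feature dim {H.shape[-1]} does not match theta rows "
            f"{thetas[0].shape[0]}"
        )
    t_prev = H
    out = t_prev @ thetas[0]
    if K >= 2:
        t_cur = Lt @ H
        out = out + t_cur @ thetas[1]
        for k in range(2, K):
            t_next = (Lt @ t_cur) * 2.0 - t_prev
            out = out + t_next @ thetas[k]
            t_prev, t_cur = t_cur, t_next
    return out


class ChebBlock(Module):
    """ChebConv -> BatchNorm -> ReLU -> Dropout, plus a residual connection
    (identity when dimensions match, learned projection otherwise)."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        K: int,
        dropout: float,
        rng: np.random.Generator,
        residual: bool = True,
    ):
        super().__init__()
        self.K = K
        self.thetas = [
            Tensor(glorot_uniform(rng, d_in, d_out), requires_grad=True)
            for _ in range(K)
        ]
        self.bn = BatchNorm(d_out)
        self.drop = Dropout(dropout, rng)
        self.residual = residual
        self.proj = Linear(d_in, d_out, rng) if (residual and d_in != d_out) else None

    def __call__(self, H: Tensor, lap) -> Tensor:
        out = self.drop(self.bn(cheb_conv(H, lap, self.thetas, self.K)).relu())
        if not self.residual:
            return out
        skip = self.proj(H) if self.proj is not None else H
        return out + skip


def afm_aggregate(H_list: list[Tensor], r: Tensor) -> Tensor:
    """Softmax-weighted sum of block outputs: s = softmax(r),
    Z = sum_l s_l H_l."""
    shapes = {tuple(h.shape) for h in H_list}
    if len(shapes) != 1:
        raise DataValidationError(f"AFM inputs must share a shape, got {shapes}")
    if r.shape != (len(H_list),):
        raise DataValidationError("one AFM logit per block required")
    s = r.softmax()
    out = H_list[0] * s[0]
    for l in range(1, len(H_list)):
        out = out + H_list[l] * s[l]
    return out


def ghop(Z: Tensor | np.ndarray) -> Tensor:
    """Graph high-order pooling: Gram matrix ZᵀZ (symmetric PSD)."""
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    return Z.swapaxes(-1, -2) @ Z


def upper_tri_flatten(T: Tensor, include_diag: bool = True) -> Tensor:
    """Row-major upper-triangle flattening of a (possibly batched) square
    matrix."""
    d = T.shape[-1]
    iu = np.triu_indices(d, k=0 if include_diag else 1)
    if T.ndim == 2:
        return T[(iu[0], iu[1])]
    if T.ndim == 3:
        return T[(slice(None), iu[0], iu[1])]
    raise DataValidationError("expected a 2-D or 3-D (batched) matrix")


def second_order_normalize(v: Tensor, eps: float = 1e-8) -> Tensor:
    """Signed square root followed by L2 normalization, the standard
    conditioning for flattened second-order (Gram/bilinear) features: keeps
    the input to the downstream MLP O(1) regardless of node count and
    embedding width."""
    absv = v.relu() + (-v).relu()
    signed_sqrt = v / (absv + eps) ** 0.5
    norm = ((signed_sqrt**2).sum(axis=-1, keepdims=True) + eps).sqrt()
    return signed_sqrt / norm


@dataclass
class LevelEmbedding:
    """Intermediate and fused outputs for one graph level."""

    Z: Tensor
    readout: Tensor
    ghop: Tensor | None
    fused: Tensor


class LevelNet(Module):
    """Per-level network: n_blocks residual ChebConv blocks, AFM
    aggregation, mean readout, and GHOP + MLP high-order term.

    Output ``fused`` has length 2*d_h with GHOP enabled, d_h without.
    """

    def __init__(
        self,
        d_in: int,
        d_h: int,
        K: int,
        n_blocks: int,
        dropout: float,
        rng: np.random.Generator,
        use_ghop: bool = True,
        residual: bool = True,
    ):
        super().__init__()
        dims = [d_in] + [d_h] * n_blocks
        self.blocks = [
            ChebBlock(dims[i], dims[i + 1], K, dropout, rng, residual=residual)
            for i in range(n_blocks)
        ]
        self.afm_logits = Tensor(
            rng.normal(0.0, 0.01, size=n_blocks), requires_grad=True
        )
        self.use_ghop = use_ghop
        if use_ghop:
            tri = d_h * (d_h + 1) // 2
            self.ghop_mlp = MLP([tri, d_h, d_h], rng)
        self.d_h = d_h

    def __call__(self, H, lap) -> LevelEmbedding:
        H = H if isinstance(H, Tensor) else Tensor(H)
        outs = []
        cur = H
        for block in self.blocks:
            cur = block(cur, lap)
            outs.append(cur)
        Z = afm_aggregate(outs, self.afm_logits)
        readout = Z.mean(axis=-2)
        if not self.use_ghop:
            return LevelEmbedding(Z=Z, readout=readout, ghop=None, fused=readout)
        G = ghop(Z)
        high = self.ghop_mlp(
            second_order_normalize(upper_tri_flatten(G, include_diag=True))
        )
        fused = concat([readout, high], axis=-1)
        return LevelEmbedding(Z=Z, readout=readout, ghop=G, fused=fused)


class HGNNBranch(Module):
    """Three parallel level networks (separate parameters per level); the
    branch output concatenates the fused level vectors."""

    def __init__(
        self,
        level_dims: dict[str, int],
        d_h: int,
        K: int,
        n_blocks: int,
        dropout: float,
        rng: np.random.Generator,
        levels: tuple[str, ...] = ("WAN", "MAN", "LAN"),
        use_ghop: bool = True,
        residual: bool = True,
    ):
        super().__init__()
        self.levels = levels
        self.nets = {
            tag: LevelNet(
                level_dims[tag], d_h, K, n_blocks, dropout, rng,
                use_ghop=use_ghop, residual=residual,
            )
            for tag in levels
        }

    def __call__(self, inputs: dict[str, tuple]) -> Tensor:
        fused = [self.nets[tag](*inputs[tag]).fused for tag in self.levels]
        return concat(fused, axis=-1)


# -- functional wrappers over single (unbatched) graph objects ---------------


def level_forward(level: BrainGraphLevel, net: LevelNet) -> LevelEmbedding:
    lap = scaled_laplacian(level.adjacency)
    return net(Tensor(level.node_features), lap.L_tilde)


def hgnn_forward(views: MultiViewGraphSet, branch: HGNNBranch) -> Tensor:
    inputs = {}
    for tag in branch.levels:
        level = {"WAN": views.wan, "MAN": views.man, "LAN": views.lan}[tag]
        lap = scaled_laplacian(level.adjacency)
        inputs[tag] = (Tensor(level.node_features), lap.L_tilde)
    return branch(inputs)
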