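"""Euclidean branch: FC vectorization, 1D-CNN stack, MLP, and high-order
pooling (HOP).

The strict upper triangle of the N x N Pearson FC matrix is flattened in
row-major order to a vector of length N(N−1)/2 (the diagonal is constant 1
and carries no information), passed through two valid-padding 1-D
convolution layers with ReLU and an MLP to the first-order feature vector
Z_fc in R^d.  HOP forms the outer product Z_fc Z_fcᵀ — pairwise
multiplicative interactions between feature dimensions — whose upper
triangle feeds a second MLP; the branch output concatenates Z_fc with that
high-order term (length 2d).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .errors import DataValidationError
from .hgnn import ghop, second_order_normalize, upper_tri_flatten
from .nn import MLP, Conv1dLayer, Module

__all__ = [
    "upper_tri_vector",
    "hop",
    "ESFEBranch",
    "esfe_forward",
]


def upper_tri_vector(C: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Row-major strict-upper-triangle flattening of a symmetric matrix:
    (C12, ..., C1N, C23, ..., C_{N−1,N})."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataValidationError("C must be square")
    if np.max(np.abs(C - C.T)) > tol:
        raise DataValidationError("C is asymmetric beyond tolerance")
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]


def hop(z) -> Tensor:
    """High-order pooling of a feature vector: outer product z zᵀ
    (symmetric, PSD, rank <= 1).  Batched input (B, d) gives (B, d, d)."""
    z = z if isinstance(z, Tensor) else Tensor(z)
    if z.ndim == 1:
        col = z.reshape(-1, 1)
        return col @ col.swapaxes(-1, -2)
    if z.ndim == 2:
        col = z.reshape(z.shape[0], z.shape[1], 1)
        return col @ col.swapaxes(-1, -2)
    raise DataValidationError("hop expects a vector or a batch of vectors")


class ESFEBranch(Module):
    """Two 1-D convolution layers -> MLP -> Z_fc, plus the HOP high-order
    path.  Defaults: conv1 8 channels/kernel 7/stride 2, conv2 16
    channels/kernel 5/stride 2, d = 64."""

    def __init__(
        self,
        n_regions: int,
        rng: np.random.Generator,
        d: int = 64,
        channels: tuple[int, int] = (8, 16),
        kernels: tuple[int, int] = (7, 5),
        strides: tuple[int, int] = (2, 2),
        mlp_hidden: int = 128,
        dropout: float = 0.0,
        use_hop: bool = True,
        hop_mode: str = "outer",
    ):
        super().__init__()
        if hop_mode not in ("outer", "channel_gram"):
            raise DataValidationError(f"unknown hop_mode '{hop_mode}'")
        self.n_regions = n_regions
        k = n_regions * (n_regions - 1) // 2
        self.conv1 = Conv1dLayer(1, channels[0], kernels[0], strides[0], rng)
        self.conv2 = Conv1dLayer(channels[0], channels[1], kernels[1], strides[1], rng)
        l1 = (k - kernels[0]) // strides[0] + 1
        l2 = (l1 - kernels[1]) // strides[1] + 1
        if l2 < 1:
            raise DataValidationError(
                f"FC vector of length {k} too short for the conv stack"
            )
        self.flat_dim = channels[1] * l2
        self.conv_out_len = l2
        self.mlp = MLP([self.flat_dim, mlp_hidden, d], rng, dropout=dropout)
        self.use_hop = use_hop
        self.hop_mode = hop_mode
        self.d = d
        if use_hop:
            if hop_mode == "outer":
                tri = d * (d + 1) // 2
            else:
                tri = channels[1] * (channels[1] + 1) // 2
            self.hop_mlp = MLP([tri, d, d], rng, dropout=dropout)
        self._last_conv1_activation: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        """``x``: (B, k) batch of FC upper-triangle vectors."""
        if x.ndim != 2:
            raise DataValidationError("expected a (batch, k) input")
        h = x.reshape(x.shape[0], 1, x.shape[1])
        a1 = self.conv1(h).relu()
        self._last_conv1_activation = a1.data
        a2 = self.conv2(a1).relu()
        z_fc = self.mlp(a2.reshape(a2.shape[0], self.flat_dim))
        if not self.use_hop:
            return z_fc
        if self.hop_mode == "outer":
            high_in = upper_tri_flatten(hop(z_fc), include_diag=True)
        else:
            # Gram matrix over conv-channel feature maps
            high_in = upper_tri_flatten(ghop(a2.swapaxes(-1, -2)), include_diag=True)
        return concat(
            [z_fc, self.hop_mlp(second_order_normalize(high_in))], axis=-1
        )


def esfe_forward(C: np.ndarray, branch: ESFEBranch) -> Tensor:
    """Single-subject wrapper: FC matrix -> branch output vector."""
    if C.shape[0] != branch.n_regions:
        raise DataValidationError(
            f"FC matrix is {C.shape[0]}x{C.shape[0]}, branch configured for "
            f"{branch.n_regions} regions"
        )
    vec = upper_tri_vector(C)
    out = branch(Tensor(vec[None, :]))
    return out.reshape(out.shape[-1])
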