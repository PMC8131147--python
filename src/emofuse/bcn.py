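"""Bilinear convolution network (BCN) feature extractor.

The BCN consumes an M x N feature matrix (M keypoints, each with an
N-dimensional gradient-orientation descriptor) and applies, in order:

1. a *left* multichannel projection layer, O_t = sum_j h_tj . I_j, which
   learns linear combinations of keypoints (rows);
2. a *right* projection layer, O_t = sum_j I_j . h_tj, which re-projects
   and reduces the descriptor (column) space;
3. a multichannel 1-D convolution along the descriptor direction of each
   row, max-pooled over positions and passed through
   F = tanh(b_c + Q);
4. flattening and two fully connected layers, optionally followed by a
   softmax classification head.

For facial expressions the input rows are landmark descriptors supplied
by the caller; for EEG the rows are descriptors computed on a fixed grid
of keypoints over each band's scalp image (see
:func:`build_feature_matrix`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import glorot, zeros_param


# --------------------------------------------------------------------------
# SIFT-style descriptors on a fixed keypoint grid
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorConfig:
    """Gradient-orientation histogram layout (SIFT-style).

    The default 4x4 spatial subcells x 8 orientation bins gives the
    classic 128-dimensional descriptor.
    """

    grid: int = 5          # keypoints per image side (M = grid^2)
    support: int = 8       # descriptor window side, pixels
    subcells: int = 4      # spatial bins per side
    orientations: int = 8  # orientation bins
    normalize: bool = True  # L2-normalise each descriptor row

    @property
    def n_keypoints(self) -> int:
        return self.grid**2

    @property
    def n_dims(self) -> int:
        return self.subcells**2 * self.orientations


def grid_keypoints(height: int, width: int, cfg: DescriptorConfig) -> np.ndarray:
    """(M, 2) integer (row, col) keypoint centres on a regular grid."""
    half = cfg.support // 2
    rows = np.linspace(half, height - half - 1, cfg.grid).round().astype(int)
    cols = np.linspace(half, width - half - 1, cfg.grid).round().astype(int)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def build_feature_matrix(
    images: np.ndarray,
    cfg: DescriptorConfig = DescriptorConfig(),
    keypoints: np.ndarray | None = None,
) -> np.ndarray:
    """Gradient-orientation histogram descriptors at fixed keypoints.

    ``images``: (..., H, W) -> (..., M, N) with M = len(keypoints) and
    N = subcells^2 * orientations.  Each descriptor accumulates gradient
    magnitude into (spatial subcell, orientation bin) histograms over the
    keypoint's support window and is L2-normalised (all-zero windows stay
    zero).  Deterministic; vectorised over leading axes.
    """
    images = np.asarray(images, dtype=float)
    H, W = images.shape[-2:]
    if keypoints is None:
        keypoints = grid_keypoints(H, W, cfg)
    keypoints = np.asarray(keypoints, dtype=int)
    half = cfg.support // 2
    if (
        (keypoints[:, 0] - half < 0).any()
        or (keypoints[:, 0] + half > H).any()
        or (keypoints[:, 1] - half < 0).any()
        or (keypoints[:, 1] + half > W).any()
    ):
        raise ValueError("keypoint support window outside image bounds")

    lead = images.shape[:-2]
    flat = images.reshape(-1, H, W)
    B = flat.shape[0]
    gy, gx = np.gradient(flat, axis=(-2, -1))
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % (2 * np.pi)
    obin = np.minimum((ang / (2 * np.pi) * cfg.orientations).astype(int),
                      cfg.orientations - 1)

    # per-keypoint window pixel coordinates and spatial subcell ids
    off = np.arange(cfg.support) - half
    wr, wc = np.meshgrid(off, off, indexing="ij")
    rows = keypoints[:, 0][:, None] + wr.ravel()[None, :]  # (M, s^2)
    cols = keypoints[:, 1][:, None] + wc.ravel()[None, :]
    cell_side = cfg.support // cfg.subcells
    sub = (wr.ravel() + half) // cell_side * cfg.subcells + (wc.ravel() + half) // cell_side

    M, P = rows.shape
    mag_w = mag[:, rows, cols]      # (B, M, P)
    bin_w = obin[:, rows, cols]     # (B, M, P)
    idx = (
        np.arange(B)[:, None, None] * (M * cfg.n_dims)
        + np.arange(M)[None, :, None] * cfg.n_dims
        + sub[None, None, :] * cfg.orientations
        + bin_w
    )
    hist = np.bincount(idx.ravel(), weights=mag_w.ravel(),
                       minlength=B * M * cfg.n_dims)
    desc = hist.reshape(B, M, cfg.n_dims)
    if cfg.normalize:
        norm = np.linalg.norm(desc, axis=-1, keepdims=True)
        desc = np.divide(desc, norm, out=np.zeros_like(desc), where=norm > 1e-12)
    return desc.reshape(lead + (M, cfg.n_dims))


# --------------------------------------------------------------------------
# BCN layers
# --------------------------------------------------------------------------

def left_project(inputs: Tensor, params: Tensor) -> Tensor:
    """O_t = sum_j h_tj . I_j over input channels.

    ``inputs``: (..., C_l, M, N); ``params``: (N_l, C_l, M', M)
    -> (..., N_l, M', N).
    """
    if inputs.shape[-3] != params.shape[1]:
        raise ValueError(
            f"channel mismatch: input C={inputs.shape[-3]}, params C={params.shape[1]}"
        )
    if inputs.shape[-2] != params.shape[-1]:
        raise ValueError(
            f"row mismatch: input M={inputs.shape[-2]}, params M={params.shape[-1]}"
        )
    x = inputs.reshape(inputs.shape[:-3] + (1,) + inputs.shape[-3:])
    out = params @ x  # (..., N_l, C_l, M', N)
    return out.sum(axis=-3)


def right_project(inputs: Tensor, params: Tensor) -> Tensor:
    """O_t = sum_j I_j . h_tj over input channels.

    ``inputs``: (..., C_r, M', N); ``params``: (N_r, C_r, N, N')
    -> (..., N_r, M', N').  N' < N reduces the descriptor dimension.
    """
    if inputs.shape[-3] != params.shape[1]:
        raise ValueError(
            f"channel mismatch: input C={inputs.shape[-3]}, params C={params.shape[1]}"
        )
    if inputs.shape[-1] != params.shape[-2]:
        raise ValueError(
            f"column mismatch: input N={inputs.shape[-1]}, params N={params.shape[-2]}"
        )
    x = inputs.reshape(inputs.shape[:-3] + (1,) + inputs.shape[-3:])
    out = x @ params  # (..., N_r, C_r, M', N')
    return out.sum(axis=-3)


def conv1d_pool_activate(
    features: Tensor, filters: Tensor, bias: Tensor, pool_size: int
) -> Tensor:
    """1-D convolution along each row, non-overlapping max pool, tanh.

    ``features``: (B, C_in, M, N); ``filters``: (C_out, C_in, K);
    ``bias``: (C_out,).  Returns F = tanh(b_c + Q) of shape
    (B, C_out, M, floor((N-K+1)/pool_size)).
    """
    B, Cin, M, N = features.shape
    Cout, _, K = filters.shape
    resp_len = N - K + 1
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if pool_size > resp_len:
        raise ValueError(f"pool window {pool_size} exceeds response length {resp_len}")
    x = features.swapaxes(-3, -2).reshape(B * M, Cin, N)
    q = ad.conv1d(x, filters)  # (B*M, C_out, resp_len)
    n_win = resp_len // pool_size
    q = q[:, :, : n_win * pool_size].reshape(B * M, Cout, n_win, pool_size)
    q = q.max(axis=-1)
    f = ad.tanh(bias.reshape(1, Cout, 1) + q)
    return f.reshape(B, M, Cout, n_win).swapaxes(-3, -2)


class BCN:
    """The full feature network; see module docstring for the layer order."""

    def __init__(
        self,
        m: int,
        n: int,
        in_channels: int = 1,
        n_left: int = 4,
        m_out: int | None = None,
        n_right: int = 4,
        n_out: int | None = None,
        conv_channels: int = 4,
        filter_len: int = 5,
        pool_size: int = 2,
        fc_hidden: int = 64,
        feature_dim: int = 32,
        n_classes: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = np.random.default_rng(0) if rng is None else rng
        m_out = m if m_out is None else m_out
        n_out = min(n, 32) if n_out is None else n_out
        self.m, self.n = m, n
        self.pool_size = pool_size
        self.n_classes = n_classes
        resp = n_out - filter_len + 1
        if resp < pool_size:
            raise ValueError("filter/pool configuration leaves no conv response")
        flat_dim = conv_channels * m_out * (resp // pool_size)
        self.params = {
            "left": glorot(rng, (n_left, in_channels, m_out, m)),
            "right": glorot(rng, (n_right, n_left, n, n_out)),
            "conv_w": glorot(rng, (conv_channels, n_right, filter_len)),
            "conv_b": zeros_param((conv_channels,)),
            "fc1_w": glorot(rng, (fc_hidden, flat_dim)),
            "fc1_b": zeros_param((fc_hidden,)),
            "fc2_w": glorot(rng, (feature_dim, fc_hidden)),
            "fc2_b": zeros_param((feature_dim,)),
        }
        if n_classes is not None:
            self.params["head_w"] = glorot(rng, (n_classes, feature_dim))
            self.params["head_b"] = zeros_param((n_classes,))

    def forward(self, matrices, return_posteriors: bool = False):
        """(B, C_in, M, N) feature matrices -> (B, feature_dim) vectors.

        With ``return_posteriors`` (requires a classification head) also
        returns softmax class posteriors.
        """
        x = matrices if isinstance(matrices, Tensor) else Tensor(matrices)
        if x.ndim == 3:  # (B, M, N) single-channel convenience
            x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
        p = self.params
        h = left_project(x, p["left"])
        h = right_project(h, p["right"])
        h = conv1d_pool_activate(h, p["conv_w"], p["conv_b"], self.pool_size)
        h = h.reshape(h.shape[0], -1)
        h = ad.tanh(h @ p["fc1_w"].T + p["fc1_b"])
        feat = h @ p["fc2_w"].T + p["fc2_b"]
        if return_posteriors:
            if self.n_classes is None:
                raise ValueError("BCN built without a classification head")
            logits = feat @ p["head_w"].T + p["head_b"]
            return feat, ad.softmax(logits, axis=-1)
        return feat
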