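"""Subspace adaptive-weight feature fusion and the three-layer
bidirectional LSTM fusion network.

Subspace fusion projects each of n feature vectors (dimension df) into k
learned subspaces of dimension dk = df / k, weights each projection by a
Gaussian kernel of its distance to a learned per-subspace centre,

    sw_ij = exp(-(1/df) ||f_i SW_j - M_j||^2),
    Sf_j  = sum_i sw_ij (f_i SW_j),

and concatenates Sf_1..Sf_k back to dimension df.  Mapping matrices and
centres are ordinary trainable parameters.

The temporal fusion network has three layers: (1) one bidirectional
(attention-gated) LSTM per stream; (2) a per-time-step sigmoid-linear
merge of the two streams' hidden states; (3) a bidirectional LSTM over
the merged sequence.  Its pooled output feeds the classification heads.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import AMLSTMCell


def subspace_fusion(
    features: list[Tensor], mappings: Tensor, centers: Tensor
) -> tuple[Tensor, Tensor]:
    """Fuse n df-dimensional features into one df-dimensional vector.

    ``features``: list of (B, df); ``mappings``: (k, df, dk);
    ``centers``: (k, dk).  Returns (SF (B, df), weights sw (B, n, k));
    every weight lies in (0, 1], reaching 1 iff the projected feature
    coincides with the subspace centre.
    """
    k, df, dk = mappings.shape
    if df != k * dk:
        raise ValueError(f"df = {df} must equal k * dk = {k}*{dk}")
    if centers.shape != (k, dk):
        raise ValueError(f"centers must be (k, dk) = ({k}, {dk}), got {centers.shape}")
    for f in features:
        if f.shape[-1] != df:
            raise ValueError(f"feature dim {f.shape[-1]} != df {df}")
    projs = []  # each (B, k, dk)
    sws = []
    sf_parts: list[Tensor | None] = [None] * k
    for f in features:
        proj = (f.reshape(f.shape[0], 1, 1, df) @ mappings).reshape(f.shape[0], k, dk)
        d2 = ((proj - centers) ** 2).sum(axis=-1)  # (B, k)
        sw = ad.exp(d2 * (-1.0 / df))
        projs.append(proj)
        sws.append(sw)
    for j in range(k):
        acc = None
        for proj, sw in zip(projs, sws):
            term = sw[:, j : j + 1] * proj[:, j, :]
            acc = term if acc is None else acc + term
        sf_parts[j] = acc
    SF = ad.concat(sf_parts, axis=-1)  # (B, k*dk) = (B, df)
    weights = ad.stack(sws, axis=1)  # (B, n, k)
    return SF, weights


def bilstm_layer(
    xs: list[Tensor],
    forward_cell: AMLSTMCell,
    backward_cell: AMLSTMCell,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> list[Tensor]:
    """Bidirectional recurrent layer.

    Runs ``forward_cell`` over the sequence and ``backward_cell`` over
    its reversal, concatenating per-step hidden states, so reversing the
    input and swapping the two cells reverses the output sequence
    exactly.
    """
    if not xs:
        raise ValueError("empty sequence")
    h_fwd = forward_cell.run(xs, train=train, rng=rng)
    h_bwd = backward_cell.run(xs[::-1], train=train, rng=rng)[::-1]
    return [ad.concat([hf, hb], axis=-1) for hf, hb in zip(h_fwd, h_bwd)]


def fuse_streams(h_expr_t: Tensor, h_eeg_t: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """f_t = sigmoid(w . [h_expr_t, h_eeg_t] + b), entries in (0, 1)."""
    if h_expr_t.shape[0] != h_eeg_t.shape[0]:
        raise ValueError("stream batch sizes differ")
    joint = ad.concat([h_expr_t, h_eeg_t], axis=-1)
    if joint.shape[-1] != w.shape[-1]:
        raise ValueError(f"fusion weight expects dim {w.shape[-1]}, got {joint.shape[-1]}")
    return ad.sigmoid(joint @ w.T + b)


class FusionNetwork:
    """Layers 1-3 of the temporal fusion architecture plus pooling/FC.

    ``stream_dims`` maps stream name -> per-step input dim.  With a
    single stream, layer 2 reduces to a sigmoid-linear transform of that
    stream alone.
    """

    def __init__(
        self,
        stream_dims: dict[str, int],
        hidden_dim: int = 24,
        fused_dim: int = 32,
        out_dim: int = 32,
        dropout: float = 0.1,
        rng: np.random.Generator | None = None,
    ):
        rng = np.random.default_rng(0) if rng is None else rng
        from .nn import glorot, zeros_param

        self.stream_names = tuple(stream_dims)
        self.hidden_dim = hidden_dim
        self.cells = {
            name: (
                AMLSTMCell(d, hidden_dim, rng, dropout=dropout),
                AMLSTMCell(d, hidden_dim, rng, dropout=dropout),
            )
            for name, d in stream_dims.items()
        }
        joint = 2 * hidden_dim * len(stream_dims)
        self.fuse_w = glorot(rng, (fused_dim, joint))
        self.fuse_b = zeros_param((fused_dim,))
        self.layer3 = (
            AMLSTMCell(fused_dim, hidden_dim, rng, dropout=dropout),
            AMLSTMCell(fused_dim, hidden_dim, rng, dropout=dropout),
        )
        self.out_w = glorot(rng, (out_dim, 2 * hidden_dim))
        self.out_b = zeros_param((out_dim,))

    def params(self) -> dict:
        d = {
            f"{name}_{i}": cell.params
            for name, pair in self.cells.items()
            for i, cell in enumerate(pair)
        }
        d["layer3_0"] = self.layer3[0].params
        d["layer3_1"] = self.layer3[1].params
        d["fuse_w"], d["fuse_b"] = self.fuse_w, self.fuse_b
        d["out_w"], d["out_b"] = self.out_w, self.out_b
        return d

    def forward(
        self,
        streams: dict[str, list[Tensor]],
        train: bool = False,
        rng: np.random.Generator | None = None,
        precomputed_hidden: dict[str, list[Tensor]] | None = None,
    ) -> dict:
        """Time-aligned per-stream input sequences -> pooled feature.

        ``precomputed_hidden`` lets a caller supply layer-1 hidden
        sequences for a stream whose recurrence is interleaved with
        other computation (the EEG stream's band attention).
        """
        if set(streams) != set(self.stream_names):
            raise ValueError(f"expected streams {self.stream_names}, got {tuple(streams)}")
        lengths = {len(v) for v in streams.values()}
        if len(lengths) != 1:
            raise ValueError("stream sequences must be time-aligned (equal lengths)")
        (T,) = lengths
        if T == 0:
            raise ValueError("empty sequence")
        hidden: dict[str, list[Tensor]] = {}
        for name in self.stream_names:
            if precomputed_hidden and name in precomputed_hidden:
                hidden[name] = precomputed_hidden[name]
            else:
                fwd, bwd = self.cells[name]
                hidden[name] = bilstm_layer(streams[name], fwd, bwd, train=train, rng=rng)
        fused = []
        for t in range(T):
            joint = ad.concat([hidden[name][t] for name in self.stream_names], axis=-1)
            fused.append(ad.sigmoid(joint @ self.fuse_w.T + self.fuse_b))
        h_f = bilstm_layer(fused, *self.layer3, train=train, rng=rng)
        pooled = ad.stack(h_f, axis=1).mean(axis=1)  # (B, 2H)
        out = ad.tanh(pooled @ self.out_w.T + self.out_b)
        return {"hidden": hidden, "fused": fused, "h_f": h_f, "pooled": out}
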