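"""End-to-end multimodal network: BCN encoders, band attention, the
attention-gated bidirectional LSTM fusion stack, subspace fusion, and
AM-Softmax classifier heads.

Per trial the EEG branch receives, for each segment, three band feature
matrices (descriptors of the alpha/beta/theta scalp images).  A single
BCN (shared across bands) encodes each matrix; the three band features
are fused by softmax band attention whose logits are driven by the
previous forward hidden state of the EEG stream, then passed through a
fully connected layer to give the per-segment EEG input x_e,n.  The
expression branch encodes the per-frame landmark-descriptor matrix with
its own BCN.  Both streams enter the three-layer bidirectional fusion
network; pooled stream features, the subspace-fused feature, and the
averaged branch posteriors are supervised by the compound AM-Softmax
objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import AMLSTMCell, band_attention
from .bcn import BCN
from .fusion import bilstm_layer, subspace_fusion
from .losses import LossBreakdown, decision_fusion_posterior, total_loss
from .nn import collect_params, glorot, normal_param, zeros_param

HEADS = ("arousal", "valence")


@dataclass
class ModelConfig:
    streams: tuple[str, ...] = ("expr", "eeg")
    heads: tuple[str, ...] = HEADS
    n_classes: int = 3
    eeg_matrix_shape: tuple[int, int] = (25, 32)   # (M, N) per band image
    expr_matrix_shape: tuple[int, int] = (16, 32)
    bcn_left_channels: int = 2
    bcn_right_channels: int = 2
    bcn_m_out: int = 12
    bcn_n_out: int = 16
    bcn_conv_channels: int = 4
    bcn_filter_len: int = 5
    bcn_pool_size: int = 2
    bcn_fc_hidden: int = 48
    stream_feature_dim: int = 24   # per-segment x_e,n / x_v,n dimension
    lstm_hidden: int = 16
    fused_dim: int = 24            # layer-2 sigmoid merge dimension
    subspace_df: int = 64
    subspaces_k: int = 4
    dropout: float = 0.1
    am_scale: float = 12.0
    am_margin: float = 0.35

    def __post_init__(self) -> None:
        if not self.streams or any(s not in ("expr", "eeg") for s in self.streams):
            raise ValueError("streams must be a nonempty subset of ('expr', 'eeg')")
        if any(h not in HEADS for h in self.heads):
            raise ValueError(f"heads must be among {HEADS}")
        if self.subspace_df % self.subspaces_k != 0:
            raise ValueError("subspace_df must be divisible by subspaces_k")


class MultimodalEmotionNet:
    """Trainable network; parameters live in nested dicts of Tensors."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        H = cfg.lstm_hidden
        D = cfg.stream_feature_dim
        self.modules: dict = {}
        if "eeg" in cfg.streams:
            m, n = cfg.eeg_matrix_shape
            self.bcn_eeg = self._make_bcn(m, n, rng)
            self.modules["bcn_eeg"] = self.bcn_eeg.params
            self.band_w = normal_param(rng, (3, H), scale=0.1)
            self.band_b = zeros_param((3,))
            self.eeg_fc_w = glorot(rng, (D, 24))
            self.eeg_fc_b = zeros_param((D,))
            self.eeg_fwd = AMLSTMCell(D, H, rng, dropout=cfg.dropout)
            self.eeg_bwd = AMLSTMCell(D, H, rng, dropout=cfg.dropout)
            self.modules.update(
                band_w=self.band_w, band_b=self.band_b,
                eeg_fc_w=self.eeg_fc_w, eeg_fc_b=self.eeg_fc_b,
                eeg_fwd=self.eeg_fwd.params, eeg_bwd=self.eeg_bwd.params,
            )
        if "expr" in cfg.streams:
            m, n = cfg.expr_matrix_shape
            self.bcn_expr = self._make_bcn(m, n, rng)
            self.modules["bcn_expr"] = self.bcn_expr.params
            self.expr_fc_w = glorot(rng, (D, 24))
            self.expr_fc_b = zeros_param((D,))
            self.expr_fwd = AMLSTMCell(D, H, rng, dropout=cfg.dropout)
            self.expr_bwd = AMLSTMCell(D, H, rng, dropout=cfg.dropout)
            self.modules.update(
                expr_fc_w=self.expr_fc_w, expr_fc_b=self.expr_fc_b,
                expr_fwd=self.expr_fwd.params, expr_bwd=self.expr_bwd.params,
            )
        joint = 2 * H * len(cfg.streams)
        self.fuse_w = glorot(rng, (cfg.fused_dim, joint))
        self.fuse_b = zeros_param((cfg.fused_dim,))
        self.l3_fwd = AMLSTMCell(cfg.fused_dim, H, rng, dropout=cfg.dropout)
        self.l3_bwd = AMLSTMCell(cfg.fused_dim, H, rng, dropout=cfg.dropout)
        self.modules.update(
            fuse_w=self.fuse_w, fuse_b=self.fuse_b,
            l3_fwd=self.l3_fwd.params, l3_bwd=self.l3_bwd.params,
        )

        df, k = cfg.subspace_df, cfg.subspaces_k
        # per-head projections of pooled hidden sequences to df dims, and
        # a per-head subspace-fusion block: each dimensional classifier
        # shapes its own feature geometry, so the two heads' cosine
        # objectives do not fight over one shared embedding
        self.proj = {
            head: {
                name: {"w": glorot(rng, (df, 2 * H)), "b": zeros_param((df,))}
                for name in (*cfg.streams, "temporal")
            }
            for head in cfg.heads
        }
        self.modules["proj"] = self.proj
        self.subspace = {
            head: {
                "SW": normal_param(rng, (k, df, df // k), scale=0.1),
                "M": normal_param(rng, (k, df // k), scale=0.1),
            }
            for head in cfg.heads
        }
        self.modules["subspace"] = self.subspace
        # AM-Softmax classifier weights per head per branch
        c = cfg.n_classes
        self.classifiers = {
            head: {
                **{name: glorot(rng, (c, df)) for name in cfg.streams},
                "sf": glorot(rng, (c, df)),
                "df": glorot(rng, (c, c)),  # on log averaged posteriors
            }
            for head in cfg.heads
        }
        self.modules["classifiers"] = self.classifiers

    def _make_bcn(self, m: int, n: int, rng: np.random.Generator) -> BCN:
        c = self.cfg
        return BCN(
            m, n,
            n_left=c.bcn_left_channels, m_out=c.bcn_m_out,
            n_right=c.bcn_right_channels, n_out=c.bcn_n_out,
            conv_channels=c.bcn_conv_channels, filter_len=c.bcn_filter_len,
            pool_size=c.bcn_pool_size, fc_hidden=c.bcn_fc_hidden,
            feature_dim=24, rng=rng,
        )

    def parameters(self) -> list[Tensor]:
        return collect_params(self.modules)

    # ------------------------------------------------------------------
    def _eeg_stream(self, eeg_feats: np.ndarray, train: bool,
                    rng: np.random.Generator | None):
        """Band-attended per-segment encoding and layer-1 hidden states.

        ``eeg_feats``: (B, S, 3, M, N).  The forward direction drives the
        band attention with its previous hidden state; the backward
        direction runs over the per-segment inputs produced in the
        forward loop.
        """
        B, S, _, M, N = eeg_feats.shape
        flat = eeg_feats.reshape(B * S * 3, 1, M, N)
        feats = self.bcn_eeg.forward(Tensor(flat))  # (B*S*3, Df)
        feats = feats.reshape(B, S, 3, feats.shape[-1])
        h, c_state = self.eeg_fwd.init_state(B)
        xs: list[Tensor] = []
        h_fwd: list[Tensor] = []
        thetas: list[Tensor] = []
        for n_seg in range(S):
            f_a = feats[:, n_seg, 0, :]
            f_b = feats[:, n_seg, 1, :]
            f_t = feats[:, n_seg, 2, :]
            fused, theta = band_attention(f_a, f_b, f_t, h, self.band_w, self.band_b)
            x_n = ad.tanh(fused @ self.eeg_fc_w.T + self.eeg_fc_b)
            xs.append(x_n)
            thetas.append(theta)
            mask = self._dropout_mask(B, train, rng)
            h, c_state = self.eeg_fwd.step(x_n, h, c_state, mask)
            h_fwd.append(h)
        h_bwd = self.eeg_bwd.run(xs[::-1], train=train, rng=rng)[::-1]
        hidden = [ad.concat([hf, hb], axis=-1) for hf, hb in zip(h_fwd, h_bwd)]
        return xs, hidden, thetas

    def _dropout_mask(self, batch: int, train: bool,
                      rng: np.random.Generator | None) -> np.ndarray | None:
        p = self.cfg.dropout
        if not train or p <= 0:
            return None
        if rng is None:
            raise ValueError("training with dropout requires an rng")
        keep = rng.random((batch, self.cfg.lstm_hidden)) >= p
        return keep / (1.0 - p)

    def forward(
        self,
        eeg_feats: np.ndarray | None,
        expr_feats: np.ndarray | None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        cfg = self.cfg
        hidden: dict[str, list[Tensor]] = {}
        attention_series = None
        B = None
        if "eeg" in cfg.streams:
            if eeg_feats is None:
                raise ValueError("model expects EEG features")
            B = eeg_feats.shape[0]
            _, hidden["eeg"], thetas = self._eeg_stream(eeg_feats, train, rng)
            attention_series = np.stack([t.data for t in thetas], axis=1)  # (B, S, 3)
        if "expr" in cfg.streams:
            if expr_feats is None:
                raise ValueError("model expects expression features")
            B = expr_feats.shape[0]
            Bx, S, M, N = expr_feats.shape
            flat = expr_feats.reshape(Bx * S, 1, M, N)
            feats = self.bcn_expr.forward(Tensor(flat)).reshape(Bx, S, -1)
            xs = [
                ad.tanh(feats[:, t, :] @ self.expr_fc_w.T + self.expr_fc_b)
                for t in range(S)
            ]
            hidden["expr"] = bilstm_layer(xs, self.expr_fwd, self.expr_bwd,
                                          train=train, rng=rng)
        lengths = {len(v) for v in hidden.values()}
        if len(lengths) != 1:
            raise ValueError("stream sequences are not time-aligned")
        (T,) = lengths

        fused = []
        for t in range(T):
            joint = ad.concat([hidden[s][t] for s in cfg.streams], axis=-1)
            fused.append(ad.sigmoid(joint @ self.fuse_w.T + self.fuse_b))
        h_f = bilstm_layer(fused, self.l3_fwd, self.l3_bwd, train=train, rng=rng)

        def pool(seq: list[Tensor]) -> Tensor:
            return ad.stack(seq, axis=1).mean(axis=1)

        pooled = {name: pool(hidden[name]) for name in cfg.streams}
        pooled["temporal"] = pool(h_f)

        out = {
            "branch_features": {},
            "sf": {},
            "subspace_weights": {},
            "attention": attention_series,
            "posteriors": {},
            "logits": {},
            "branch_posteriors": {},
        }
        for head in cfg.heads:
            feats_h = {
                name: pooled[name] @ p["w"].T + p["b"]
                for name, p in self.proj[head].items()
            }
            sf_inputs = [feats_h[s] for s in cfg.streams] + [feats_h["temporal"]]
            sf, sw = subspace_fusion(
                sf_inputs, self.subspace[head]["SW"], self.subspace[head]["M"]
            )
            out["branch_features"][head] = feats_h
            out["sf"][head] = sf
            out["subspace_weights"][head] = sw
            cls = self.classifiers[head]
            posts = []
            for name in cfg.streams:
                cos = _cosine_logits(feats_h[name], cls[name], cfg.am_scale)
                posts.append(ad.softmax(cos, axis=-1))
            cos_sf = _cosine_logits(sf, cls["sf"], cfg.am_scale)
            posts.append(ad.softmax(cos_sf, axis=-1))
            avg = decision_fusion_posterior(posts)
            out["posteriors"][head] = avg
            out["logits"][head] = cos_sf
            out["branch_posteriors"][head] = posts
        return out

    def loss(
        self,
        out: dict,
        labels: dict[str, np.ndarray],
        scale: float | None = None,
        margin: float | None = None,
    ) -> LossBreakdown:
        """Compound objective; ``scale``/``margin`` override the configured
        AM-Softmax settings (used by the trainer's warm-up schedule)."""
        cfg = self.cfg
        scale = cfg.am_scale if scale is None else scale
        margin = cfg.am_margin if margin is None else margin
        parts: list[LossBreakdown] = []
        for head in cfg.heads:
            cls = self.classifiers[head]
            # decision fusion combines finished decisions: its loss trains
            # only the DF classifier weights, so the branch posteriors are
            # detached from the graph here (backpropagating the DF loss
            # into the features provably destabilises training)
            lb = total_loss(
                stream_features=[out["branch_features"][head][s] for s in cfg.streams],
                sf_feature=out["sf"][head],
                df_posteriors=[Tensor(p.data) for p in out["branch_posteriors"][head]],
                labels=labels[head],
                stream_weights=[cls[s] for s in cfg.streams],
                sf_weights=cls["sf"],
                df_weights=cls["df"],
                s=scale,
                m=margin,
            )
            parts.append(lb)
        f = parts[0].loss_F
        sf = parts[0].loss_SF
        dfl = parts[0].loss_DF
        for p in parts[1:]:
            f = f + p.loss_F
            sf = sf + p.loss_SF
            dfl = dfl + p.loss_DF
        return LossBreakdown(f, sf, dfl, f + sf + dfl)

    def predict(self, out: dict) -> dict[str, np.ndarray]:
        return {h: np.argmax(out["posteriors"][h].data, axis=-1) for h in self.cfg.heads}


def _cosine_logits(features: Tensor, weights: Tensor, scale: float) -> Tensor:
    xn = features * ((features**2).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
    wn = weights * ((weights**2).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
    return (xn @ wn.T) * scale
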