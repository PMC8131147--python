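"""Soft attention: spatial band attention and the attention-gated LSTM.

Two mechanisms, both differentiable:

* **Band attention** — a softmax over the three EEG frequency bands.
  The logit for band i is ``w_i . h_prev + b_i`` where ``h_prev`` is the
  EEG-stream LSTM hidden state from the previous segment, so the network
  can shift attention between alpha, beta, and theta over time.  The
  fused feature is the attention-weighted sum of the band features.

* **Temporal attention gate (AM-LSTM)** — a sigmoid gate
  ``a_t = sigmoid(W_x x_t + W_h h_{t-1} + b_a)`` that reweights each
  component of the input vector before a standard LSTM step.  Sigmoid
  (not softmax) is used so components are weighted independently in
  (0, 1).  Dropout on the hidden state uses the inverted convention:
  mask entries are 0 or 1/(1-p) during training and all ones at
  evaluation, so no rescaling is needed at inference.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import glorot, zeros_param


def band_attention(
    f_alpha: Tensor, f_beta: Tensor, f_theta: Tensor,
    h_prev: Tensor, weights: Tensor, biases: Tensor,
) -> tuple[Tensor, Tensor]:
    """Fuse three band features with softmax importances.

    ``f_*``: (B, D); ``h_prev``: (B, H); ``weights``: (3, H);
    ``biases``: (3,).  Returns (fused (B, D), importances (B, 3)); the
    importances are positive and sum to 1 over the band axis.
    """
    if not (f_alpha.shape == f_beta.shape == f_theta.shape):
        raise ValueError("band features must share a common shape")
    if h_prev.shape[-1] != weights.shape[-1]:
        raise ValueError(
            f"hidden dim {h_prev.shape[-1]} does not match weights {weights.shape}"
        )
    logits = h_prev @ weights.T + biases  # (B, 3)
    theta = ad.softmax(logits, axis=-1)
    fused = (
        theta[:, 0:1] * f_alpha + theta[:, 1:2] * f_beta + theta[:, 2:3] * f_theta
    )
    return fused, theta


def attention_gate(
    x_t: Tensor, h_prev: Tensor, w_x: Tensor, w_h: Tensor, b_a: Tensor
) -> tuple[Tensor, Tensor]:
    """Elementwise sigmoid attention over the input vector.

    ``x_t``: (B, D); ``h_prev``: (B, H); ``w_x``: (D, D); ``w_h``: (D, H);
    ``b_a``: (D,).  Returns (gated input a_t * x_t, gate a_t in (0,1)).
    """
    if x_t.shape[-1] != w_x.shape[-1] or h_prev.shape[-1] != w_h.shape[-1]:
        raise ValueError("attention gate weight shapes inconsistent with inputs")
    a_t = ad.sigmoid(x_t @ w_x.T + h_prev @ w_h.T + b_a)
    return a_t * x_t, a_t


def am_lstm_step(
    x_hat: Tensor, h_prev: Tensor, c_prev: Tensor,
    params: dict[str, Tensor], mask: np.ndarray | None = None,
) -> tuple[Tensor, Tensor]:
    """One LSTM step on the attention-gated input.

    Standard gate equations (input i, forget f, output o, candidate via
    tanh); the dropout mask ``mask`` (entries 0 or 1/(1-p), or None for
    evaluation) multiplies the emitted hidden state h_t = o * tanh(c_t).
    """

    def gate(prefix: str, act):
        return act(
            x_hat @ params[f"w_x{prefix}"].T
            + h_prev @ params[f"w_h{prefix}"].T
            + params[f"b_{prefix}"]
        )

    i = gate("i", ad.sigmoid)
    f = gate("f", ad.sigmoid)
    o = gate("o", ad.sigmoid)
    cand = gate("c", ad.tanh)
    c_t = f * c_prev + i * cand
    h_t = o * ad.tanh(c_t)
    if mask is not None:
        h_t = h_t * mask
    return h_t, c_t


class AMLSTMCell:
    """Attention-gated LSTM cell: sigmoid input gate, then the recurrent
    step.  The gate output dimension equals ``input_dim``."""

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator, dropout: float = 0.0,
                 use_gate: bool = True):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.dropout = dropout
        self.use_gate = use_gate
        p: dict[str, Tensor] = {}
        if use_gate:
            p["w_xa"] = glorot(rng, (input_dim, input_dim))
            p["w_ha"] = glorot(rng, (input_dim, hidden_dim))
            p["b_a"] = zeros_param((input_dim,))
        for g in ("i", "f", "o", "c"):
            p[f"w_x{g}"] = glorot(rng, (hidden_dim, input_dim))
            p[f"w_h{g}"] = glorot(rng, (hidden_dim, hidden_dim))
            p[f"b_{g}"] = zeros_param((hidden_dim,))
        self.params = p

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.hidden_dim))
        return Tensor(z), Tensor(z.copy())

    def step(
        self, x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
        mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        if self.use_gate:
            x_t, _ = attention_gate(
                x_t, h_prev, self.params["w_xa"], self.params["w_ha"], self.params["b_a"]
            )
        return am_lstm_step(x_t, h_prev, c_prev, self.params, mask)

    def run(
        self, xs: list[Tensor], train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> list[Tensor]:
        """Process a sequence; returns the hidden states in input order."""
        if not xs:
            raise ValueError("empty sequence")
        batch = xs[0].shape[0]
        h, c = self.init_state(batch)
        hs = []
        for x_t in xs:
            mask = None
            if train and self.dropout > 0:
                if rng is None:
                    raise ValueError("training with dropout requires an rng")
                keep = rng.random((batch, self.hidden_dim)) >= self.dropout
                mask = keep / (1.0 - self.dropout)
            h, c = self.step(x_t, h, c, mask)
            hs.append(h)
        return hs


def export_attention_csv(path: str | Path, theta_series: np.ndarray) -> None:
    """Write a per-segment (theta_alpha, theta_beta, theta_theta) series."""
    theta_series = np.asarray(theta_series)
    if theta_series.ndim != 2 or theta_series.shape[1] != 3:
        raise ValueError("theta_series must be (n_segments, 3)")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["segment_index", "theta_alpha", "theta_beta", "theta_theta"])
        for i, (a, b, t) in enumerate(theta_series):
            w.writerow([i, f"{a:.8f}", f"{b:.8f}", f"{t:.8f}"])
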