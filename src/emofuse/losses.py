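"""Training objectives: cross-entropy, cosine softmax, AM-Softmax, and
the summed compound loss.

AM-Softmax replaces the inner-product logits of softmax cross-entropy by
scaled cosine similarities and subtracts an additive margin m from the
target-class cosine:

    L = -mean_i log  e^{s(cos t_yi - m)} /
                    (e^{s(cos t_yi - m)} + sum_{j != yi} e^{s cos t_j})

With s = 1, m = 0 it reduces exactly to the cosine softmax loss.  The
compound objective sums per-feature losses (loss_F), the fused-feature
loss (loss_SF), and the decision-fusion loss (loss_DF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_EPS = 1e-12


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D integer array")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    return labels.astype(int)


def _ce_from_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log softmax probability of the true class."""
    n, c = logits.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    true_logit = (logits * onehot).sum(axis=-1)
    return (ad.logsumexp(logits, axis=-1) - true_logit).mean()


def cross_entropy_loss(
    features: Tensor, labels: np.ndarray, weights: Tensor, biases: Tensor
) -> Tensor:
    """Softmax cross-entropy on logits w_j . x + b_j."""
    features = ad.as_tensor(features)
    labels = _check_labels(labels, weights.shape[0])
    logits = features @ weights.T + biases
    return _ce_from_logits(logits, labels)


def _cosines(features: Tensor, weights: Tensor) -> Tensor:
    if np.any(np.linalg.norm(features.data, axis=-1) < _EPS):
        raise ValueError("zero-norm feature: cosine undefined")
    if np.any(np.linalg.norm(weights.data, axis=-1) < _EPS):
        raise ValueError("zero-norm class weight: cosine undefined")
    xn = features * ((features**2).sum(axis=-1, keepdims=True) ** -0.5)
    wn = weights * ((weights**2).sum(axis=-1, keepdims=True) ** -0.5)
    return xn @ wn.T


def cosine_softmax_loss(features: Tensor, labels: np.ndarray, weights: Tensor) -> Tensor:
    """Cross-entropy on cosine-similarity logits; invariant to ||x||."""
    features = ad.as_tensor(features)
    labels = _check_labels(labels, weights.shape[0])
    return _ce_from_logits(_cosines(features, weights), labels)


def am_softmax_loss(
    features: Tensor, labels: np.ndarray, weights: Tensor,
    s: float = 30.0, m: float = 0.35,
) -> Tensor:
    """Additive-margin cosine softmax loss."""
    if s <= 0:
        raise ValueError("scale s must be positive")
    if not 0.0 <= m < 1.0:
        raise ValueError("margin m must be in [0, 1)")
    features = ad.as_tensor(features)
    labels = _check_labels(labels, weights.shape[0])
    cos = _cosines(features, weights)
    n, c = cos.shape
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    logits = (cos - m * onehot) * s
    return _ce_from_logits(logits, labels)


@dataclass
class LossBreakdown:
    """Components of the compound objective; ``total`` is their exact sum."""

    loss_F: Tensor
    loss_SF: Tensor
    loss_DF: Tensor
    total: Tensor

    def as_floats(self) -> dict[str, float]:
        return {
            "loss_F": self.loss_F.item(),
            "loss_SF": self.loss_SF.item(),
            "loss_DF": self.loss_DF.item(),
            "total": self.total.item(),
        }


def decision_fusion_posterior(posteriors: list[Tensor]) -> Tensor:
    """Average the branch softmax posteriors (the decision-fusion rule)."""
    if not posteriors:
        raise ValueError("no posteriors to fuse")
    acc = posteriors[0]
    for p in posteriors[1:]:
        if p.shape != acc.shape:
            raise ValueError("posterior shapes differ across branches")
        acc = acc + p
    return acc * (1.0 / len(posteriors))


def total_loss(
    stream_features: list[Tensor],
    sf_feature: Tensor | None,
    df_posteriors: list[Tensor] | None,
    labels: np.ndarray,
    stream_weights: list[Tensor],
    sf_weights: Tensor | None,
    df_weights: Tensor | None,
    s: float = 30.0,
    m: float = 0.35,
) -> LossBreakdown:
    """loss_F + loss_SF + loss_DF on one batch.

    loss_F sums AM-Softmax over the per-stream features; loss_SF applies
    it to the subspace-fused feature; loss_DF applies it to the log of
    the averaged branch posteriors.  Disabled components (None) count 0.
    """
    if len(stream_features) != len(stream_weights):
        raise ValueError("one weight matrix required per stream feature")
    zero = Tensor(0.0)
    loss_f = zero
    for f, w in zip(stream_features, stream_weights):
        loss_f = loss_f + am_softmax_loss(f, labels, w, s=s, m=m)
    loss_sf = (
        am_softmax_loss(sf_feature, labels, sf_weights, s=s, m=m)
        if sf_feature is not None
        else zero
    )
    if df_posteriors is not None:
        avg = decision_fusion_posterior(df_posteriors)
        log_post = ad.log(avg + _EPS)
        loss_df = am_softmax_loss(log_post, labels, df_weights, s=s, m=m)
    else:
        loss_df = zero
    return LossBreakdown(loss_f, loss_sf, loss_df, loss_f + loss_sf + loss_df)
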