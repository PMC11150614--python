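"""Training losses: TopK cross-entropy, soft Dice, and their sum.

The TopK term averages per-pixel binary cross-entropy over the hardest
k% of pixels (largest per-pixel loss); the Dice term is the soft region
overlap complement.  The compound objective is their unweighted sum,
with a plain cross-entropy arm (the k = 100 degenerate) available for
ablations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor

__all__ = ["LossConfig", "topk_loss", "dice_loss", "combined_loss", "per_pixel_bce"]

#: probabilities are clamped to this interval so logs stay finite
PROB_EPS = 1e-7


@dataclass
class LossConfig:
    """Switches and constants for the compound training objective."""

    k_percent: float = 10.0
    use_topk: bool = True
    use_dice: bool = True
    use_ce: bool = False
    epsilon: float = 1e-6
    per_image: bool = False

    def __post_init__(self):
        if not (0.0 < self.k_percent <= 100.0):
            raise ValueError("k_percent must lie in (0, 100]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (self.use_topk or self.use_dice or self.use_ce):
            raise ValueError("at least one loss term must be enabled")


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def per_pixel_bce(probs: Tensor, target: Tensor) -> Tensor:
    """Elementwise binary cross-entropy with clamped probabilities."""
    p = _coerce(probs).clamp(PROB_EPS, 1.0 - PROB_EPS)
    g = _coerce(target).detach()
    return -(g * p.log() + (1.0 - g) * (1.0 - p).log())


def topk_loss(probs, target, k_percent: float = 10.0,
              per_image: bool = False) -> Tensor:
    """Mean cross-entropy over the k% pixels with the largest loss.

    Pixels are ranked by their per-pixel cross-entropy (descending, ties
    broken by flat pixel index); the selection size is ``ceil(k% * N)``
    floored at one pixel.  With ``per_image`` the ranking and averaging
    are done separately per leading-axis element, otherwise over the
    flattened batch.
    """
    if not (0.0 < k_percent <= 100.0):
        raise ValueError("k_percent must lie in (0, 100]")
    losses = per_pixel_bce(probs, target)
    if per_image and losses.ndim > 1:
        n_img = losses.shape[0]
        flat = losses.reshape(n_img, -1)
        total = Tensor(0.0)
        for i in range(n_img):
            total = total + _topk_mean(flat[i], k_percent)
        return total * (1.0 / n_img)
    return _topk_mean(losses.reshape(losses.size), k_percent)


def _topk_mean(flat: Tensor, k_percent: float) -> Tensor:
    n = flat.size
    m = max(1, int(np.ceil(k_percent / 100.0 * n)))
    if m >= n:
        return flat.mean()
    # stable sort on negated values -> descending, ties by pixel index
    order = np.argsort(-flat.data, kind="stable")[:m]
    return flat[order].mean()


def dice_loss(probs, target, epsilon: float = 1e-6) -> Tensor:
    """Soft Dice overlap complement: 1 − 2|Vs∩Vg| / (|Vs| + |Vg|).

    Computed on probabilities (soft intersection Σ s·g); the epsilon in
    numerator and denominator makes the empty-vs-empty case return 0.
    """
    p = _coerce(probs)
    g = _coerce(target).detach()
    inter = (p * g).sum()
    total = p.sum() + g.sum()
    return 1.0 - (2.0 * inter + epsilon) / (total + epsilon)


def combined_loss(probs, target, config: LossConfig | None = None) -> Tensor:
    """Unweighted sum of the enabled loss terms.

    ``use_ce`` replaces the TopK term with full-image mean cross-entropy
    (exactly the k = 100 degenerate of the TopK loss).
    """
    if config is None:
        config = LossConfig()
    total = Tensor(0.0)
    if config.use_ce:
        total = total + topk_loss(probs, target, 100.0, config.per_image)
    elif config.use_topk:
        total = total + topk_loss(probs, target, config.k_percent, config.per_image)
    if config.use_dice:
        total = total + dice_loss(probs, target, config.epsilon)
    return total


def loss_components(probs, target, config: LossConfig) -> dict:
    """Scalar values of each enabled term, for logging."""
    out = {}
    if config.use_ce:
        out["ce"] = topk_loss(probs, target, 100.0, config.per_image).item()
    elif config.use_topk:
        out["topk"] = topk_loss(probs, target, config.k_percent, config.per_image).item()
    if config.use_dice:
        out["dice"] = dice_loss(probs, target, config.epsilon).item()
    return out
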