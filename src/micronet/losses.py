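"""Training objectives.

The regression target is dominated by zero-valued background, so a plain
MSE admits the trivial all-zero solution.  The weighted MSE used here
up-weights the residual at pixel (u, v) by ``y_uv + lam * y_bar``, where
``y_bar`` is the mean of the image's gold map: nucleus interiors always get
extra weight, and because ``y_bar`` is computed per *image*, even an
all-background crop of an annotated image keeps a non-zero weight, which is
what prevents the network from collapsing to zero output.

For mixed-source training the per-iteration objective is the weighted sum
``gamma * L_target + L_auxiliary``; ``gamma = 1`` reproduces naive pooling
of the two sources exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _autograd as ag
from .labels import ProximityMap

__all__ = ["LossParams", "weighted_mse", "last_layer_gradient", "combined_loss"]


@dataclass(frozen=True)
class LossParams:
    """lam: background/foreground weight control (λ); lam = 0 recovers the
    plain foreground-only weighting.  gamma: target/auxiliary balance (γ);
    gamma = 1 is naive dataset pooling.  normalize_by_pixels: divide the
    per-image loss by its pixel count."""

    lam: float = 5.0
    gamma: float = 1.0
    normalize_by_pixels: bool = True

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")


def _values(m) -> np.ndarray:
    return m.values if isinstance(m, ProximityMap) else np.asarray(m, dtype=np.float64)


def loss_weights(gold: np.ndarray, lam: float, y_bar: Optional[float] = None) -> np.ndarray:
    """Per-pixel weights ``y + lam * y_bar``.

    ``y_bar`` defaults to the mean of ``gold`` itself; training passes the
    mean of the *full source image's* map so that background-only crops keep
    their penalty.
    """
    if y_bar is None:
        y_bar = float(gold.mean())
    return gold + lam * y_bar


def weighted_mse(
    prediction,
    gold,
    params: LossParams = LossParams(),
    y_bar: Optional[float] = None,
) -> float:
    """Weighted mean squared error between a predicted and a gold map.

    Returns ``0.5 * sum((y + lam*y_bar) * (o - y)^2)``, divided by the pixel
    count when ``params.normalize_by_pixels`` is set.
    """
    o = _values(prediction)
    y = _values(gold)
    if o.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {o.shape} vs gold {y.shape}")
    w = loss_weights(y, params.lam, y_bar)
    loss = 0.5 * float(np.sum(w * (o - y) ** 2))
    if params.normalize_by_pixels:
        loss /= y.size
    return loss


def weighted_mse_tensor(
    prediction: "ag.Tensor",
    gold: np.ndarray,
    params: LossParams,
    y_bar: Optional[float] = None,
) -> "ag.Tensor":
    """Tape-based version of :func:`weighted_mse` for training; ``prediction``
    stays on the autodiff tape."""
    y = np.asarray(gold, dtype=prediction.data.dtype)
    w = loss_weights(y.astype(np.float64), params.lam, y_bar).astype(prediction.data.dtype)
    resid = ag.sub_const(prediction, y)
    weighted = ag.mul_const(ag.mul(resid, resid), w)
    factor = 0.5 / (y.size if params.normalize_by_pixels else 1.0)
    return ag.mul_const(ag.sum_all(weighted), factor)


def last_layer_gradient(
    prediction,
    gold,
    params: LossParams = LossParams(),
    preactivation=None,
    y_bar: Optional[float] = None,
) -> np.ndarray:
    """Analytic gradient of the weighted MSE w.r.t. the last-layer
    pre-activation when the output head is a sigmoid.

    With ``o = sigmoid(z)`` the per-pixel derivative is

        dL/dz = (y + lam*y_bar) * (o - y) * o * (1 - o)

    (divided by the pixel count under ``normalize_by_pixels``).  Serves as an
    independent oracle against the automatic differentiation route.
    """
    o = _values(prediction)
    y = _values(gold)
    if o.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {o.shape} vs gold {y.shape}")
    if preactivation is not None:
        a = 1.0 / (1.0 + np.exp(-np.asarray(preactivation, dtype=np.float64)))
    else:
        a = o
    grad = loss_weights(y, params.lam, y_bar) * (o - y) * a * (1.0 - a)
    if params.normalize_by_pixels:
        grad = grad / y.size
    return grad


def combined_loss(target_loss: float, auxiliary_loss: float, params: LossParams) -> float:
    """Weighted target/auxiliary combination ``gamma * L_T + L_A``."""
    for name, v in (("target_loss", target_loss), ("auxiliary_loss", auxiliary_loss)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and non-negative, got {v}")
    return params.gamma * target_loss + auxiliary_loss
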