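"""Prediction and nucleus localization.

The network is fully convolutional, so an arbitrary-sized image is
predicted in a single forward pass (no sliding window).  Nucleus centers
are then localized on the predicted proximity map by suppressing pixels
below a fraction ``xi`` of the map's maximum and extracting local maxima;
the threshold is relative to the maximum, so detection is invariant to
positive rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .labels import ProximityMap
from .model import MicroNet

__all__ = ["DetectionSet", "predict", "predict_batch", "detect"]

#: default local-maxima exclusion radius, in pixels — roughly the smallest
#: plausible nucleus radius under the d=15 proximity encoding
DEFAULT_MIN_DISTANCE = 6


@dataclass
class DetectionSet:
    """Predicted nucleus centers for one image.

    points : list of (row, col), real-valued, inside the image bounds
    scores : predicted proximity value at each point
    xi     : threshold fraction that produced this set
    """

    points: list[tuple[float, float]] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)
    xi: float = 0.0

    def __len__(self):
        return len(self.points)


def _normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-channel zero-mean/unit-sd normalization, as used in training."""
    x = np.asarray(image, dtype=np.float32)
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    return (x - mean) / np.maximum(sd, 1e-6)


def predict(network: MicroNet, image: np.ndarray) -> ProximityMap:
    """Predict the proximity map of one H x W x 3 image.

    Images smaller than the network's minimum size (but at least 8 px on a
    side) are reflect-padded for the forward pass and the output cropped
    back; anything smaller is rejected.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    if min(h, w) < 8:
        raise ValueError(f"image {h}x{w} is below the absolute 8-px floor")
    m = network.spec.min_input_size
    ph, pw = max(0, m - h), max(0, m - w)
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    x = _normalize_image(img).transpose(2, 0, 1)[None]
    out = network.forward(x, train=False)
    return ProximityMap(out.data[0, 0, :h, :w].astype(np.float64))


def predict_batch(network: MicroNet, images: Sequence[np.ndarray]) -> list[ProximityMap]:
    """Predict several same-sized images in one forward pass."""
    if not images:
        return []
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) > 1:
        return [predict(network, im) for im in images]
    x = np.stack([_normalize_image(im).transpose(2, 0, 1) for im in images])
    out = network.forward(x, train=False)
    return [ProximityMap(out.data[i, 0].astype(np.float64)) for i in range(len(images))]


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def detect(
    pmap: ProximityMap | np.ndarray,
    xi: float,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> DetectionSet:
    """Localize nuclei on a proximity map.

    Pixels below ``xi * max(map)`` are suppressed (set to zero); the
    remaining local maxima — pixels >= every neighbor within Euclidean
    distance ``min_distance`` — are returned.  Connected plateaus of equal
    value collapse to a single detection at their centroid.  Border pixels
    are eligible.
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must be in [0, 1], got {xi}")
    values = pmap.values if isinstance(pmap, ProximityMap) else np.asarray(pmap, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("proximity map contains non-finite values")
    peak = values.max() if values.size else 0.0
    if peak <= 0:
        return DetectionSet(xi=xi)
    processed = np.where(values >= xi * peak, values, 0.0)
    foot = _disk_footprint(min_distance)
    local_max = ndimage.maximum_filter(processed, footprint=foot, mode="constant", cval=0.0)
    candidate = (processed > 0) & (processed == local_max)
    if not candidate.any():
        return DetectionSet(xi=xi)
    # collapse equal-valued plateaus: label connected candidate pixels that
    # share a value, take each component's centroid
    labels, n = ndimage.label(candidate)
    points, scores = [], []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        vals = processed[rows, cols]
        if not np.allclose(vals, vals[0]):
            # mixed-value component: each pixel is individually a maximum of
            # its own neighborhood; keep them all
            for r, c in zip(rows, cols):
                points.append((float(r), float(c)))
                scores.append(float(processed[r, c]))
        else:
            points.append((float(rows.mean()), float(cols.mean())))
            scores.append(float(vals[0]))
    order = np.argsort([-s for s in scores], kind="stable")
    return DetectionSet(
        points=[points[i] for i in order], scores=[scores[i] for i in order], xi=xi
    )
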