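"""Proximity-map label encoding.

Point annotations of nucleus centers are turned into dense regression
targets: each pixel stores a value that decays exponentially with the
Euclidean distance to its nearest annotated center,

    y(u, v) = scale * (exp(alpha * (1 - D/d)) - 1) / (exp(alpha) - 1)   if D <= d
    y(u, v) = 0                                                         otherwise

where D is the distance from pixel (u, v) to the closest center, ``d`` caps
the support of each nucleus and ``alpha`` controls the decay.  The map is
exactly ``scale`` at a center and falls continuously to zero at distance
``d``; everything farther than ``d`` from all centers is zero, so a dominant
portion of each map is background.  Distances are computed exactly from
integer pixel centers to the real-valued annotation points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ProximityEncodingParams", "ProximityMap", "proximity_map", "mean_proximity"]


@dataclass(frozen=True)
class ProximityEncodingParams:
    """Hyperparameters of the proximity encoding.

    alpha : decay control (dimensionless), > 0
    d     : distance threshold in pixels; support radius of each nucleus
    scale : multiplicative factor applied to the unit-range proximity values
            to ease regression training
    """

    alpha: float = 3.0
    d: float = 15.0
    scale: float = 5.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.d > 0 and self.scale > 0):
            raise ValueError(
                f"alpha, d and scale must all be positive, got "
                f"alpha={self.alpha}, d={self.d}, scale={self.scale}"
            )


@dataclass
class ProximityMap:
    """A 2-D real-valued proximity map.

    ``params`` is set for gold-standard maps and ``None`` for maps predicted
    by the network (predictions are not clipped to the gold value range).
    """

    values: np.ndarray
    params: Optional[ProximityEncodingParams] = field(default=None)

    @property
    def shape(self):
        return self.values.shape

    def save_tiff(self, path) -> None:
        """Serialize as a single-channel 32-bit float TIFF."""
        import tifffile

        tifffile.imwrite(str(path), self.values.astype(np.float32))

    @staticmethod
    def load_tiff(path) -> "ProximityMap":
        import tifffile

        return ProximityMap(np.asarray(tifffile.imread(str(path)), dtype=np.float32))


def proximity_values(distances: np.ndarray, params: ProximityEncodingParams) -> np.ndarray:
    """Apply the encoding transfer function to an array of distances."""
    dist = np.asarray(distances, dtype=np.float64)
    inside = dist <= params.d
    out = np.zeros_like(dist)
    num = np.expm1(params.alpha * (1.0 - dist[inside] / params.d))
    out[inside] = params.scale * num / np.expm1(params.alpha)
    return out


def proximity_map(
    centers: Sequence[tuple[float, float]],
    height: int,
    width: int,
    params: ProximityEncodingParams = ProximityEncodingParams(),
) -> ProximityMap:
    """Encode nucleus centers as a gold-standard proximity map.

    Parameters
    ----------
    centers : sequence of (row, col)
        Real-valued nucleus centers, 0-based, pixel centers at integer
        coordinates.  May be empty, in which case the map is all zero.
    height, width : int
        Spatial size of the map.
    params : ProximityEncodingParams
        Encoding hyperparameters.
    """
    pts = np.asarray(list(centers), dtype=np.float64).reshape(-1, 2)
    if pts.size:
        if not np.all(np.isfinite(pts)):
            raise ValueError("centers must be finite")
        if (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > height - 1
            or pts[:, 1].max() > width - 1
        ):
            raise ValueError("centers must lie within the image bounds")
    if len(pts) == 0:
        return ProximityMap(np.zeros((height, width)), params)
    rows, cols = np.mgrid[0:height, 0:width]
    grid = np.column_stack([rows.ravel(), cols.ravel()]).astype(np.float64)
    # exact nearest-center Euclidean distance for every pixel
    dist, _ = cKDTree(pts).query(grid, k=1)
    return ProximityMap(proximity_values(dist.reshape(height, width), params), params)


def mean_proximity(pmap: ProximityMap | np.ndarray) -> float:
    """Arithmetic mean of the map over all pixels (the per-image ȳ that the
    weighted loss uses to balance foreground against background)."""
    values = pmap.values if isinstance(pmap, ProximityMap) else np.asarray(pmap)
    if values.size == 0:
        raise ValueError("cannot take the mean of an empty map")
    return float(values.mean())
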