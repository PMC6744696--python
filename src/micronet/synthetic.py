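"""Seeded generator of H&E-like microscopy tiles with known nucleus centers.

Real nucleus-detection corpora are point-annotated crops of hematoxylin and
eosin stained tissue.  This module emulates their testable structure:
elliptical hematoxylin-dark nuclei of varying scale and orientation,
rendered with anti-aliased edges and a radial intensity falloff over an
eosin-pink background with low-frequency texture and per-pixel noise.
"Organ styles" (stain hue, nucleus density, size distribution) make
cross-style and mixed-style training experiments meaningful, standing in
for the multi-organ structure of real archives.

Every sample is fully determined by its seed, and every generated image
carries its exact sub-pixel center list, so downstream detection and
matching can be scored against known ground truth.

Not a physically realistic stain simulator: there is no cytoplasm
segmentation, chromatin texture, or slide-level illumination field.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

__all__ = [
    "SynthStyle",
    "SynthSample",
    "generate_image",
    "generate_dataset",
    "generate_multistyle_corpus",
    "split_dataset",
    "default_styles",
    "write_corpus",
]


@dataclass(frozen=True)
class SynthStyle:
    """One "organ style": the knobs controlling appearance and geometry.

    All colors are 8-bit RGB.  ``overlap_fraction`` is the target fraction
    of nuclei placed touching an existing nucleus; the remaining nuclei are
    placed with pairwise distance at least the sum of their radii.
    """

    style_id: str = "default"
    nucleus_count_range: tuple[int, int] = (8, 14)
    radius_range: tuple[float, float] = (4.0, 7.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    nucleus_color: tuple[int, int, int] = (92, 58, 138)  # hematoxylin purple
    nucleus_color_jitter: float = 14.0
    background_color: tuple[int, int, int] = (226, 188, 206)  # eosin pink
    background_texture_amp: float = 16.0
    overlap_fraction: float = 0.1
    noise_sd: float = 6.0
    # background clutter: non-annotated eosin-dark structures (stromal
    # debris, cytoplasm clumps) that a detector must learn to ignore
    distractor_count_range: tuple[int, int] = (8, 14)
    distractor_color: tuple[int, int, int] = (152, 100, 130)
    distractor_opacity: float = 0.9

    def __post_init__(self):
        lo, hi = self.nucleus_count_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid nucleus_count_range {self.nucleus_count_range}")
        if self.radius_range[0] < 2:
            raise ValueError("minimum nucleus radius must be >= 2 px")
        if self.radius_range[1] < self.radius_range[0]:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if not (0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1):
            raise ValueError(f"invalid eccentricity_range {self.eccentricity_range}")
        for c in (*self.nucleus_color, *self.background_color):
            if not 0 <= c <= 255:
                raise ValueError("color channels must be in [0, 255]")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError(f"overlap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        dlo, dhi = self.distractor_count_range
        if dlo < 0 or dhi < dlo:
            raise ValueError(f"invalid distractor_count_range {self.distractor_count_range}")
        for c in self.distractor_color:
            if not 0 <= c <= 255:
                raise ValueError("color channels must be in [0, 255]")
        if not 0.0 <= self.distractor_opacity <= 1.0:
            raise ValueError("distractor_opacity must be in [0, 1]")


@dataclass
class SynthSample:
    """A rendered tile: image, its exact nucleus centers (row, col; 0-based,
    sub-pixel), and the geometry used to render them."""

    image: np.ndarray
    centers: list[tuple[float, float]]
    style_id: str
    seed: int
    image_id: str = ""
    radii: list[float] = field(default_factory=list)

    @property
    def shape(self):
        return self.image.shape


def default_styles() -> list[SynthStyle]:
    """Three contrasting organ styles for cross-style experiments: the
    default purple-on-pink, a denser small-nucleus blue style, and a sparse
    large-nucleus dark style."""
    return [
        SynthStyle(style_id="styleA"),
        SynthStyle(
            style_id="styleB",
            nucleus_count_range=(12, 18),
            radius_range=(3.0, 5.0),
            nucleus_color=(45, 75, 170),
            background_color=(242, 218, 234),
        ),
        SynthStyle(
            style_id="styleC",
            nucleus_count_range=(4, 8),
            radius_range=(6.0, 9.0),
            nucleus_color=(70, 40, 90),
            background_color=(218, 175, 190),
            overlap_fraction=0.2,
        ),
    ]


def _place_centers(style: SynthStyle, height: int, width: int, rng: np.random.Generator):
    """Dart-throwing placement.  Non-overlap nuclei keep pairwise distance
    >= r_i + r_j; the overlap fraction is produced by perturbing existing
    centers so the pair touches."""
    lo, hi = style.nucleus_count_range
    count = int(rng.integers(lo, hi + 1))
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    n_overlap = int(round(style.overlap_fraction * count)) if count > 1 else 0
    margin = 1.0
    for i in range(count):
        r = float(rng.uniform(*style.radius_range))
        if centers and i >= count - n_overlap:
            j = int(rng.integers(len(centers)))
            for _ in range(50):
                theta = rng.uniform(0, 2 * np.pi)
                dist = 0.85 * (radii[j] + r)
                cy = centers[j][0] + dist * np.sin(theta)
                cx = centers[j][1] + dist * np.cos(theta)
                if margin <= cy <= height - 1 - margin and margin <= cx <= width - 1 - margin:
                    break
            else:
                cy = float(np.clip(centers[j][0], margin, height - 1 - margin))
                cx = float(np.clip(centers[j][1], margin, width - 1 - margin))
            centers.append((float(cy), float(cx)))
            radii.append(r)
            continue
        placed = False
        for _ in range(400):
            cy = rng.uniform(margin, height - 1 - margin)
            cx = rng.uniform(margin, width - 1 - margin)
            if all(
                np.hypot(cy - oy, cx - ox) >= r + orad
                for (oy, ox), orad in zip(centers, radii)
            ):
                centers.append((float(cy), float(cx)))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {count} non-overlapping nuclei of radius "
                f"~{r:.1f} in a {height}x{width} tile; reduce the count or radius"
            )
    return centers, radii


def _background(style: SynthStyle, height: int, width: int, rng: np.random.Generator):
    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = style.background_color
    if style.background_texture_amp > 0:
        # low-frequency luminance texture: coarse noise upsampled and smoothed
        gh, gw = max(2, height // 16), max(2, width // 16)
        coarse = rng.normal(0.0, 1.0, (gh, gw))
        tex = zoom(coarse, (height / gh, width / gw), order=1, mode="nearest")
        tex = gaussian_filter(tex, 2.0)[:height, :width]
        sd = tex.std()
        if sd > 0:
            tex = tex / sd * style.background_texture_amp
        img += tex[:, :, None] * np.array([0.9, 1.0, 0.95])
    return img


def _render_nucleus(img, cy, cx, r, ecc, theta, color, rng, opacity=1.0):
    """Anti-aliased filled ellipse with a radial intensity falloff (darker
    core, slightly lighter rim)."""
    b = r * np.sqrt(1.0 - ecc**2)  # minor semi-axis
    pad = int(np.ceil(r)) + 2
    h, w = img.shape[:2]
    y0, y1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dy * ct + dx * st
    v = -dy * st + dx * ct
    rho = np.sqrt((u / r) ** 2 + (v / b) ** 2)  # normalized elliptical radius
    coverage = opacity * np.clip((1.0 - rho) / 0.25, 0.0, 1.0)  # soft 0.25-wide edge
    falloff = 0.8 + 0.35 * np.clip(rho, 0.0, 1.0) ** 2
    tile = img[y0:y1, x0:x1]
    nucleus = np.asarray(color, dtype=np.float64) * falloff[:, :, None]
    img[y0:y1, x0:x1] = tile * (1 - coverage[:, :, None]) + nucleus * coverage[:, :, None]


def generate_image(style: SynthStyle, height: int, width: int, seed: int) -> SynthSample:
    """Render one tile.  Deterministic given (style, size, seed)."""
    if height < 32 or width < 32:
        raise ValueError(f"tile size must be at least 32x32, got {height}x{width}")
    if style.radius_range[1] > min(height, width) / 2:
        raise ValueError(
            f"radius_range {style.radius_range} exceeds half the tile size "
            f"min({height},{width})/2; nuclei would not fit"
        )
    rng = np.random.default_rng(seed)
    centers, radii = _place_centers(style, height, width, rng)
    img = _background(style, height, width, rng)
    # clutter first, nuclei on top
    dlo, dhi = style.distractor_count_range
    for _ in range(int(rng.integers(dlo, dhi + 1))):
        dy = rng.uniform(1.0, height - 2.0)
        dx = rng.uniform(1.0, width - 2.0)
        dr = rng.uniform(0.6 * style.radius_range[0], 1.1 * style.radius_range[1])
        ecc = rng.uniform(*style.eccentricity_range)
        theta = rng.uniform(0, np.pi)
        color = np.clip(
            np.asarray(style.distractor_color, dtype=np.float64) + rng.normal(0.0, 12.0, 3),
            0,
            255,
        )
        _render_nucleus(img, dy, dx, dr, ecc, theta, color, rng, style.distractor_opacity)
    for (cy, cx), r in zip(centers, radii):
        ecc = rng.uniform(*style.eccentricity_range)
        theta = rng.uniform(0, np.pi)
        color = np.clip(
            np.asarray(style.nucleus_color, dtype=np.float64)
            + rng.normal(0.0, style.nucleus_color_jitter, 3),
            0,
            255,
        )
        _render_nucleus(img, cy, cx, r, ecc, theta, color, rng)
    if style.noise_sd > 0:
        img += rng.normal(0.0, style.noise_sd, img.shape)
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SynthSample(
        image=image,
        centers=centers,
        style_id=style.style_id,
        seed=seed,
        image_id=f"{style.style_id}_{seed}",
        radii=radii,
    )


def generate_dataset(
    style: SynthStyle, n_images: int, height: int, width: int, seed: int
) -> list[SynthSample]:
    """Generate ``n_images`` tiles with per-sample seeds derived
    deterministically from the master seed."""
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_images)
    samples = []
    for i, s in enumerate(child_seeds):
        sample = generate_image(style, height, width, int(s))
        sample.image_id = f"{style.style_id}_{i:04d}"
        samples.append(sample)
    return samples


def split_dataset(samples: Sequence, seed: int, val_fraction: float = 0.2):
    """Randomly split a corpus into two halves (train pool / test), then set
    aside ``val_fraction`` of the training pool as validation.

    Returns (train, val, test); the three sets are pairwise disjoint.
    """
    n = len(samples)
    order = np.random.default_rng(seed).permutation(n)
    n_test = n // 2
    test = [samples[i] for i in order[:n_test]]
    pool = [samples[i] for i in order[n_test:]]
    n_val = int(round(val_fraction * len(pool)))
    val = pool[:n_val]
    train = pool[n_val:]
    return train, val, test


def generate_multistyle_corpus(
    styles: Sequence[SynthStyle], n_per_style: int, height: int, width: int, seed: int
) -> dict[str, list[SynthSample]]:
    """Independent seeded corpora per style, keyed by style_id; the raw
    material for target-versus-auxiliary pooling experiments."""
    if len(styles) < 2:
        raise ValueError("need at least 2 styles for a multi-style corpus")
    ids = [s.style_id for s in styles]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate style_ids: {ids}")
    rng = np.random.default_rng(seed)
    corpus = {}
    for style in styles:
        corpus[style.style_id] = generate_dataset(
            style, n_per_style, height, width, int(rng.integers(0, 2**31 - 1))
        )
    return corpus


def write_corpus(samples: Sequence[SynthSample], out_dir, fmt: str = "png") -> Path:
    """Write images (8-bit RGB PNG or TIFF) plus a single ``centers.csv``
    with header ``image_id,x,y`` (x = column, y = row, 0-based, real)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "centers.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for s in samples:
            iio.imwrite(out / f"{s.image_id}.{fmt}", s.image)
            for (row, col) in s.centers:
                writer.writerow([s.image_id, f"{col:.6f}", f"{row:.6f}"])
    return out
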