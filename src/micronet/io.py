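"""Readers, writers, experiment configuration and orchestration.

Repo-wide coordinate convention: annotations and detections are stored in
CSV with header ``image_id,x,y`` where x is the column index and y the row
index, both 0-based and real-valued, with pixel centers at integer
coordinates.  Images are 8-bit RGB PNG or TIFF; grayscale inputs are
replicated to three channels with a warning.  Proximity maps serialize as
32-bit float TIFF.  Every experiment directory gets a manifest listing its
artifacts with content hashes, and all randomness flows from the config
seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .labels import ProximityEncodingParams
from .losses import LossParams
from .model import NetworkSpec

__all__ = [
    "AnnotatedImage",
    "ExperimentConfig",
    "read_annotations",
    "write_annotations",
    "write_detections",
    "read_image",
    "load_corpus",
    "run_experiment",
]


@dataclass
class AnnotatedImage:
    """An RGB tile with its gold-standard nucleus centers (row, col)."""

    image_id: str
    image: np.ndarray
    centers: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        h, w = self.image.shape[:2]
        for r, c in self.centers:
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise ValueError(
                    f"center ({r}, {c}) outside the {h}x{w} bounds of {self.image_id!r}"
                )


def read_annotations(path) -> dict[str, list[tuple[float, float]]]:
    """Read a ``image_id,x,y`` CSV into a mapping image_id -> [(row, col)].

    Malformed rows are reported with their line number; negative
    coordinates are rejected.
    """
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != ["image_id", "x", "y"]:
            raise ValueError(f"{path}: expected header 'image_id,x,y', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            image_id = row[0].strip()
            try:
                x, y = float(row[1]), float(row[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate: {exc}") from None
            if not np.isfinite([x, y]).all():
                raise ValueError(f"{path}:{lineno}: non-finite coordinate")
            if x < 0 or y < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate ({x}, {y})")
            out.setdefault(image_id, []).append((y, x))  # store as (row, col)
    return out


def write_annotations(mapping: dict[str, Sequence[tuple[float, float]]], path) -> None:
    """Inverse of :func:`read_annotations` (centers given as (row, col))."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y"])
        for image_id, centers in mapping.items():
            for r, c in centers:
                writer.writerow([image_id, f"{c:.6f}", f"{r:.6f}"])


def write_detections(rows, path) -> None:
    """Write ``image_id,x,y,score`` detection rows; ``rows`` is an iterable
    of (image_id, DetectionSet)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "x", "y", "score"])
        for image_id, dets in rows:
            for (r, c), s in zip(dets.points, dets.scores):
                writer.writerow([image_id, f"{c:.6f}", f"{r:.6f}", f"{s:.6f}"])


def read_detections(path) -> dict[str, list[tuple[float, float]]]:
    """Read a detections CSV back into image_id -> [(row, col)] (scores are
    not needed for matching)."""
    out: dict[str, list[tuple[float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.setdefault(row["image_id"], []).append((float(row["y"]), float(row["x"])))
    return out


def read_image(path) -> np.ndarray:
    """Load an 8-bit image as HxWx3 RGB; grayscale is replicated with a
    warning, an alpha channel is dropped."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)))
    if img.ndim == 2:
        warnings.warn(f"{path}: grayscale image replicated to 3 channels")
        img = np.repeat(img[:, :, None], 3, axis=2)
    elif img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def load_corpus(images_dir, annotations_csv) -> list[AnnotatedImage]:
    """Pair every image file in a directory with its annotation rows
    (images with no rows get empty center lists)."""
    mapping = read_annotations(annotations_csv)
    out = []
    for p in sorted(Path(images_dir).iterdir()):
        if p.suffix.lower() not in (".png", ".tif", ".tiff"):
            continue
        out.append(AnnotatedImage(p.stem, read_image(p), mapping.get(p.stem, [])))
    return out


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Everything one reproducible experiment needs.

    Cross-field consistency is enforced: the proximity-encoding scale must
    equal the network's output scale.
    """

    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(base_width=8))
    encoding: ProximityEncodingParams = field(default_factory=ProximityEncodingParams)
    loss: LossParams = field(default_factory=LossParams)
    training: dict = field(default_factory=dict)  # TrainConfig overrides
    profile: str = "desk"
    seed: int = 0
    # evaluation
    radius: float = 16.0
    xi_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    min_distance: int = 6
    # data: synthetic corpus declaration
    height: int = 64
    width: int = 64
    n_per_style: int = 60
    styles: Optional[list[dict]] = None  # None -> default_styles()
    target_style: str = "styleA"
    auxiliary_styles: tuple[str, ...] = ()
    aux_fraction: float = 1.0
    frozen_blocks: int = 0
    base_checkpoint: Optional[str] = None

    def __post_init__(self):
        if self.encoding.scale != self.network.output_scale:
            raise ValueError(
                f"encoding.scale ({self.encoding.scale}) must equal "
                f"network.output_scale ({self.network.output_scale})"
            )
        if self.profile not in ("desk", "full"):
            raise ValueError(f"profile must be 'desk' or 'full', got {self.profile!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        if "network" in kw:
            kw["network"] = NetworkSpec(**kw["network"])
        if "encoding" in kw:
            kw["encoding"] = ProximityEncodingParams(**kw["encoding"])
        if "loss" in kw:
            kw["loss"] = LossParams(**kw["loss"])
        if "xi_grid" in kw:
            kw["xi_grid"] = tuple(kw["xi_grid"])
        if "auxiliary_styles" in kw:
            kw["auxiliary_styles"] = tuple(kw["auxiliary_styles"])
        known = {f.name for f in fields(cls)}
        unknown = set(kw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xi_grid"] = list(self.xi_grid)
        d["auxiliary_styles"] = list(self.auxiliary_styles)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_train_config(cfg: ExperimentConfig):
    from .training import desk_profile, full_profile

    overrides = dict(cfg.training)
    overrides.setdefault("seed", cfg.seed)
    overrides.setdefault("xi_grid", cfg.xi_grid)
    overrides.setdefault("eval_radius", cfg.radius)
    overrides.setdefault("min_distance", cfg.min_distance)
    maker = desk_profile if cfg.profile == "desk" else full_profile
    return maker(**overrides)


def run_experiment(config, out_dir, progress: bool = False) -> Path:
    """Run one config-driven experiment end to end.

    Generates the synthetic corpora, trains (from scratch, fine-tuned, or
    with an auxiliary source per the config), selects xi on validation,
    detects on the held-out test images, and writes checkpoint, logs,
    detections, report, PR curve, the resolved config and a hashed
    manifest into ``out_dir``.
    """
    from .evaluation import metrics, match, pooled_metrics, pr_curve, select_xi
    from .inference import detect, predict_batch
    from .model import build_network, save_checkpoint
    from .synthetic import SynthStyle, default_styles, generate_multistyle_corpus, split_dataset
    from .training import DataSource, fine_tune, train

    if not isinstance(config, ExperimentConfig):
        config = ExperimentConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    styles = (
        default_styles()
        if config.styles is None
        else [SynthStyle(**s) for s in config.styles]
    )
    corpus = generate_multistyle_corpus(
        styles, config.n_per_style, config.height, config.width, config.seed
    )
    if config.target_style not in corpus:
        raise ValueError(f"target_style {config.target_style!r} not among the styles")
    train_set, val_set, test_set = split_dataset(corpus[config.target_style], config.seed)
    auxiliary = None
    if config.auxiliary_styles:
        pooled = [s for sid in config.auxiliary_styles for s in corpus[sid]]
        auxiliary = DataSource(pooled, role="auxiliary", fraction=config.aux_fraction)

    tc = _build_train_config(config)
    target = DataSource(train_set, role="target")
    if config.base_checkpoint is not None:
        network, history = fine_tune(
            config.base_checkpoint,
            target,
            config=tc,
            frozen_blocks=config.frozen_blocks,
            loss_params=config.loss,
            encoding=config.encoding,
            validation=val_set,
            progress=progress,
        )
    else:
        network = build_network(config.network, seed=config.seed)
        network, history = train(
            network,
            target,
            auxiliary=auxiliary,
            config=tc,
            loss_params=config.loss,
            encoding=config.encoding,
            validation=val_set,
            progress=progress,
        )

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    save_checkpoint(network, out / "checkpoint.npz", encoding=config.encoding, train_seed=config.seed)
    with open(out / "history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "loss", "lr", "val_f1"])
        for h in history:
            writer.writerow([h["iteration"], h["loss"], h["lr"], h["val_f1"]])

    xi = select_xi(network, val_set, config.xi_grid, config.radius, config.min_distance)
    maps = predict_batch(network, [s.image for s in test_set])
    det_rows = [(s.image_id, detect(m, xi, config.min_distance)) for s, m in zip(test_set, maps)]
    write_detections(det_rows, out / "detections.csv")
    write_annotations({s.image_id: s.centers for s in test_set}, out / "annotations.csv")

    reports = [
        match(dets, s.centers, config.radius) for (_, dets), s in zip(det_rows, test_set)
    ]
    pooled = pooled_metrics(reports)
    per_image = {
        s.image_id: asdict(metrics(r)) for s, r in zip(test_set, reports)
    }
    report = {
        "selected_xi": xi,
        "pooled": asdict(pooled),
        "per_image": per_image,
        "n_train": len(train_set),
        "n_val": len(val_set),
        "n_test": len(test_set),
        "seed": config.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)

    curve = pr_curve(network, test_set, config.xi_grid, config.radius, config.min_distance)
    with open(out / "pr_curve.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["xi", "precision", "recall"])
        writer.writerows(curve)

    manifest = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
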