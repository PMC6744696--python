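"""Model training: patch sampling, augmentation, and the optimization loop.

Training follows the standard recipe for dense regression on annotated
tiles: patches are cropped dynamically each iteration (never materialized
as a dataset), normalized per channel, and augmented with a geometric
transform applied identically to the image and its proximity-map label.
Optimization is stochastic gradient descent with Nesterov momentum; the
learning rate decays by ``lr_decay_factor`` whenever pooled validation F1
(at the best threshold xi on a small grid) has not improved for
``patience_iterations``, stopping the decay once it would drop below
``lr_floor``.

Mixed-source training draws a batch from the target source and one from the
auxiliary source each iteration and minimizes

    (gamma * sum_T loss_i + sum_A loss_i) / (n_T + n_A)

which at gamma = 1 is exactly the naive pooling of the two sources.  The
per-pixel loss weight of a patch uses the mean proximity of its *full
source image*, so background-only crops of annotated images retain their
penalty (see `micronet.losses`).

The per-image loss, by default, is normalized by the pixel count.  Two
named configurations are provided: the full-scale profile used on real
500x500 tiles, and a desk-scale profile (base-width-8 network, 64x64
tiles) small enough to train end-to-end on one CPU in minutes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from . import _autograd as ag
from .evaluation import GOLD_RADIUS, _evaluate_grid
from .labels import ProximityEncodingParams, proximity_map
from .losses import LossParams, loss_weights
from .model import MicroNet, freeze_blocks, load_checkpoint

__all__ = [
    "TrainConfig",
    "DataSource",
    "desk_profile",
    "full_profile",
    "crop_patches",
    "normalize_patch",
    "augment",
    "train",
    "fine_tune",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and data-pipeline hyperparameters (full-scale defaults)."""

    lr: float = 0.01
    momentum: float = 0.9  # Nesterov
    weight_decay: float = 1e-6
    batch_size: int = 4
    max_iterations: int = 100_000
    lr_decay_factor: float = 10.0
    patience_iterations: int = 10_000
    lr_floor: float = 1e-4
    patch_size: int = 200
    patches_per_image: int = 4
    snapshot_every: int = 2000
    val_interval: int = 1000
    seed: int = 0
    # augmentation
    shift_max: int = 8
    elastic_spacing: int = 32
    elastic_magnitude: float = 8.0
    elastic_sigma: float = 4.0
    arbitrary_rotation: bool = False
    # validation threshold grid and matching
    xi_grid: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    eval_radius: float = GOLD_RADIUS
    min_distance: int = 6
    aux_batch_size: Optional[int] = None  # defaults to batch_size

    def __post_init__(self):
        for name in (
            "lr",
            "momentum",
            "batch_size",
            "max_iterations",
            "lr_decay_factor",
            "patience_iterations",
            "lr_floor",
            "patch_size",
            "patches_per_image",
            "snapshot_every",
            "val_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0 or self.shift_max < 0 or self.elastic_magnitude < 0:
            raise ValueError("weight_decay, shift_max and elastic_magnitude must be >= 0")


@dataclass
class DataSource:
    """A pool of annotated images with a training role.

    ``fraction`` subsamples the pool (round(f * N) images, drawn
    deterministically under the training seed) for mixing experiments.
    """

    samples: list
    role: str = "target"
    fraction: float = 1.0

    def __post_init__(self):
        if self.role not in ("target", "auxiliary"):
            raise ValueError(f"role must be 'target' or 'auxiliary', got {self.role!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.role == "target" and not self.samples:
            raise ValueError("target source must be non-empty")


def desk_profile(**overrides) -> TrainConfig:
    """CPU-sized configuration: 64x64 tiles, one patch per image draw, short
    schedule.  Used throughout the test-suite and the worked examples."""
    base = dict(
        max_iterations=600,
        patch_size=64,
        patches_per_image=1,
        val_interval=150,
        patience_iterations=450,
        snapshot_every=300,
        elastic_magnitude=4.0,
        shift_max=4,
    )
    base.update(overrides)
    return TrainConfig(**base)


def full_profile(**overrides) -> TrainConfig:
    """The full-scale profile (500x500 tiles, 1e5 iterations)."""
    return TrainConfig(**overrides)


# ---------------------------------------------------------------------------
# patch pipeline
# ---------------------------------------------------------------------------


def crop_patches(
    image: np.ndarray,
    label: np.ndarray,
    patch_size: int,
    n_patches: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Randomly crop ``n_patches`` aligned (image, label) patch pairs.

    Images smaller than the patch size are reflect-padded first.  When the
    patch size equals the image size the crop is the identity.
    """
    h, w = image.shape[:2]
    ph, pw = max(0, patch_size - h), max(0, patch_size - w)
    if ph or pw:
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        label = np.pad(label, ((0, ph), (0, pw)), mode="reflect")
        h, w = image.shape[:2]
    pairs = []
    for _ in range(n_patches):
        r = int(rng.integers(0, h - patch_size + 1))
        c = int(rng.integers(0, w - patch_size + 1))
        pairs.append(
            (
                image[r : r + patch_size, c : c + patch_size],
                label[r : r + patch_size, c : c + patch_size],
            )
        )
    return pairs


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Per-channel zero-mean / unit-sd normalization of one HxWx3 patch.
    A constant channel maps to all zeros."""
    x = np.asarray(patch, dtype=np.float32)
    if x.ndim != 3 or x.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 patch, got shape {x.shape}")
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    return (x - mean) / np.maximum(sd, np.float32(1e-6))


def _elastic_field(shape, spacing, magnitude, sigma, rng):
    gh = max(2, int(np.ceil(shape[0] / spacing)) + 1)
    gw = max(2, int(np.ceil(shape[1] / spacing)) + 1)
    field_ = rng.normal(0.0, 1.0, (2, gh, gw))
    disp = np.stack(
        [
            gaussian_filter(
                zoom(field_[i], (shape[0] / gh, shape[1] / gw), order=1, mode="nearest")[
                    : shape[0], : shape[1]
                ],
                sigma,
            )
            for i in range(2)
        ]
    )
    peak = np.abs(disp).max()
    if peak > 0:
        disp *= magnitude / peak
    return disp


def augment(
    image: np.ndarray,
    label: np.ndarray,
    rng: np.random.Generator | int,
    shift_max: int = 8,
    elastic_spacing: int = 32,
    elastic_magnitude: float = 8.0,
    elastic_sigma: float = 4.0,
    arbitrary_rotation: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to an image patch
    and its label patch.

    The transform is a composition of a dihedral-group element (right-angle
    rotation plus optional mirroring — exact, no interpolation), a shift of
    up to ``shift_max`` pixels with reflect padding, and an elastic
    distortion from a smoothed random displacement field.  Arbitrary-angle
    rotation (interpolating) is available behind ``arbitrary_rotation``.
    An identity draw returns the pair unchanged.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    img, lab = np.asarray(image), np.asarray(label)

    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    if k:
        img = np.rot90(img, k, axes=(0, 1))
        lab = np.rot90(lab, k, axes=(0, 1))
    if flip:
        img = img[:, ::-1]
        lab = lab[:, ::-1]

    if arbitrary_rotation:
        from scipy.ndimage import rotate

        angle = float(rng.uniform(0.0, 360.0))
        img = rotate(img, angle, axes=(0, 1), reshape=False, order=1, mode="reflect")
        lab = rotate(lab, angle, axes=(0, 1), reshape=False, order=1, mode="reflect")

    if shift_max > 0:
        dy, dx = (int(v) for v in rng.integers(-shift_max, shift_max + 1, 2))
        if dy or dx:
            s = shift_max
            pimg = np.pad(img, ((s, s), (s, s), (0, 0)), mode="reflect")
            plab = np.pad(lab, ((s, s), (s, s)), mode="reflect")
            h, w = img.shape[:2]
            img = pimg[s + dy : s + dy + h, s + dx : s + dx + w]
            lab = plab[s + dy : s + dy + h, s + dx : s + dx + w]

    if elastic_magnitude > 0:
        disp = _elastic_field(lab.shape, elastic_spacing, elastic_magnitude, elastic_sigma, rng)
        rows, cols = np.mgrid[0 : lab.shape[0], 0 : lab.shape[1]].astype(np.float64)
        coords = np.stack([rows + disp[0], cols + disp[1]])
        lab = map_coordinates(lab.astype(np.float64), coords, order=1, mode="reflect")
        img = np.stack(
            [
                map_coordinates(img[..., c].astype(np.float64), coords, order=1, mode="reflect")
                for c in range(img.shape[2])
            ],
            axis=2,
        )
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class _NesterovSGD:
    def __init__(self, params, lr, momentum, weight_decay):
        self.params = list(params)
        self.lr, self.mu, self.wd = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if not p.requires_grad or p.grad is None:
                continue
            d = p.grad.astype(p.data.dtype, copy=False)
            if self.wd:
                d = d + self.wd * p.data
            v *= self.mu
            v += d
            p.data -= self.lr * (d + self.mu * v)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------


class _Prepared:
    """Per-image cache: float image, gold map, and the full-image mean
    proximity used as the loss-weight baseline for every crop of it."""

    __slots__ = ("image", "label", "y_bar")

    def __init__(self, sample, encoding):
        self.image = np.asarray(sample.image, dtype=np.float32)
        pm = proximity_map(
            sample.centers, self.image.shape[0], self.image.shape[1], encoding
        )
        self.label = pm.values.astype(np.float32)
        self.y_bar = float(pm.values.mean())


def _draw_batch(prepared, n, config, rng):
    """Dynamically crop and augment ``n`` patches; returns stacked arrays
    plus each patch's source-image y_bar."""
    xs, ys, ybars = [], [], []
    while len(xs) < n:
        src = prepared[int(rng.integers(len(prepared)))]
        k = min(config.patches_per_image, n - len(xs))
        for img, lab in crop_patches(src.image, src.label, config.patch_size, k, rng):
            img, lab = augment(
                img,
                lab,
                rng,
                shift_max=config.shift_max,
                elastic_spacing=config.elastic_spacing,
                elastic_magnitude=config.elastic_magnitude,
                elastic_sigma=config.elastic_sigma,
                arbitrary_rotation=config.arbitrary_rotation,
            )
            xs.append(normalize_patch(img).transpose(2, 0, 1))
            ys.append(lab.astype(np.float32))
            ybars.append(src.y_bar)
    x = np.stack(xs).astype(np.float32)
    y = np.stack(ys)[:, None].astype(np.float32)
    return x, y, ybars


def _batch_loss_tensor(out, y, ybars, coefs, lam, normalize_by_pixels):
    """0.5 * sum_i coef_i * sum_uv w_i(uv) (o - y)^2 [/ npix] as one tape op."""
    npix = y.shape[2] * y.shape[3]
    w = np.empty_like(y)
    for i in range(y.shape[0]):
        w[i, 0] = loss_weights(y[i, 0].astype(np.float64), lam, ybars[i])
        w[i, 0] *= coefs[i]
    if normalize_by_pixels:
        w /= npix
    resid = ag.sub_const(out, y)
    return ag.mul_const(ag.sum_all(ag.mul_const(ag.mul(resid, resid), w)), 0.5)


def _validation_f1(network, samples, config):
    summaries = _evaluate_grid(
        network, samples, config.xi_grid, config.eval_radius, config.min_distance
    )
    return max(s.f1 for s in summaries)


def _snapshot(network):
    return (
        [p.data.copy() for p in network.parameters()],
        [(bn.running_mean.copy(), bn.running_var.copy()) for bn in network.batch_norms()],
    )


def _restore(network, snap):
    params, stats = snap
    for p, d in zip(network.parameters(), params):
        p.data = d.copy()
    for bn, (m, v) in zip(network.batch_norms(), stats):
        bn.running_mean, bn.running_var = m.copy(), v.copy()


def subsample(samples: Sequence, fraction: float, rng: np.random.Generator) -> list:
    """Deterministically select round(fraction * N) samples."""
    n = int(round(fraction * len(samples)))
    idx = rng.permutation(len(samples))[:n]
    return [samples[i] for i in sorted(idx)]


def train(
    network: MicroNet,
    target: DataSource,
    auxiliary: Optional[DataSource] = None,
    config: TrainConfig = None,
    loss_params: LossParams = LossParams(),
    encoding: ProximityEncodingParams = ProximityEncodingParams(),
    validation: Optional[Sequence] = None,
    snapshot_dir=None,
    progress: bool = False,
):
    """Run the optimization loop.

    Returns ``(network, history)`` where history is a list of per-iteration
    dicts (iteration, loss, lr, val_f1 — NaN between validations).  If the
    loss diverges to NaN the last snapshot is restored and training stops.
    With ``snapshot_dir`` set, a checkpoint is also written there every
    ``snapshot_every`` iterations (the raw material for early-transfer
    fine-tuning experiments).
    """
    if config is None:
        config = TrainConfig()
    rng = np.random.default_rng(config.seed)

    target_samples = list(target.samples)
    if target.fraction < 1.0:
        target_samples = subsample(target_samples, target.fraction, rng)
    if validation is None:
        # carve a validation fifth off the target pool
        order = rng.permutation(len(target_samples))
        n_val = max(1, int(round(0.2 * len(target_samples))))
        validation = [target_samples[i] for i in order[:n_val]]
        target_samples = [target_samples[i] for i in order[n_val:]]
    if not target_samples:
        raise ValueError("no target training samples left after splitting")

    prep_t = [_Prepared(s, encoding) for s in target_samples]
    prep_a = None
    if auxiliary is not None:
        aux_samples = list(auxiliary.samples)
        if auxiliary.fraction < 1.0:
            aux_samples = subsample(aux_samples, auxiliary.fraction, rng)
        if aux_samples:
            prep_a = [_Prepared(s, encoding) for s in aux_samples]

    opt = _NesterovSGD(
        network.parameters(), config.lr, config.momentum, config.weight_decay
    )
    history: list[dict] = []
    best_f1, best_iter = -1.0, 0
    snap = _snapshot(network)
    aborted = False

    for it in range(1, config.max_iterations + 1):
        xt, yt, ybt = _draw_batch(prep_t, config.batch_size, config, rng)
        if prep_a is not None:
            n_aux = config.aux_batch_size or config.batch_size
            xa, ya, yba = _draw_batch(prep_a, n_aux, config, rng)
            x = np.concatenate([xt, xa])
            y = np.concatenate([yt, ya])
            ybars = ybt + yba
            n_total = x.shape[0]
            coefs = [loss_params.gamma / n_total] * xt.shape[0] + [1.0 / n_total] * xa.shape[0]
        else:
            x, y, ybars = xt, yt, ybt
            coefs = [1.0 / x.shape[0]] * x.shape[0]

        out = network.forward(x, train=True, rng=rng)
        loss = _batch_loss_tensor(
            out, y, ybars, coefs, loss_params.lam, loss_params.normalize_by_pixels
        )
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            _restore(network, snap)
            aborted = True
            history.append(dict(iteration=it, loss=loss_val, lr=opt.lr, val_f1=np.nan))
            break
        ag.backward(loss)
        opt.step()
        opt.zero_grad()

        val_f1 = np.nan
        if it % config.val_interval == 0 or it == config.max_iterations:
            val_f1 = _validation_f1(network, validation, config)
            if val_f1 > best_f1:
                best_f1, best_iter = val_f1, it
            elif it - best_iter >= config.patience_iterations:
                new_lr = opt.lr / config.lr_decay_factor
                if new_lr >= config.lr_floor:
                    opt.lr = new_lr
                    best_iter = it  # restart the patience window
            if progress:
                print(f"iter {it:6d}  loss {loss_val:.5f}  lr {opt.lr:g}  val F1 {val_f1:.3f}")
        if it % config.snapshot_every == 0:
            snap = _snapshot(network)
            if snapshot_dir is not None:
                from pathlib import Path

                from .model import save_checkpoint

                out = Path(snapshot_dir)
                out.mkdir(parents=True, exist_ok=True)
                save_checkpoint(
                    network, out / f"snapshot_{it:06d}.npz", encoding=encoding,
                    train_seed=config.seed,
                )
        history.append(dict(iteration=it, loss=loss_val, lr=opt.lr, val_f1=val_f1))

    if not aborted:
        snap = None  # final weights stand
    return network, history


def fine_tune(
    checkpoint,
    target: DataSource,
    config: TrainConfig = None,
    frozen_blocks: int = 0,
    loss_params: LossParams = LossParams(),
    encoding: ProximityEncodingParams = ProximityEncodingParams(),
    validation: Optional[Sequence] = None,
    expected_spec=None,
    progress: bool = False,
):
    """Initialize from a checkpoint, freeze blocks 1..frozen_blocks, and
    train on the target source.  ``checkpoint`` is a path or a MicroNet."""
    if isinstance(checkpoint, MicroNet):
        network = copy.deepcopy(checkpoint)
        if expected_spec is not None and network.spec != expected_spec:
            raise ValueError("checkpoint spec does not match the expected spec")
    else:
        network, _ = load_checkpoint(checkpoint, expected_spec=expected_spec)
    freeze_blocks(network, frozen_blocks)
    return train(
        network,
        target,
        auxiliary=None,
        config=config,
        loss_params=loss_params,
        encoding=encoding,
        validation=validation,
        progress=progress,
    )
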