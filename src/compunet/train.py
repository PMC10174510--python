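"""Training loop: augmentations, per-plane optimisation, ablation configs.

Each configured plane gets its own independently trained single-planar
2.5D U-Net (no weight sharing).  Every training sample is a 3-slice input
stack from the degraded volume paired with the central slice of the clean
volume; the same randomly drawn flip / rotation / crop is applied to all
three input channels and the target.  Optimisation is Adam at the stated
defaults (100 epochs, learning rate 0.001 at paper scale; the desk-scale
preset trains 5 epochs on 48-pixel crops).

Ablation configurations:
  model1   — single plane (axial), L1 loss only
  model2   — all three planes, L1 loss only
  compunet — all three planes, combined L1 + contextual loss
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .loss import LossConfig, contextual_loss_batched, make_extractor
from .ndl import Adam, Tensor, no_grad
from .net import PLANES, ModelSpec, SliceSample, UNet2p5, slice_to_samples
from .volume import Volume, normalize

#: Samples whose target slice has less than this fraction of voxels above
#: -900 HU are skipped as air-only.
FOREGROUND_FRACTION = 0.02
_FG_THRESHOLD = float(normalize(np.float64(-900.0)))


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 8
    crop_size: int = 240
    rotation_range_deg: float = 90.0
    flip_probability: float = 0.5
    planes: tuple[str, ...] = PLANES
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 0
    max_slices_per_epoch: int | None = None
    val_fraction: float = 0.1

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.crop_size < 16:
            raise ValueError("crop_size must be >= 16")
        bad = [p for p in self.planes if p not in PLANES]
        if bad:
            raise ValueError(f"unknown planes {bad}")
        self.loss.validate()


def desk_scale_config(seed: int = 0, lambda_cx: float = 0.1,
                      planes: tuple[str, ...] = PLANES) -> TrainConfig:
    """The small-problem preset used throughout the test suite:
    64^3 volumes, 48-pixel crops, 5 epochs, 240 slices per epoch."""
    loss = LossConfig(lambda_cx=lambda_cx, max_features=256, seed=seed)
    return TrainConfig(epochs=5, crop_size=48, planes=planes, loss=loss,
                       seed=seed, max_slices_per_epoch=160, val_fraction=0.05)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentParams:
    flip_h: bool
    flip_v: bool
    angle_deg: float
    corner: tuple[int, int]
    crop_size: int


def sample_augment_params(rng: np.random.Generator, shape: tuple[int, int],
                          cfg: TrainConfig) -> AugmentParams:
    h, w = shape
    if cfg.crop_size > h or cfg.crop_size > w:
        raise ValueError(f"crop {cfg.crop_size} larger than slice {h}x{w}")
    return AugmentParams(
        flip_h=bool(rng.random() < cfg.flip_probability),
        flip_v=bool(rng.random() < cfg.flip_probability),
        angle_deg=float(rng.uniform(-cfg.rotation_range_deg,
                                    cfg.rotation_range_deg)),
        corner=(int(rng.integers(0, h - cfg.crop_size + 1)),
                int(rng.integers(0, w - cfg.crop_size + 1))),
        crop_size=cfg.crop_size,
    )


def apply_augment(stack: np.ndarray, target: np.ndarray,
                  p: AugmentParams) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled flip/rotation/crop identically to all channels
    of the input stack and to the target slice."""
    s, t = stack, target
    if p.flip_v:
        s, t = s[:, ::-1, :], t[::-1, :]
    if p.flip_h:
        s, t = s[:, :, ::-1], t[:, ::-1]
    if p.angle_deg != 0.0:
        s = ndimage.rotate(s, p.angle_deg, axes=(1, 2), reshape=False,
                           order=1, mode="reflect")
        t = ndimage.rotate(t, p.angle_deg, axes=(0, 1), reshape=False,
                           order=1, mode="reflect")
    i, j = p.corner
    k = p.crop_size
    return (np.ascontiguousarray(s[:, i:i + k, j:j + k]),
            np.ascontiguousarray(t[i:i + k, j:j + k]))


def augment(stack: np.ndarray, target: np.ndarray, rng: np.random.Generator,
            cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample augmentation parameters and apply them to the pair."""
    p = sample_augment_params(rng, stack.shape[1:], cfg)
    return apply_augment(stack, target, p)


# ---------------------------------------------------------------------------
# fitting


def _sample_pool(dataset, plane: str) -> list[SliceSample]:
    pool: list[SliceSample] = []
    for cbct, mdct in dataset:
        for s in slice_to_samples(cbct, plane, target_vol=mdct):
            if (s.target > _FG_THRESHOLD).mean() >= FOREGROUND_FRACTION:
                pool.append(s)
    if not pool:
        raise ValueError("no usable (non-air) training slices found")
    return pool


def _batch_loss(model, stacks: np.ndarray, targets: np.ndarray,
                loss_cfg: LossConfig, extractor):
    out = model(Tensor(stacks))                        # (B, 1, k, k)
    tgt = Tensor(targets[:, None])
    l1 = (out - tgt).abs().mean()
    if loss_cfg.lambda_cx == 0:
        return l1, l1.item(), 0.0
    pf = extractor.forward_batch(out)
    tf = extractor.forward_batch(tgt)
    terms = [contextual_loss_batched(a, t, loss_cfg).mean()
             for a, t in zip(pf, tf)]
    cx = terms[0]
    for term in terms[1:]:
        cx = cx + term
    cx = cx * (1.0 / len(terms))
    total = l1 + cx * loss_cfg.lambda_cx
    return total, l1.item(), cx.item()


def fit(dataset, model_spec: ModelSpec, cfg: TrainConfig,
        verbose: bool = False) -> tuple[dict[str, UNet2p5], pd.DataFrame]:
    """Train one U-Net per configured plane on (cbct, mdct) volume pairs.

    Volumes are expected co-registered and clipped to the HU window.
    Returns ({plane: model}, history) where history has one row per
    (plane, epoch) with the separate L1 and contextual loss terms.
    Fully reproducible from ``cfg.seed`` on a single device.
    """
    cfg.validate()
    model_spec.validate()
    if len(dataset) < 1:
        raise ValueError("need at least one training pair")
    ss = np.random.SeedSequence(cfg.seed)
    plane_seeds = [int(c.generate_state(1)[0] >> 1)
                   for c in ss.spawn(len(cfg.planes))]
    extractor = make_extractor(cfg.loss) if cfg.loss.lambda_cx > 0 else None

    models: dict[str, UNet2p5] = {}
    rows = []
    for plane, pseed in zip(cfg.planes, plane_seeds):
        rng = np.random.default_rng(pseed)
        model = UNet2p5(replace(model_spec, seed=pseed))
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        pool = _sample_pool(dataset, plane)
        order = rng.permutation(len(pool))
        n_val = int(len(pool) * cfg.val_fraction)
        val_idx, train_idx = order[:n_val], order[n_val:]
        val_samples = [pool[i] for i in val_idx[:16]]
        train_samples = [pool[i] for i in train_idx]

        for epoch in range(cfg.epochs):
            perm = rng.permutation(len(train_samples))
            if cfg.max_slices_per_epoch is not None:
                perm = perm[:cfg.max_slices_per_epoch]
            ep_loss, ep_l1, ep_cx, n_batches = 0.0, 0.0, 0.0, 0
            for start in range(0, len(perm), cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                pairs = [augment(train_samples[i].input_stack,
                                 train_samples[i].target, rng, cfg)
                         for i in idx]
                stacks = np.stack([p[0] for p in pairs]).astype(np.float32)
                targets = np.stack([p[1] for p in pairs]).astype(np.float32)
                model.zero_grad()
                total, l1v, cxv = _batch_loss(model, stacks, targets,
                                              cfg.loss, extractor)
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"NaN/inf loss at plane={plane} epoch={epoch} "
                        f"batch={n_batches} (sample indices {idx.tolist()})")
                total.backward()
                opt.step()
                ep_loss += total.item()
                ep_l1 += l1v
                ep_cx += cxv
                n_batches += 1
            val_l1 = _validate(model, val_samples, cfg) if val_samples else np.nan
            rows.append({"plane": plane, "epoch": epoch,
                         "loss": ep_loss / n_batches, "l1": ep_l1 / n_batches,
                         "cx": ep_cx / n_batches, "val_l1": val_l1})
            if verbose:
                print(f"[{plane}] epoch {epoch}: loss={ep_loss/n_batches:.5f}")
        models[plane] = model
    return models, pd.DataFrame(rows)


def _validate(model, samples, cfg: TrainConfig) -> float:
    errs = []
    with no_grad():
        for s in samples:
            k = cfg.crop_size
            h, w = s.target.shape
            i, j = (h - k) // 2, (w - k) // 2
            stack = s.input_stack[:, i:i + k, j:j + k][None]
            out = model(Tensor(stack)).data[0, 0]
            errs.append(np.abs(out - s.target[i:i + k, j:j + k]).mean())
    return float(np.mean(errs))


def ablation_config(name: str, seed: int = 0,
                    desk_scale: bool = True) -> TrainConfig:
    """Named ablation configuration: 'model1', 'model2' or 'compunet'."""
    presets = {
        "model1": dict(planes=("axial",), lambda_cx=0.0),
        "model2": dict(planes=PLANES, lambda_cx=0.0),
        "compunet": dict(planes=PLANES, lambda_cx=0.1),
    }
    if name not in presets:
        raise ValueError(f"unknown ablation config {name!r}")
    p = presets[name]
    if desk_scale:
        return desk_scale_config(seed=seed, lambda_cx=p["lambda_cx"],
                                 planes=p["planes"])
    return TrainConfig(planes=p["planes"],
                       loss=LossConfig(lambda_cx=p["lambda_cx"], seed=seed),
                       seed=seed)
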