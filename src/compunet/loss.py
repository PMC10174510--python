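"""Combined L1 + contextual objective.

The contextual term compares two *sets* of features rather than pixels at
corresponding locations, which makes it tolerant to the residual spatial
misalignment that survives rigid/affine registration of scans taken in
different postures.  For predicted features {p_i} and target features {t_j}
(mean-centred per set):

    d_ij   = 1 − cos(p_i, t_j)                     cosine distance
    d̃_ij   = d_ij / (min_k d_ik + ε)               normalised distance
    w_ij   = exp((1 − d̃_ij) / h)                   affinity, bandwidth h
    CX_ij  = w_ij / Σ_k w_ik                       row-normalised
    loss   = −log( (1/Np) Σ_j max_i CX_ij )

Identical sets give loss ≈ 0; every row of CX sums to 1.  Features come
from a seeded random convolutional bank by default (three strided stages),
so no pretrained weights are required; raw 3×3 patches and externally
supplied extractors are alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ndl import Tensor

_NORM_FLOOR = 1e-12


@dataclass
class FeatureSet:
    """Spatially indexed feature vectors from one extractor stage."""

    features: np.ndarray   # (N, D)
    layer_id: int = 0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 2:
            raise ValueError("a FeatureSet needs >= 2 feature vectors (N, D)")


@dataclass(frozen=True)
class LossConfig:
    """All knobs of the combined objective."""

    lambda_cx: float = 0.1       # weight of the contextual term
    bandwidth_h: float = 0.5     # affinity temperature h
    epsilon: float = 1e-5        # distance-normalisation stabiliser
    extractor: str = "random-conv"   # or "raw-patches"
    layers: tuple[int, ...] = (0, 1, 2)
    max_features: int = 4096
    seed: int = 0
    patch_size: int = 3

    def validate(self) -> None:
        if self.lambda_cx < 0:
            raise ValueError("lambda_cx must be >= 0")
        if self.bandwidth_h <= 0 or self.epsilon <= 0:
            raise ValueError("bandwidth_h and epsilon must be > 0")
        if self.extractor not in ("random-conv", "raw-patches"):
            raise ValueError(f"unknown extractor {self.extractor!r}")


# ---------------------------------------------------------------------------
# feature extraction


class RandomConvExtractor:
    """Seeded, fixed (non-trained) convolutional bank with strided stages.

    Stage s halves the spatial resolution; features at stage s are the
    per-location channel vectors of its ReLU output.
    """

    STAGE_CHANNELS = (8, 16, 24)

    def __init__(self, cfg: LossConfig):
        rng = np.random.default_rng(cfg.seed)
        self.weights = []
        in_ch = 1
        for out_ch in self.STAGE_CHANNELS:
            fan = in_ch * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan), size=(out_ch, in_ch, 3, 3))
            self.weights.append(Tensor(w.astype(np.float32)))
            in_ch = out_ch
        self.layers = tuple(cfg.layers)
        if any(l < 0 or l >= len(self.STAGE_CHANNELS) for l in self.layers):
            raise ValueError(f"layer ids must be in 0..{len(self.STAGE_CHANNELS)-1}")

    def forward_batch(self, imgs: Tensor) -> list[Tensor]:
        """Batched extraction: (B, 1, H, W) -> per layer (B, N, C)."""
        h, w = imgs.shape[-2:]
        need = 2 ** len(self.STAGE_CHANNELS)
        if h < need or w < need:
            raise ValueError(
                f"image {h}x{w} smaller than extractor receptive field ({need})")
        x = imgs
        outs = []
        for wt in self.weights:
            x = x.conv2d(wt, stride=2, padding=1).relu()
            outs.append(x)
        feats = []
        for l in self.layers:
            o = outs[l]                        # (B, C, h, w)
            B, C = o.shape[0], o.shape[1]
            feats.append(o.reshape(B, C, -1).transpose(0, 2, 1))
        return feats

    def __call__(self, img: Tensor) -> list[Tensor]:
        h, w = img.shape[-2:]
        return [f[0] for f in self.forward_batch(img.reshape(1, 1, h, w))]


class RawPatchExtractor:
    """All k×k patches of the image as flat feature vectors."""

    def __init__(self, cfg: LossConfig):
        self.k = int(cfg.patch_size)

    def __call__(self, img: Tensor) -> list[Tensor]:
        h, w = img.shape[-2:]
        k = self.k
        if h < k or w < k:
            raise ValueError(f"image {h}x{w} smaller than patch size {k}")
        hp, wp = h - k + 1, w - k + 1
        from .ndl import concat
        cols = [img[di:di + hp, dj:dj + wp].reshape(-1, 1)
                for di in range(k) for dj in range(k)]
        return [concat(cols, axis=1)]


def make_extractor(cfg: LossConfig):
    cfg.validate()
    if cfg.extractor == "random-conv":
        return RandomConvExtractor(cfg)
    return RawPatchExtractor(cfg)


def extract_features(img: np.ndarray, cfg: LossConfig,
                     extractor=None) -> list[FeatureSet]:
    """Feature sets of a 2D slice, one per configured extractor stage."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    ext = make_extractor(cfg) if extractor is None else extractor
    feats = ext(Tensor(img))
    layers = cfg.layers if cfg.extractor == "random-conv" else (0,)
    return [FeatureSet(f.data, layer_id=l) for f, l in zip(feats, layers)]


# ---------------------------------------------------------------------------
# contextual loss


def _subsample(f: Tensor, cap: int, rng: np.random.Generator) -> Tensor:
    n = f.shape[-2]
    if n <= cap:
        return f
    idx = np.sort(rng.choice(n, size=cap, replace=False))
    return f[..., idx, :] if f.ndim == 3 else f[idx]


def _center_normalize(f: Tensor, strict: bool) -> Tensor:
    f = f - f.mean(axis=f.ndim - 2, keepdims=True)
    sq = (f * f).sum(axis=f.ndim - 1, keepdims=True)
    if strict and np.all(sq.data < _NORM_FLOOR):
        raise ValueError("all feature vectors have zero norm after centering")
    return f / sq.clamp_min(_NORM_FLOOR).sqrt()


def contextual_loss_batched(pred_f: Tensor, target_f: Tensor,
                            cfg: LossConfig, strict: bool = False) -> Tensor:
    """Contextual loss on batched feature sets (B, N, D) -> (B,) losses."""
    if pred_f.shape[-1] != target_f.shape[-1]:
        raise ValueError("feature dimensionality mismatch")
    rng = np.random.default_rng(cfg.seed)
    p = _subsample(pred_f, cfg.max_features, rng)
    t = _subsample(target_f, cfg.max_features, rng)
    p = _center_normalize(p, strict)
    t = _center_normalize(t, strict)
    sim = p @ t.transpose(0, 2, 1)                 # (B, Np, Nt) cosine sim
    d = 1.0 - sim
    dmin = d.min(axis=2, keepdims=True)            # min over targets k
    dnorm = d / (dmin + cfg.epsilon)
    w = ((1.0 - dnorm) * (1.0 / cfg.bandwidth_h)).exp()
    cx = w / w.sum(axis=2, keepdims=True)          # rows sum to 1
    score = cx.max(axis=1)                         # best match per target j
    np_count = float(p.shape[-2])
    return -((score.sum(axis=1) * (1.0 / np_count)).log())


def contextual_loss_t(pred_f: Tensor, target_f: Tensor, cfg: LossConfig,
                      strict: bool = False) -> Tensor:
    """Differentiable contextual loss between two (N, D) feature sets."""
    p = pred_f.reshape(1, *pred_f.shape)
    t = target_f.reshape(1, *target_f.shape)
    return contextual_loss_batched(p, t, cfg, strict).sum()


def contextual_loss(pred_f, target_f, cfg: LossConfig) -> float:
    """Contextual loss between two feature sets (non-negative scalar)."""
    cfg.validate()
    pf = pred_f.features if isinstance(pred_f, FeatureSet) else np.asarray(pred_f)
    tf = target_f.features if isinstance(target_f, FeatureSet) else np.asarray(target_f)
    if pf.shape[0] < 1 or tf.shape[0] < 1:
        raise ValueError("feature sets must be nonempty")
    val = contextual_loss_t(Tensor(pf), Tensor(tf), cfg, strict=True).item()
    return max(val, 0.0)


# ---------------------------------------------------------------------------
# combined loss


def combined_loss_t(pred: Tensor, target: Tensor, cfg: LossConfig,
                    extractor=None) -> tuple[Tensor, float, float]:
    """Differentiable combined objective on two 2D slices.

    Returns (total loss tensor, L1 term value, contextual term value).
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    l1 = (pred - target).abs().mean()
    if cfg.lambda_cx == 0:
        return l1, l1.item(), 0.0
    ext = make_extractor(cfg) if extractor is None else extractor
    pf = ext(pred)
    tf = ext(target)
    cx_terms = [contextual_loss_t(a, b, cfg) for a, b in zip(pf, tf)]
    cx = cx_terms[0]
    for term in cx_terms[1:]:
        cx = cx + term
    cx = cx * (1.0 / len(cx_terms))
    total = l1 + cx * cfg.lambda_cx
    return total, l1.item(), cx.item()


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  cfg: LossConfig) -> float:
    """Mean absolute pixel error plus ``lambda_cx`` times the mean
    contextual loss over the configured extractor stages.

    With ``lambda_cx = 0`` this reduces exactly to the L1 loss.
    """
    cfg.validate()
    total, _, _ = combined_loss_t(Tensor(np.asarray(pred, dtype=np.float64)),
                                  Tensor(np.asarray(target, dtype=np.float64)),
                                  cfg)
    return total.item()


def combined_loss_terms(pred: np.ndarray, target: np.ndarray,
                        cfg: LossConfig) -> tuple[float, float, float]:
    """(total, l1 term, contextual term) for logging."""
    cfg.validate()
    total, l1, cx = combined_loss_t(
        Tensor(np.asarray(pred, dtype=np.float64)),
        Tensor(np.asarray(target, dtype=np.float64)), cfg)
    return total.item(), l1, cx
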