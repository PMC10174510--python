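"""The multi-planar 2.5D attention U-Net.

A volume is sliced along one of the three orthogonal planes into 3-slice
stacks (slices N−1, N, N+1 as channels); a 2D U-Net with a residual-block
encoder (4 blocks), an attention-gated decoder (4 blocks) and a residual
output head predicts the corrected central slice.  Per-plane predictions
are reassembled into volumes and the three planes averaged voxelwise in HU
for the final multi-planar estimate.

Intensities are normalised from the HU clip window [−1200, 3071] to [0, 1]
before the network and denormalised after; volumes store float32 so this
round trip is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import ndl
from .ndl import Tensor
from .volume import Volume, denormalize, normalize

PLANES = ("axial", "coronal", "sagittal")
_PLANE_AXIS = {"axial": 0, "coronal": 1, "sagittal": 2}


@dataclass
class SliceSample:
    """One 2.5D unit: a 3-slice input stack and (optionally) its target."""

    input_stack: np.ndarray           # (3, H, W), normalised [0, 1]
    target: np.ndarray | None         # (H, W) or None at inference
    plane: str
    index: int

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if self.input_stack.shape[0] != 3:
            raise ValueError("input stack must have 3 channels")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture knobs of one single-planar 2.5D U-Net."""

    base_channels: int = 8
    attention: bool = True
    in_channels: int = 3
    out_channels: int = 1
    encoder_blocks: int = 4
    decoder_blocks: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.encoder_blocks != 4 or self.decoder_blocks != 4:
            raise ValueError("this architecture is fixed at 4 encoder and "
                             "4 decoder blocks")
        if self.in_channels != 3 or self.out_channels != 1:
            raise ValueError("2.5D slicing requires in_channels=3, out_channels=1")


def slice_to_samples(vol: Volume, plane: str,
                     target_vol: Volume | None = None) -> list[SliceSample]:
    """One sample per slice along the plane axis; replicate edge padding.

    If ``target_vol`` is given (same grid), its central slice is attached to
    each sample as the training target.
    """
    axis = _PLANE_AXIS[plane]
    data = normalize(np.moveaxis(vol.data, axis, 0))
    tdata = None
    if target_vol is not None:
        if target_vol.shape != vol.shape:
            raise ValueError("target volume grid mismatch")
        tdata = normalize(np.moveaxis(target_vol.data, axis, 0))
    depth = data.shape[0]
    samples = []
    for n in range(depth):
        lo = max(n - 1, 0)
        hi = min(n + 1, depth - 1)
        stack = np.stack([data[lo], data[n], data[hi]])
        samples.append(SliceSample(stack, None if tdata is None else tdata[n],
                                   plane, n))
    return samples


# ---------------------------------------------------------------------------
# network blocks


class _ResBlock(ndl.Module):
    """Two 3x3 convs with a residual connection (identity channel count)."""

    def __init__(self, ch: int, rng: np.random.Generator):
        self.c1 = ndl.Conv2d(ch, ch, 3, rng)
        self.c2 = ndl.Conv2d(ch, ch, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        h = self.c2(h)
        return (h + x).relu()


class AttentionGate(ndl.Module):
    """Additive attention over a skip connection.

    ``xl`` are the encoder (skip) features; ``g`` is the gating signal from
    the next-coarser scale (half the spatial resolution).  Both are projected
    to a common width, summed, passed through ReLU, projected to one channel
    and squashed with a sigmoid into per-pixel coefficients α ∈ (0, 1); the
    gated output is α ⊙ xl.
    """

    def __init__(self, x_ch: int, g_ch: int, inter_ch: int,
                 rng: np.random.Generator):
        self.wx = ndl.Conv2d(x_ch, inter_ch, 1, rng, bias=False)
        self.wg = ndl.Conv2d(g_ch, inter_ch, 1, rng, bias=True)
        self.psi = ndl.Conv2d(inter_ch, 1, 1, rng, bias=True)

    def forward(self, xl: Tensor, g: Tensor) -> tuple[Tensor, Tensor]:
        if (g.shape[-2] * 2, g.shape[-1] * 2) != (xl.shape[-2], xl.shape[-1]):
            raise ValueError(
                f"gating signal must be at half the resolution of the skip: "
                f"got g {g.shape[-2:]} vs x {xl.shape[-2:]}")
        g_up = g.upsample2x()
        a = (self.wx(xl) + self.wg(g_up)).relu()
        alpha = self.psi(a).sigmoid()
        return alpha * xl, alpha


class _DecoderBlock(ndl.Module):
    def __init__(self, in_ch: int, skip_ch: int, out_ch: int, attention: bool,
                 rng: np.random.Generator):
        self.up = ndl.Conv2d(in_ch, out_ch, 3, rng)
        self.gate = AttentionGate(skip_ch, in_ch, max(skip_ch // 2, 1), rng) \
            if attention else None
        self.c1 = ndl.Conv2d(out_ch + skip_ch, out_ch, 3, rng)
        self.c2 = ndl.Conv2d(out_ch, out_ch, 3, rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        if self.gate is not None:
            skip, _ = self.gate(skip, x)
        h = self.up(x.upsample2x()).relu()
        h = ndl.concat([h, skip], axis=1)
        h = self.c1(h).relu()
        return self.c2(h).relu()


class UNet2p5(ndl.Module):
    """Single-planar 2.5D U-Net with residual encoder blocks, attention-gated
    decoder blocks and a residual output head (the network predicts a
    correction added to the central input slice)."""

    def __init__(self, spec: ModelSpec):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        C = spec.base_channels
        self.stem = ndl.Conv2d(spec.in_channels, C, 3, rng)
        self.enc = [_ResBlock(C, rng), _ResBlock(2 * C, rng),
                    _ResBlock(4 * C, rng), _ResBlock(8 * C, rng)]
        self.down = [ndl.Conv2d(C, 2 * C, 3, rng, stride=2),
                     ndl.Conv2d(2 * C, 4 * C, 3, rng, stride=2),
                     ndl.Conv2d(4 * C, 8 * C, 3, rng, stride=2),
                     ndl.Conv2d(8 * C, 16 * C, 3, rng, stride=2)]
        self.mid = _ResBlock(16 * C, rng)
        self.dec = [
            _DecoderBlock(16 * C, 8 * C, 8 * C, spec.attention, rng),
            _DecoderBlock(8 * C, 4 * C, 4 * C, spec.attention, rng),
            _DecoderBlock(4 * C, 2 * C, 2 * C, spec.attention, rng),
            _DecoderBlock(2 * C, C, C, spec.attention, rng),
        ]
        self.head = ndl.Conv2d(C, spec.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x.astype(np.float32)   # network runs in float32
        h = self.stem(x).relu()
        skips = []
        for blk, down in zip(self.enc, self.down):
            h = blk(h)
            skips.append(h)
            h = down(h).relu()
        h = self.mid(h)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = blk(h, skip)
        delta = self.head(h)
        return delta + x[:, 1:2]


class PassThroughModel(ndl.Module):
    """Returns the central input channel unchanged; a plumbing check."""

    def forward(self, x: Tensor) -> Tensor:
        return x[:, 1:2]


# ---------------------------------------------------------------------------
# inference


def _pad_to_multiple(arr: np.ndarray, mult: int = 16):
    """Symmetric zero-pad trailing 2 axes up to a multiple of ``mult``."""
    h, w = arr.shape[-2:]
    ph = (-h) % mult
    pw = (-w) % mult
    pad = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    if ph or pw:
        width = [(0, 0)] * (arr.ndim - 2) + [(pad[0], pad[1]), (pad[2], pad[3])]
        arr = np.pad(arr, width)
    return arr, pad, (h, w)


def run_model(model: ndl.Module, stacks: np.ndarray) -> np.ndarray:
    """Forward a batch of normalised stacks (N, 3, H, W) -> (N, H, W).

    Spatial sizes not divisible by 16 are symmetrically zero-padded and the
    output cropped back.
    """
    padded, pad, (h, w) = _pad_to_multiple(stacks)
    with ndl.no_grad():
        out = model(Tensor(padded)).data
    t, _, l, _ = pad
    return out[:, 0, t:t + h, l:l + w]


def forward(sample: SliceSample, model: ndl.Module) -> np.ndarray:
    """Corrected central slice (normalised scale) for one sample."""
    return run_model(model, sample.input_stack[None])[0]


def predict_volume(vol: Volume, model: ndl.Module, plane: str,
                   batch_size: int = 8) -> Volume:
    """Run the model over every slice of a plane and reassemble in HU."""
    samples = slice_to_samples(vol, plane)
    stacks = np.stack([s.input_stack for s in samples])
    outs = []
    for i in range(0, len(stacks), batch_size):
        outs.append(run_model(model, stacks[i:i + batch_size]))
    pred = np.concatenate(outs, axis=0)
    data = np.moveaxis(pred, 0, _PLANE_AXIS[plane])
    return Volume(denormalize(data), vol.spacing, vol.origin, "predicted")


def predict_multiplanar(vol: Volume, models: dict[str, ndl.Module],
                        batch_size: int = 8) -> Volume:
    """Voxelwise mean (in HU) of the per-plane predictions."""
    preds = [predict_volume(vol, models[p], p, batch_size) for p in models]
    shapes = {p.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError(f"per-plane prediction grids differ: {shapes}")
    mean = np.mean([p.data.astype(np.float64) for p in preds], axis=0)
    return Volume(mean.astype(np.float32), vol.spacing, vol.origin, "predicted")


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: UNet2p5, path, plane: str | None = None) -> None:
    """Weights + architecture spec + normalisation window in one .npz."""
    meta = {"spec": asdict(model.spec), "plane": plane,
            "norm_window": [-1200.0, 3071.0]}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> tuple[UNet2p5, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = UNet2p5(ModelSpec(**meta["spec"]))
    model.load_state_dict(state)
    return model, meta
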