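"""Training facilities: overlap losses, ground-truth rendering, augmentation,
ImageNet normalisation, patch subdivision, and the phased curriculum.

Ground truth is rendered as a 5-pixel cross (plus sign) over each dot centre;
this inflates the tiny positive class enough for overlap losses to have
gradient signal.  Training follows a multi-phase schedule in which synthetic
patches supplement the real ones early on and are tapered out, with the
encoder frozen during the first phase so randomly initialised decoder layers
cannot destroy pretrained features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn.autograd import Tensor
from .nn.optim import AdaDelta
from .netarch import DotSegNet
from .synthgen import SyntheticPatch

__all__ = [
    "IMAGENET_MEAN_BGR", "IMAGENET_STD_BGR",
    "LossConfig", "OptimizerConfig", "PhaseSpec", "AugmentConfig",
    "SchedulingError", "render_gt_mask", "tversky_loss", "dice_loss",
    "jaccard_loss", "bce_loss", "make_loss", "subdivide_patch", "Tile",
    "apply_geometric", "augment", "normalize_input", "denormalize_input",
    "default_schedule", "train", "predict_map", "binary_iou",
]

# canonical ImageNet statistics, reordered to the BGR channel layout used here
IMAGENET_MEAN_BGR = np.array([0.406, 0.456, 0.485])
IMAGENET_STD_BGR = np.array([0.225, 0.224, 0.229])


@dataclass
class LossConfig:
    kind: str = "tversky"          # bce | dice | jaccard | tversky
    alpha: float = 0.6             # recall weight (tversky); beta = 1 - alpha
    smooth: float = 1e-6

    def __post_init__(self):
        if self.kind not in ("bce", "dice", "jaccard", "tversky"):
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class OptimizerConfig:
    learning_rate: float = 0.005
    rho: float = 0.975
    batch_size: int = 4
    eps: float = 1e-6        # AdaDelta accumulator floor; larger = faster warm-up

    def __post_init__(self):
        if min(self.learning_rate, self.rho, self.batch_size, self.eps) <= 0:
            raise ValueError("optimizer settings must be positive")


@dataclass
class PhaseSpec:
    real_samples_per_epoch: int
    generated_samples_per_epoch: int
    epochs: int
    backbone_frozen: bool = False

    def __post_init__(self):
        if self.real_samples_per_epoch < 0 or self.generated_samples_per_epoch < 0:
            raise ValueError("sample counts must be >= 0")
        if self.epochs <= 0:
            raise ValueError("epochs must be > 0")


@dataclass
class AugmentConfig:
    max_rotation_degrees: float = 90.0
    allow_hflip: bool = True
    allow_vflip: bool = True

    def __post_init__(self):
        if not 0.0 <= self.max_rotation_degrees <= 90.0:
            raise ValueError("rotation must be in [0, 90] degrees")


class SchedulingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# ground truth and losses
# ---------------------------------------------------------------------------

def render_gt_mask(dots: list[tuple[int, int]] | list[tuple[int, int, str]],
                   shape: tuple[int, int]) -> np.ndarray:
    """Binary mask with a 5-pixel cross (centre plus the 4 axial neighbours)
    over each dot location; crosses are clipped at borders and unioned."""
    H, W = shape
    mask = np.zeros((H, W), dtype=np.float64)
    for dot in dots:
        x, y = int(dot[0]), int(dot[1])
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"dot ({x}, {y}) outside mask shape {shape}")
        for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
            xx, yy = x + dx, y + dy
            if 0 <= xx < W and 0 <= yy < H:
                mask[yy, xx] = 1.0
    return mask


def _as_pair(pred, gt):
    wrapped = not isinstance(pred, Tensor)
    p = pred if isinstance(pred, Tensor) else Tensor(pred)
    g = gt if isinstance(gt, Tensor) else Tensor(gt)
    if p.shape != g.shape:
        raise ValueError(f"pred shape {p.shape} != gt shape {g.shape}")
    return p, g, wrapped


def _finish(loss: Tensor, wrapped: bool):
    return loss.item() if wrapped else loss


def tversky_loss(pred, gt, alpha: float = 0.6, smooth: float = 1e-6):
    """1 - (TP+s) / (TP + a FN + (1-a) FP + s) with soft (probabilistic) counts.

    alpha weights false negatives (recall emphasis); alpha = beta = 0.5
    recovers Dice loss exactly.
    """
    p, g, wrapped = _as_pair(pred, gt)
    tp = (p * g).sum()
    fn = ((1.0 - p) * g).sum()
    fp = (p * (1.0 - g)).sum()
    loss = 1.0 - (tp + smooth) / (tp + alpha * fn + (1.0 - alpha) * fp + smooth)
    return _finish(loss, wrapped)


def dice_loss(pred, gt, smooth: float = 1e-6):
    return tversky_loss(pred, gt, alpha=0.5, smooth=smooth)


def jaccard_loss(pred, gt, smooth: float = 1e-6):
    p, g, wrapped = _as_pair(pred, gt)
    tp = (p * g).sum()
    fn = ((1.0 - p) * g).sum()
    fp = (p * (1.0 - g)).sum()
    loss = 1.0 - (tp + smooth) / (tp + fp + fn + smooth)
    return _finish(loss, wrapped)


def bce_loss(pred, gt, eps: float = 1e-7):
    p, g, wrapped = _as_pair(pred, gt)
    # clamp away from {0,1} via affine squeeze to keep logs finite
    p = p * (1.0 - 2.0 * eps) + eps
    loss = -(g * p.log() + (1.0 - g) * (1.0 - p).log()).mean()
    return _finish(loss, wrapped)


def make_loss(config: LossConfig):
    if config.kind == "bce":
        return lambda p, g: bce_loss(p, g)
    if config.kind == "dice":
        return lambda p, g: dice_loss(p, g, smooth=config.smooth)
    if config.kind == "jaccard":
        return lambda p, g: jaccard_loss(p, g, smooth=config.smooth)
    return lambda p, g: tversky_loss(p, g, alpha=config.alpha, smooth=config.smooth)


# ---------------------------------------------------------------------------
# subdivision, augmentation, normalisation
# ---------------------------------------------------------------------------

@dataclass
class Tile:
    image: np.ndarray
    dots: list[tuple[int, int, str]]
    origin: tuple[int, int]          # (x0, y0) of the tile in the source patch
    mask: np.ndarray | None = None


def _grid_origins(dim: int, tile: int, stride: int) -> list[int]:
    origins = list(range(0, dim - tile + 1, stride))
    if origins[-1] != dim - tile:
        origins.append(dim - tile)
    return origins


def subdivide_patch(image: np.ndarray, dots, mode: str, tile: int = 224,
                    stride: int = 128, rng: np.random.Generator | None = None,
                    n_crops: int = 1, mask: np.ndarray | None = None) -> list[Tile]:
    """Cut a large patch into network-sized tiles.

    'train' mode takes seeded random crops; 'eval' mode tiles a deterministic
    sliding grid (stride 128 gives a 3x3 grid on a 480x480 patch).  Dot
    coordinates are shifted into the tile frame; dots outside are dropped.
    """
    H, W = image.shape[:2]
    if H < tile or W < tile:
        raise ValueError(f"image {H}x{W} smaller than tile {tile}")
    if mode == "train":
        if rng is None:
            raise ValueError("train-mode subdivision requires an rng")
        origins = [(int(rng.integers(0, W - tile + 1)),
                    int(rng.integers(0, H - tile + 1))) for _ in range(n_crops)]
    elif mode == "eval":
        origins = [(x0, y0) for y0 in _grid_origins(H, tile, stride)
                   for x0 in _grid_origins(W, tile, stride)]
    else:
        raise ValueError(f"unknown subdivision mode {mode!r}")

    tiles = []
    for x0, y0 in origins:
        sub = image[y0:y0 + tile, x0:x0 + tile]
        local = [(d[0] - x0, d[1] - y0) + tuple(d[2:]) for d in dots
                 if x0 <= d[0] < x0 + tile and y0 <= d[1] < y0 + tile]
        m = mask[y0:y0 + tile, x0:x0 + tile] if mask is not None else None
        tiles.append(Tile(image=sub, dots=local, origin=(x0, y0), mask=m))
    return tiles


def apply_geometric(image: np.ndarray, mask: np.ndarray, angle: float = 0.0,
                    hflip: bool = False, vflip: bool = False):
    """Deterministically apply one geometric transform to an image/mask pair.
    The image is interpolated bilinearly, the mask nearest-neighbour so it
    stays binary."""
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError("image and mask shapes differ")
    img, msk = image, mask
    if hflip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if vflip:
        img, msk = img[::-1], msk[::-1]
    if angle != 0.0:
        img = ndimage.rotate(img.astype(np.float64), angle, axes=(1, 0),
                             reshape=False, order=1, mode="reflect")
        msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False,
                             order=0, mode="reflect")
        if image.dtype == np.uint8:
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img.copy(), msk.copy()


def augment(image: np.ndarray, mask: np.ndarray, rng: np.random.Generator,
            config: AugmentConfig | None = None):
    """Random rotation of up to 90 degrees plus vertical and/or horizontal flips."""
    config = config or AugmentConfig()
    angle = float(rng.uniform(0.0, config.max_rotation_degrees))
    hflip = bool(config.allow_hflip and rng.random() < 0.5)
    vflip = bool(config.allow_vflip and rng.random() < 0.5)
    return apply_geometric(image, mask, angle=angle, hflip=hflip, vflip=vflip)


def normalize_input(image: np.ndarray) -> np.ndarray:
    """8-bit BGR image -> float map scaled to [0,1] then standardised with the
    ImageNet channel statistics (reordered for BGR)."""
    x = image.astype(np.float64) / 255.0
    return (x - IMAGENET_MEAN_BGR) / IMAGENET_STD_BGR


def denormalize_input(x: np.ndarray) -> np.ndarray:
    return (x * IMAGENET_STD_BGR + IMAGENET_MEAN_BGR) * 255.0


# ---------------------------------------------------------------------------
# schedule and training loop
# ---------------------------------------------------------------------------

def default_schedule() -> list[PhaseSpec]:
    """The six-phase curriculum: 460 real samples per epoch throughout
    (115 patches sampled 4x), generated samples halving each phase from 1071
    to 0, 128 epochs per phase except a 1024-epoch final phase; the backbone
    is frozen only in phase 1."""
    rows = [(460, 1071, 128, True), (460, 460, 128, False), (460, 230, 128, False),
            (460, 115, 128, False), (460, 58, 128, False), (460, 0, 1024, False)]
    return [PhaseSpec(r, g, e, f) for r, g, e, f in rows]


def _unwrap(item) -> tuple[np.ndarray, list]:
    if isinstance(item, SyntheticPatch):
        return item.image, item.dots
    image, dots = item
    return image, list(dots)


def _prepare_sample(image, dots, input_size, rng, aug: AugmentConfig | None):
    H, W = image.shape[:2]
    mask = render_gt_mask(dots, (H, W))
    if H > input_size or W > input_size:
        t = subdivide_patch(image, dots, "train", tile=input_size, rng=rng)[0]
        image, mask = t.image, render_gt_mask(t.dots, (input_size, input_size))
    if aug is not None:
        image, mask = augment(image, mask, rng, aug)
    return normalize_input(image), mask


def binary_iou(pred_map: np.ndarray, gt_mask: np.ndarray,
               threshold: float = 0.5) -> float:
    p = pred_map > threshold
    g = gt_mask > 0.5
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def predict_map(model: DotSegNet, image: np.ndarray) -> np.ndarray:
    """Run one 8-bit BGR image through the network; returns an (H, W) map in [0,1]."""
    model.eval()
    x = normalize_input(image).transpose(2, 0, 1)[None].astype(np.float32)
    out = model(Tensor(x))
    return out.data[0, 0].astype(np.float64)


def train(model: DotSegNet, real_data, generated_data,
          schedule: list[PhaseSpec], loss: LossConfig | None = None,
          optimizer: OptimizerConfig | None = None, seed: int = 0,
          val_data=None, augment_config: AugmentConfig | None = AugmentConfig(),
          val_every: int = 1, callback=None) -> list[dict]:
    """Run the phased curriculum; returns one history record per epoch.

    Per epoch each phase draws `real_samples_per_epoch` samples by cycling the
    real patches and `generated_samples_per_epoch` distinct generated patches
    (raising SchedulingError if too few exist).  Backbone freezing follows the
    phase flag.  Fully deterministic for a fixed seed.
    """
    loss = loss or LossConfig()
    optimizer = optimizer or OptimizerConfig()
    rng = np.random.default_rng(seed)
    model.set_rng(rng)
    loss_fn = make_loss(loss)
    opt = AdaDelta(model.parameters(), learning_rate=optimizer.learning_rate,
                   rho=optimizer.rho, eps=optimizer.eps)
    real = [_unwrap(it) for it in real_data]
    gen = [_unwrap(it) for it in generated_data]
    if not real:
        raise ValueError("real_data must be non-empty")
    input_size = model.config.input_size
    history: list[dict] = []

    for phase_idx, phase in enumerate(schedule, start=1):
        if phase.generated_samples_per_epoch > len(gen):
            raise SchedulingError(
                f"phase {phase_idx} wants {phase.generated_samples_per_epoch} "
                f"generated samples but only {len(gen)} are available")
        model.freeze_backbone(phase.backbone_frozen)
        for epoch in range(phase.epochs):
            order = []
            idx = rng.permutation(len(real))
            for k in range(phase.real_samples_per_epoch):
                order.append(real[idx[k % len(real)]])
            if phase.generated_samples_per_epoch:
                for gi in rng.choice(len(gen), size=phase.generated_samples_per_epoch,
                                     replace=False):
                    order.append(gen[gi])
            order = [order[i] for i in rng.permutation(len(order))]

            model.train()
            epoch_loss, n_batches = 0.0, 0
            for b0 in range(0, len(order), optimizer.batch_size):
                batch = order[b0:b0 + optimizer.batch_size]
                xs, ms = [], []
                for image, dots in batch:
                    x, m = _prepare_sample(image, dots, input_size, rng,
                                           augment_config)
                    xs.append(x.transpose(2, 0, 1))
                    ms.append(m[None])
                pred = model(Tensor(np.stack(xs).astype(np.float32)))
                l = loss_fn(pred, Tensor(np.stack(ms).astype(np.float32)))
                opt.zero_grad()
                l.backward()
                opt.step()
                epoch_loss += l.item()
                n_batches += 1

            rec = {"phase": phase_idx, "epoch": epoch + 1,
                   "loss": epoch_loss / max(n_batches, 1)}
            if val_data is not None and val_every and (epoch + 1) % val_every == 0:
                ious = []
                for item in val_data:
                    image, dots = _unwrap(item)
                    pm = predict_map(model, image)
                    ious.append(binary_iou(pm, render_gt_mask(dots, image.shape[:2])))
                rec["val_iou"] = float(np.mean(ious))
            history.append(rec)
            if callback is not None:
                callback(rec)
    return history
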