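"""Seeded generation of synthetic chromogenic RNAscope patches.

Real chromogenic RNAscope slides show small brown (DAB) dots — one per
detected RNA transcript — on haematoxylin-counterstained tissue.  This module
builds artificial training patches whose dot positions are known exactly:
a bluish textured background with nucleus-like regions, onto which subtractive
dot masks are applied.  Two dot phenotypes are modelled: a plain radial dot
whose hue runs from light yellow to dark brown, and a dark-centred dot with a
yellow tinge.  All colour triples are stored in BGR channel order.

Every routine draws from an explicit ``numpy.random.Generator``; the same seed
reproduces a patch bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as _ellipse
from skimage.transform import resize as _resize

__all__ = [
    "LIGHT_YELLOW_BGR", "DARK_BROWN_BGR", "SECONDARY_BGR", "MIN_SEPARATION",
    "DotColour", "DotMask", "PerturbParams", "PatchPlan", "SyntheticPatch",
    "sample_dot_count", "sample_scale_offset", "interpolate_primary_colour",
    "circular_gaussian_kernel", "make_primary_dot_mask", "make_secondary_dot_mask",
    "combine_masks", "perturb_dot", "sample_perturb_params", "plan_patch",
    "place_dots", "generate_background", "apply_dots", "generate_patch",
]

# Endpoints of the primary-dot colour axis and the fixed secondary colour (BGR)
LIGHT_YELLOW_BGR = (225.0, 253.0, 255.0)
DARK_BROWN_BGR = (160.0, 200.0, 217.0)
SECONDARY_BGR = (200.0, 210.0, 215.0)
MIN_SEPARATION = 3.0  # pixels, Euclidean, between any two dot centres
_PLACEMENT_RETRY_BUDGET = 1000
_MASK_RADIUS = 9  # half-width of the working canvas for one dot mask


class DotColour(NamedTuple):
    b: float
    g: float
    r: float


@dataclass
class DotMask:
    """Subtractive 3-channel mask for one dot; applying it never brightens."""

    values: np.ndarray           # (h, w, 3) float, >= 0
    anchor: tuple[int, int]      # (row, col) of the dot centre inside `values`
    dot_type: str = "primary"    # "primary" | "secondary"


@dataclass
class PerturbParams:
    cardinal_stretch: tuple[int, int, int, int]  # (+x, -x, +y, -y), pixels
    base_scale_x: float
    base_scale_y: float
    shared_offset: float                         # r' = 0.4 r^2
    noise_low: float = 0.975
    noise_high: float = 1.025
    rotation: int = 0                            # integer degrees


@dataclass
class PatchPlan:
    n: int
    colour_window: tuple[float, float]   # width exactly 0.20 of the unit axis
    has_secondary: bool
    secondary_prob: float
    min_separation: float = MIN_SEPARATION


@dataclass
class SyntheticPatch:
    image: np.ndarray                        # uint8 (H, W, 3), BGR
    dots: list[tuple[int, int, str]]         # (x, y, dot_type), 0-based pixels
    seed: int | None = None
    plan: PatchPlan | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# per-patch sampling formulas
# ---------------------------------------------------------------------------

def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def sample_dot_count(r: float) -> int:
    """Dot count n = round(2^(1 + 5 r)), an exponential scale from 2 to 64.

    Most patches carry few dots and a minority carry many, matching the
    bimodal-looking counts seen on real tissue.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    return int(_round_half_up(2.0 ** (1.0 + 5.0 * r)))


def sample_scale_offset(r: float) -> float:
    """Shared scale addend r' = 0.4 r^2; rarely large, so big dots are rare."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    return 0.4 * r * r


def interpolate_primary_colour(t: float) -> DotColour:
    """Linear blend from light yellow (t=0) to dark brown (t=1), same t per channel."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must be in [0, 1], got {t}")
    return DotColour(*((1.0 - t) * np.array(LIGHT_YELLOW_BGR)
                       + t * np.array(DARK_BROWN_BGR)))


# ---------------------------------------------------------------------------
# dot-mask construction
# ---------------------------------------------------------------------------

def circular_gaussian_kernel(size: int, sigma: float | None = None) -> np.ndarray:
    """Gaussian kernel zeroed outside the inscribed circle, normalised to sum 1.

    sigma defaults to size/4, a common choice for compact circular kernels.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be odd and positive")
    sigma = size / 4.0 if sigma is None else sigma
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    k[np.hypot(yy, xx) > size / 2.0] = 0.0
    return k / k.sum()


def _blurred_impulse_mask(colour, kernel_size: int, dot_type: str) -> DotMask:
    """Centre pixel 255-colour, circular Gaussian blur, rescale so the centre
    pixel regains its pre-blur value."""
    c = _MASK_RADIUS
    size = 2 * _MASK_RADIUS + 1
    values = np.zeros((size, size, 3), dtype=np.float64)
    centre = 255.0 - np.asarray(colour, dtype=np.float64)
    values[c, c, :] = centre
    kernel = circular_gaussian_kernel(kernel_size)
    for ch in range(3):
        values[:, :, ch] = ndimage.convolve(values[:, :, ch], kernel, mode="constant")
        peak = values[c, c, ch]
        if peak > 0:
            values[:, :, ch] *= centre[ch] / peak
    return DotMask(values=values, anchor=(c, c), dot_type=dot_type)


def make_primary_dot_mask(colour: DotColour, kernel_size: int = 9) -> DotMask:
    return _blurred_impulse_mask(colour, kernel_size, "primary")


def make_secondary_dot_mask() -> DotMask:
    """Dark-centred dot: fixed colour (200, 210, 215) BGR, 5x5 kernel; darkens
    every channel by at least 40 at the centre."""
    return _blurred_impulse_mask(SECONDARY_BGR, 5, "secondary")


def combine_masks(primary: DotMask, secondary: DotMask,
                  offset: tuple[int, int]) -> DotMask:
    """Add the secondary mask onto the primary with its centre shifted by
    (dx, dy) in {-1, 0, 1}; sums clip at 255."""
    dx, dy = offset
    if dx not in (-1, 0, 1) or dy not in (-1, 0, 1):
        raise ValueError(f"offset components must be in {{-1, 0, 1}}, got {offset}")
    out = primary.values.copy()
    pr, pc = primary.anchor
    sr, sc = secondary.anchor
    h, w = secondary.values.shape[:2]
    # secondary anchor lands at (pr + dy, pc + dx)
    r0, c0 = pr + dy - sr, pc + dx - sc
    rs, cs = max(r0, 0), max(c0, 0)
    re = min(r0 + h, out.shape[0])
    ce = min(c0 + w, out.shape[1])
    out[rs:re, cs:ce] += secondary.values[rs - r0:re - r0, cs - c0:ce - c0]
    np.clip(out, 0.0, 255.0, out=out)
    return DotMask(values=out, anchor=primary.anchor, dot_type="secondary")


def _radial_extent(nonzero: np.ndarray, anchor: tuple[int, int],
                   direction: str) -> int:
    r, c = anchor
    if direction == "+x":
        cols = np.where(nonzero[:, c:].any(axis=0))[0]
        return int(cols.max()) if cols.size else 0
    if direction == "-x":
        cols = np.where(nonzero[:, :c + 1].any(axis=0))[0]
        return int(c - cols.min()) if cols.size else 0
    if direction == "+y":
        rows = np.where(nonzero[r:, :].any(axis=1))[0]
        return int(rows.max()) if rows.size else 0
    rows = np.where(nonzero[:r + 1, :].any(axis=1))[0]
    return int(r - rows.min()) if rows.size else 0


def _stretch_half(values: np.ndarray, anchor, direction: str, s: int) -> np.ndarray:
    """Resample one half-axis strip so its radial extent grows by `s` pixels."""
    if s <= 0:
        return values
    nz = values.sum(axis=2) > 1e-9
    e = _radial_extent(nz, anchor, direction)
    if e == 0:
        return values
    r, c = anchor
    out = values.copy()

    def stretched(sub, new_len, axis):
        shape = list(sub.shape)
        shape[axis] = new_len
        return _resize(sub, tuple(shape[:2]), order=1, mode="constant",
                       cval=0.0, anti_aliasing=False, preserve_range=True)

    if direction == "+x":
        sub = values[:, c:c + e + 1]
        out[:, c:] = 0.0
        out[:, c:c + e + s + 1] = stretched(sub, e + s + 1, 1)
    elif direction == "-x":
        sub = values[:, c - e:c + 1][:, ::-1]
        out[:, :c + 1] = 0.0
        out[:, c - e - s:c + 1] = stretched(sub, e + s + 1, 1)[:, ::-1]
    elif direction == "+y":
        sub = values[r:r + e + 1, :]
        out[r:, :] = 0.0
        out[r:r + e + s + 1, :] = stretched(sub, e + s + 1, 0)
    else:
        sub = values[r - e:r + 1, :][::-1]
        out[:r + 1, :] = 0.0
        out[r - e - s:r + 1, :] = stretched(sub, e + s + 1, 0)[::-1]
    return out


def perturb_dot(mask: DotMask, params: PerturbParams,
                rng: np.random.Generator | None = None) -> DotMask:
    """Apply, in order: cardinal stretch, anisotropic scaling, per-pixel
    multiplicative noise, and rotation by an integer angle about the anchor."""
    values = mask.values
    for direction, s in zip(("+x", "-x", "+y", "-y"), params.cardinal_stretch):
        values = _stretch_half(values, mask.anchor, direction, int(s))

    sx = params.base_scale_x + params.shared_offset
    sy = params.base_scale_y + params.shared_offset
    if not (sx > 0 and sy > 0):
        raise ValueError("scale factors must be positive")
    if not (sx == 1.0 and sy == 1.0):
        h, w = values.shape[:2]
        nh = max(3, int(_round_half_up(h * sy)))
        nw = max(3, int(_round_half_up(w * sx)))
        nh += 1 - nh % 2  # odd canvas keeps the anchor on the centre pixel
        nw += 1 - nw % 2
        values = _resize(values, (nh, nw), order=1, mode="constant", cval=0.0,
                         anti_aliasing=False, preserve_range=True)

    if params.noise_low != 1.0 or params.noise_high != 1.0:
        if rng is None:
            raise ValueError("rng required when noise bounds are not collapsed to 1")
        noise = rng.uniform(params.noise_low, params.noise_high, size=values.shape)
        values = values * noise

    if params.rotation % 360 != 0:
        values = ndimage.rotate(values, params.rotation, axes=(1, 0),
                                reshape=False, order=1, mode="constant", cval=0.0)
        np.clip(values, 0.0, 255.0, out=values)

    anchor = (values.shape[0] // 2, values.shape[1] // 2)
    return DotMask(values=np.maximum(values, 0.0), anchor=anchor,
                   dot_type=mask.dot_type)


def sample_perturb_params(rng: np.random.Generator) -> PerturbParams:
    return PerturbParams(
        cardinal_stretch=tuple(int(v) for v in rng.integers(0, 4, size=4)),
        base_scale_x=float(rng.uniform(0.25, 0.5)),
        base_scale_y=float(rng.uniform(0.25, 0.5)),
        shared_offset=sample_scale_offset(float(rng.random())),
        rotation=int(rng.integers(0, 360)),
    )


# ---------------------------------------------------------------------------
# per-patch planning and placement
# ---------------------------------------------------------------------------

def plan_patch(rng: np.random.Generator) -> PatchPlan:
    """Draw the per-patch controls: dot count, a 20%-wide colour window, and
    the secondary-dot settings (25% of patches carry them, each dot then with
    probability uniform on [0, 0.5])."""
    n = sample_dot_count(float(rng.random()))
    start = float(rng.uniform(0.0, 0.8))
    has_secondary = bool(rng.random() < 0.25)
    secondary_prob = float(rng.uniform(0.0, 0.5)) if has_secondary else 0.0
    return PatchPlan(n=n, colour_window=(start, start + 0.2),
                     has_secondary=has_secondary, secondary_prob=secondary_prob)


class PlacementError(RuntimeError):
    pass


def place_dots(n: int, existing: list[tuple[int, int]], shape: tuple[int, int],
               rng: np.random.Generator,
               min_separation: float = MIN_SEPARATION) -> list[tuple[int, int]]:
    """Place n dots uniformly at random, redrawing any coordinate closer than
    `min_separation` (Euclidean) to an already-placed dot.

    Raises PlacementError after 1000 failed draws for a single dot.
    """
    H, W = shape
    placed = [(float(x), float(y)) for x, y in existing]
    out: list[tuple[int, int]] = []
    for _ in range(n):
        for attempt in range(_PLACEMENT_RETRY_BUDGET):
            x = int(rng.integers(0, W))
            y = int(rng.integers(0, H))
            if all((x - px) ** 2 + (y - py) ** 2 >= min_separation**2
                   for px, py in placed):
                placed.append((x, y))
                out.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place dot after {_PLACEMENT_RETRY_BUDGET} attempts "
                f"(patch too crowded: {len(placed)} dots on {H}x{W})")
    return out


# ---------------------------------------------------------------------------
# background and composition
# ---------------------------------------------------------------------------

def generate_background(shape: tuple[int, int],
                        rng: np.random.Generator) -> np.ndarray:
    """Haematoxylin-like background: pale bluish-grey field with smooth
    low-frequency variation and darker elliptical nucleus-like regions.

    No pixel drops below 100 on any channel, so applied dots (which darken by
    at most ~95 at their centre) remain distinguishable from tissue.
    """
    H, W = shape
    base = np.array([232.0, 222.0, 218.0])  # BGR: blue channel brightest
    img = np.tile(base, (H, W, 1))

    low = rng.normal(0.0, 1.0, size=(max(H // 16, 2), max(W // 16, 2), 3))
    low = _resize(low, (H, W), order=1, mode="edge", anti_aliasing=False)
    img += 8.0 * ndimage.gaussian_filter(low, sigma=(3, 3, 0))

    # nucleus-like ellipses, darker and bluer than the stroma
    nuc = np.zeros((H, W), dtype=np.float64)
    n_nuclei = rng.poisson(max(1, (H * W) // 2500))
    for _ in range(n_nuclei):
        cy, cx = rng.integers(0, H), rng.integers(0, W)
        ry, rx = rng.uniform(3, 9), rng.uniform(3, 9)
        rr, cc = _ellipse(cy, cx, ry, rx, shape=(H, W),
                          rotation=rng.uniform(0, np.pi))
        nuc[rr, cc] = 1.0
    nuc = ndimage.gaussian_filter(nuc, sigma=1.2)
    tint = np.array([0.28, 0.40, 0.42])  # darken red/green more than blue
    img *= 1.0 - nuc[:, :, None] * tint[None, None, :]

    return np.clip(_round_half_up(img), 100, 255).astype(np.uint8)


def apply_dots(image: np.ndarray,
               masks_with_coords: list[tuple[DotMask, tuple[int, int]]],
               seed: int | None = None) -> SyntheticPatch:
    """Subtract each mask from the image at its (x, y) anchor, clipping at 0;
    quantisation to uint8 happens here and only here."""
    H, W = image.shape[:2]
    acc = image.astype(np.float64)
    dots: list[tuple[int, int, str]] = []
    for mask, (x, y) in masks_with_coords:
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"dot anchor ({x}, {y}) outside image bounds")
        ar, ac = mask.anchor
        h, w = mask.values.shape[:2]
        r0, c0 = y - ar, x - ac
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + h, H), min(c0 + w, W)
        acc[rs:re, cs:ce] -= mask.values[rs - r0:re - r0, cs - c0:ce - c0]
        dots.append((x, y, mask.dot_type))
    out = np.clip(_round_half_up(acc), 0, 255).astype(np.uint8)
    return SyntheticPatch(image=out, dots=dots, seed=seed)


def generate_patch(shape: tuple[int, int] = (480, 480),
                   seed: int | None = 0,
                   rng: np.random.Generator | None = None,
                   plan: PatchPlan | None = None,
                   existing: list[tuple[int, int]] | None = None) -> SyntheticPatch:
    """Generate one full synthetic patch: background, plan, dots, composition."""
    if rng is None:
        rng = np.random.default_rng(seed)
    image = generate_background(shape, rng)
    if plan is None:
        plan = plan_patch(rng)
    coords = place_dots(plan.n, existing or [], shape, rng, plan.min_separation)

    masks: list[tuple[DotMask, tuple[int, int]]] = []
    lo, hi = plan.colour_window
    for _ in range(plan.n):
        t = float(rng.uniform(lo, hi))
        mask = make_primary_dot_mask(interpolate_primary_colour(min(t, 1.0)))
        if plan.has_secondary and rng.random() < plan.secondary_prob:
            offset = (int(rng.integers(-1, 2)), int(rng.integers(-1, 2)))
            mask = combine_masks(mask, make_secondary_dot_mask(), offset)
        mask = perturb_dot(mask, sample_perturb_params(rng), rng)
        masks.append((mask, (0, 0)))  # coordinates assigned below

    masks = [(m, c) for (m, _), c in zip(masks, coords)]
    patch = apply_dots(image, masks, seed=seed)
    patch.plan = plan
    return patch
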