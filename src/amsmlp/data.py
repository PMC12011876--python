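"""Data handling: real-image I/O, polygon annotations, splits, and a
synthetic single-leaf scene generator.

The generator emulates the imaging setup the network targets: one leaf
photographed against a *pure* (uncluttered) background such as a palm, a
desktop or soil. Each scene is a superellipse-shaped leaf with sinusoidal
edge serration, filled with a shaded green gradient and optional dark
lesion-like blemishes, composited over one of four background styles
(flat color, linear gradient, palm-like or wood-like texture). The mask is
the leaf region; lesions never alter it. Everything is a pure function of
(config, seed), so datasets regenerate bitwise from their manifest.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

logger = logging.getLogger("amsmlp")

BACKGROUND_STYLES = ("flat", "gradient", "palm_texture", "wood_texture")


@dataclass
class SegSample:
    """One RGB image with its binary ground-truth mask."""

    image: np.ndarray  # float32 [3, H, W] in [0, 1]
    mask: np.ndarray   # uint8 [H, W] in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape[1:] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} disagree"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be strictly binary")


@dataclass
class SplitSpec:
    """70/10/20 split fractions with a shuffle seed."""

    train: float = 0.7
    val: float = 0.1
    test: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class LeafSceneConfig:
    """Parameters of the synthetic leaf-scene generator.

    ``background_style`` may be one of the four styles or ``"random"`` to
    draw a style per scene. Shape parameters are sampled per scene from the
    given ranges. ``fg_fraction_range`` must stay within (0.05, 0.6) so the
    leaf neither vanishes nor fills the frame.
    """

    canvas_size: int = 64
    background_style: str = "random"
    exponent_range: tuple = (1.8, 3.2)     # superellipse squareness
    aspect_range: tuple = (0.55, 0.9)      # minor/major axis ratio
    serration_amp_range: tuple = (0.0, 0.10)
    serration_freq_range: tuple = (6, 14)  # lobes around the boundary
    lesion_count_range: tuple = (0, 4)
    fg_fraction_range: tuple = (0.15, 0.45)
    margin: int = 2                        # border pixels kept leaf-free
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.fg_fraction_range
        if not (0.05 < lo <= hi < 0.6):
            raise ValueError(
                f"fg_fraction_range {self.fg_fraction_range} outside (0.05, 0.6)"
            )
        if self.background_style not in BACKGROUND_STYLES + ("random",):
            raise ValueError(f"unknown background style {self.background_style!r}")


# ---------------------------------------------------------------------------
# polygon annotations
# ---------------------------------------------------------------------------

def _even_odd_inside(px, py, poly):
    """Even-odd rule point-in-polygon test, vectorized over points."""
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ex0, ey0, ex1, ey1 in zip(x0, y0, x1, y1):
        if ey0 == ey1:
            continue
        crosses = (ey0 <= py) != (ey1 <= py)
        xint = ex0 + (py - ey0) * (ex1 - ex0) / (ey1 - ey0)
        inside ^= crosses & (px < xint)
    return inside


def polygons_to_mask(polygons, size):
    """Rasterize a union of polygons into a binary mask.

    Coordinates are pixel units, origin top-left, x rightward, y downward.
    A pixel belongs to the mask iff its center lies inside any polygon by
    the even-odd rule (the LabelMe convention).
    """
    h, w = size
    mask = np.zeros((h, w), dtype=np.uint8)
    if not polygons:
        return mask
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs + 0.5
    py = ys + 0.5
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ValueError(
                f"degenerate polygon with shape {poly.shape}; need >= 3 vertices"
            )
        mask |= _even_odd_inside(px, py, poly).astype(np.uint8)
    return mask


def load_labelme(path, size):
    """Read a LabelMe-style JSON annotation into a binary mask."""
    with open(path) as fh:
        doc = json.load(fh)
    polys = [s["points"] for s in doc.get("shapes", [])]
    return polygons_to_mask(polys, size)


# ---------------------------------------------------------------------------
# standardization and splits
# ---------------------------------------------------------------------------

def standardize(sample, size=512):
    """Resize to ``size`` x ``size``: bilinear image, nearest-neighbor mask."""
    if sample.image.shape[1:] == (size, size):
        return SegSample(sample.image.copy(), sample.mask.copy(), sample.id)
    img = _sk_resize(
        sample.image, (3, size, size), order=1, preserve_range=True,
        anti_aliasing=False,
    ).astype(np.float32)
    msk = _sk_resize(
        sample.mask, (size, size), order=0, preserve_range=True,
        anti_aliasing=False,
    ).astype(np.uint8)
    return SegSample(img, msk, sample.id)


def split_counts(n, spec=None):
    """Train/val/test counts: round-half-up train, floor val, remainder test.

    Computed on exact rationals so e.g. 0.7 * 1385 = 969.5 rounds up to 970
    rather than falling victim to binary floating point.
    """
    from fractions import Fraction

    spec = spec or SplitSpec()
    ft = Fraction(spec.train).limit_denominator(10**6)
    fv = Fraction(spec.val).limit_denominator(10**6)
    n_train = int(ft * n + Fraction(1, 2))  # floor of x + 1/2 = round half up
    n_val = int(fv * n)
    return n_train, n_val, n - n_train - n_val


def split_dataset(ids, spec=None):
    """Deterministic seeded shuffle + 70/10/20 partition of ``ids``."""
    spec = spec or SplitSpec()
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 items to split, got {n}")
    n_train, n_val, n_test = split_counts(n, spec)
    order = np.random.default_rng(spec.seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

def _leaf_mask_from_rng(cfg, rng):
    """Sample a leaf silhouette; returns (mask, info) or raises after retries."""
    s = cfg.canvas_size
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    for _ in range(30):
        n = rng.uniform(*cfg.exponent_range)
        aspect = rng.uniform(*cfg.aspect_range)
        amp = rng.uniform(*cfg.serration_amp_range)
        freq = int(rng.integers(cfg.serration_freq_range[0],
                                cfg.serration_freq_range[1] + 1))
        phase = rng.uniform(0.0, 2.0 * np.pi)
        rot = rng.uniform(0.0, 2.0 * np.pi)
        frac = rng.uniform(*cfg.fg_fraction_range)

        # unit boundary radius and its enclosed area (polar integral)
        rho = (np.abs(np.cos(theta)) ** n + np.abs(np.sin(theta)) ** n) ** (-1.0 / n)
        rho = rho * (1.0 + amp * np.sin(freq * theta + phase))
        unit_area = 0.5 * np.trapezoid(rho**2, dx=2.0 * np.pi / len(theta)) * aspect
        radius = np.sqrt(frac * s * s / unit_area)

        # boundary extent after aspect scaling and rotation -> placement box
        bx = radius * rho * np.cos(theta)
        by = radius * rho * np.sin(theta) * aspect
        rx = bx * np.cos(rot) - by * np.sin(rot)
        ry = bx * np.sin(rot) + by * np.cos(rot)
        pad = cfg.margin + 1.0
        lo_x, hi_x = pad - rx.min(), s - pad - rx.max()
        lo_y, hi_y = pad - ry.min(), s - pad - ry.max()
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)

        ys, xs = np.mgrid[0:s, 0:s].astype(float)
        dx, dy = xs - cx, ys - cy
        # undo rotation, then aspect scaling, then compare to boundary radius
        ux = dx * np.cos(rot) + dy * np.sin(rot)
        uy = (-dx * np.sin(rot) + dy * np.cos(rot)) / aspect
        phi = np.arctan2(uy, ux)
        rr = np.hypot(ux, uy)
        bound = (np.abs(np.cos(phi)) ** n + np.abs(np.sin(phi)) ** n) ** (-1.0 / n)
        bound = bound * (1.0 + amp * np.sin(freq * phi + phase))
        mask = (rr <= radius * bound).astype(np.uint8)

        got = mask.mean()
        border = mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        if border or not (0.05 < got < 0.6):
            continue
        info = {
            "fg_fraction": float(got),
            "exponent": n,
            "aspect": aspect,
            "serration_amp": amp,
            "serration_freq": freq,
            "rotation": rot,
        }
        return mask, info
    raise RuntimeError(
        "could not place a leaf satisfying the foreground-fraction and margin "
        "constraints after 30 attempts"
    )


def make_leaf_mask(cfg, seed):
    """Deterministic leaf silhouette for (cfg, seed)."""
    mask, _ = _leaf_mask_from_rng(cfg, np.random.default_rng(seed))
    return mask


def _background(style, s, rng):
    img = np.zeros((3, s, s), dtype=float)
    ramp = np.linspace(0.0, 1.0, s)
    if style == "flat":
        col = np.array([rng.uniform(0.2, 0.75), rng.uniform(0.15, 0.42),
                        rng.uniform(0.15, 0.6)])
        img += col[:, None, None]
    elif style == "gradient":
        c0 = np.array([rng.uniform(0.2, 0.7), rng.uniform(0.15, 0.4),
                       rng.uniform(0.15, 0.55)])
        c1 = np.array([rng.uniform(0.2, 0.7), rng.uniform(0.15, 0.4),
                       rng.uniform(0.15, 0.55)])
        ang = rng.uniform(0.0, 2.0 * np.pi)
        t = np.cos(ang) * ramp[None, :] + np.sin(ang) * ramp[:, None]
        t = (t - t.min()) / max(t.max() - t.min(), 1e-9)
        img = c0[:, None, None] + (c1 - c0)[:, None, None] * t[None]
    elif style == "palm_texture":
        base = np.array([0.70, 0.42, 0.35])
        tex = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 16.0)
        tex = tex / max(np.abs(tex).max(), 1e-9)
        img = base[:, None, None] + 0.08 * tex[None]
    else:  # wood_texture
        base = np.array([0.45, 0.29, 0.17])
        ang = rng.uniform(0.0, np.pi)
        freq = rng.uniform(4.0, 9.0)
        t = np.cos(ang) * ramp[None, :] + np.sin(ang) * ramp[:, None]
        grain = 0.05 * np.sin(2.0 * np.pi * freq * t)
        tex = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 32.0)
        tex = tex / max(np.abs(tex).max(), 1e-9)
        img = base[:, None, None] + grain[None] + 0.03 * tex[None]
    img += 0.02 * rng.standard_normal((3, s, s))
    return img


def _generate_scene(cfg, seed):
    rng = np.random.default_rng(seed)
    s = cfg.canvas_size
    mask, info = _leaf_mask_from_rng(cfg, rng)

    style = cfg.background_style
    if style == "random":
        style = BACKGROUND_STYLES[int(rng.integers(len(BACKGROUND_STYLES)))]
    img = _background(style, s, rng)

    # leaf fill: shaded green gradient
    leaf = np.array([rng.uniform(0.15, 0.35), rng.uniform(0.58, 0.75),
                     rng.uniform(0.10, 0.30)])
    ang = rng.uniform(0.0, 2.0 * np.pi)
    ramp = np.linspace(-1.0, 1.0, s)
    shade = 0.08 * (np.cos(ang) * ramp[None, :] + np.sin(ang) * ramp[:, None])
    leaf_img = leaf[:, None, None] + shade[None] \
        + 0.02 * rng.standard_normal((3, s, s))
    fg = mask.astype(bool)
    img[:, fg] = leaf_img[:, fg]

    # lesion-like blemishes, strictly inside the leaf, mask unchanged
    n_lesions = int(rng.integers(cfg.lesion_count_range[0],
                                 cfg.lesion_count_range[1] + 1))
    ys, xs = np.nonzero(mask)
    lesion_color = np.array([0.30, 0.18, 0.10])
    lesion_mask = np.zeros_like(fg)
    for _ in range(n_lesions):
        if len(ys) == 0:
            break
        k = int(rng.integers(len(ys)))
        cy, cx = ys[k], xs[k]
        ry = rng.uniform(s / 32.0, s / 10.0)
        rx = rng.uniform(s / 32.0, s / 10.0)
        gy, gx = np.mgrid[0:s, 0:s].astype(float)
        blob = ((gy - cy) / ry) ** 2 + ((gx - cx) / rx) ** 2 <= 1.0
        blob &= fg
        lesion_mask |= blob
        img[:, blob] = lesion_color[:, None] \
            + 0.02 * rng.standard_normal((3, int(blob.sum())))

    img += 0.015 * rng.standard_normal((3, s, s))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    info.update({"seed": int(seed), "style": style, "lesion_mask": lesion_mask})
    return SegSample(img, mask, f"scene_{seed:08d}"), info


def generate_scene(cfg, seed):
    """One synthetic leaf scene, deterministic in (cfg, seed)."""
    sample, _ = _generate_scene(cfg, seed)
    return sample


def generate_dataset(n, cfg, seed):
    """n scenes from consecutive seeds ``seed..seed+n-1`` plus a manifest."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    samples, manifest = [], []
    for k in range(n):
        sample, info = _generate_scene(cfg, seed + k)
        samples.append(sample)
        manifest.append(
            {
                "id": sample.id,
                "seed": info["seed"],
                "style": info["style"],
                "fg_fraction": info["fg_fraction"],
            }
        )
    return samples, manifest


# ---------------------------------------------------------------------------
# on-disk layout: images/, masks/, splits/{train,val,test}.txt, manifest.csv
# ---------------------------------------------------------------------------

def save_sample(sample, root):
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "masks").mkdir(parents=True, exist_ok=True)
    img = (np.clip(sample.image, 0.0, 1.0) * 255).round().astype(np.uint8)
    Image.fromarray(img.transpose(1, 2, 0)).save(root / "images" / f"{sample.id}.png")
    Image.fromarray(sample.mask, mode="L").save(root / "masks" / f"{sample.id}.png")


def save_dataset(samples, manifest, root, split_spec=None):
    """Materialize a dataset directory with splits and a manifest CSV."""
    root = Path(root)
    for s in samples:
        save_sample(s, root)
    (root / "splits").mkdir(parents=True, exist_ok=True)
    train, val, test = split_dataset([s.id for s in samples], split_spec)
    for name, ids in (("train", train), ("val", val), ("test", test)):
        (root / "splits" / f"{name}.txt").write_text("\n".join(ids) + "\n")
    with open(root / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "seed", "style", "fg_fraction"])
        writer.writeheader()
        for row in manifest:
            writer.writerow({**row, "fg_fraction": f"{row['fg_fraction']:.6f}"})


def load_image(path):
    """RGB image file -> float32 [3, H, W] in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_mask(path):
    """Mask PNG -> binary uint8; {0, 255} encodings are normalized (logged)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    vals = np.unique(arr)
    if np.isin(vals, (0, 255)).all() and 255 in vals:
        logger.info("normalizing {0,255} mask %s to {0,1}", path)
        arr = (arr > 127).astype(np.uint8)
    elif not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask {path} has values {vals[:10]}, expected binary")
    return arr.astype(np.uint8)


def load_sample(root, sample_id):
    root = Path(root)
    return SegSample(
        load_image(root / "images" / f"{sample_id}.png"),
        load_mask(root / "masks" / f"{sample_id}.png"),
        sample_id,
    )


def load_split(root, name):
    """Load all samples of one split ('train' | 'val' | 'test')."""
    root = Path(root)
    ids = (root / "splits" / f"{name}.txt").read_text().split()
    return [load_sample(root, sid) for sid in ids]
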