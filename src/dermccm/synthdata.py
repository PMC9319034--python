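"""Seeded generator of pattern-labeled, dermoscopy-like synthetic tiles.

Real annotated BCC-pattern tiles come from private hospital collections,
so the toolkit ships a generator of lesion-like stand-ins: a skin-toned
background with Gaussian channel noise, on which one motif per dermoscopic
pattern is drawn from a per-pattern color palette:

    pigment_network  -> reticular_mesh      brown grid of lines
    ulceration       -> erosion_patch       red/white irregular patch
    ovoid_nest       -> ovoid_blobs         few large blue-gray ellipses
    multi_globules   -> scattered_globules  many small blue-gray discs
    maple_leaf       -> leaflets            brown lobed polygons near border
    spoke_wheel      -> radial_spokes       lines radiating from a hub
    telangiectasia   -> branching_lines     red branching curves

The geometry is deliberately simple — the generator exists to exercise the
color, texture and classification machinery with a known planted structure,
not to imitate real lesions.  Everything is deterministic given the seed.

The augmentation scheme quadruples a set of tiles: each image yields its
0/90/180/270-degree rotations, and every variant is then independently
flipped horizontally and/or vertically with probability 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .palette import PATTERN_CLASSES

__all__ = [
    "PatternRecipe",
    "SyntheticDataset",
    "DEFAULT_RECIPES",
    "make_pattern_image",
    "compose_multi_pattern",
    "make_dataset",
    "augment",
]

MOTIFS = (
    "reticular_mesh", "erosion_patch", "ovoid_blobs", "scattered_globules",
    "leaflets", "radial_spokes", "branching_lines",
)
_PATTERN_MOTIF = dict(zip(PATTERN_CLASSES, MOTIFS))

_SKIN = (0.87, 0.71, 0.64)


@dataclass(frozen=True, eq=False)
class PatternRecipe:
    pattern: str
    fg_colors: tuple
    bg_color: tuple = _SKIN
    density: float = 1.0
    scale: float = 1.0
    noise_sd: float = 0.02

    @property
    def motif(self) -> str:
        return _PATTERN_MOTIF[self.pattern]

    def __post_init__(self):
        if self.pattern not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not self.fg_colors:
            raise ValueError("fg_colors must be non-empty")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


DEFAULT_RECIPES = {
    "pigment_network": PatternRecipe(
        "pigment_network", ((0.42, 0.28, 0.18), (0.51, 0.35, 0.23))),
    "ulceration": PatternRecipe(
        "ulceration", ((0.72, 0.12, 0.12), (0.93, 0.88, 0.84))),
    "ovoid_nest": PatternRecipe(
        "ovoid_nest", ((0.28, 0.34, 0.48), (0.36, 0.42, 0.55))),
    "multi_globules": PatternRecipe(
        "multi_globules", ((0.47, 0.55, 0.67), (0.55, 0.62, 0.72))),
    "maple_leaf": PatternRecipe(
        "maple_leaf", ((0.33, 0.20, 0.12), (0.43, 0.28, 0.18))),
    "spoke_wheel": PatternRecipe(
        "spoke_wheel", ((0.56, 0.44, 0.35), (0.64, 0.53, 0.44))),
    "telangiectasia": PatternRecipe(
        "telangiectasia", ((0.78, 0.22, 0.26), (0.86, 0.36, 0.39))),
}


@dataclass(frozen=True, eq=False)
class SyntheticDataset:
    images: list  # H x W x 3 float arrays in [0, 1]
    labels: np.ndarray  # (N, 7) binary, fixed pattern order
    seed: int
    recipes: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.images)


def _pick(rng, colors):
    return np.asarray(colors[rng.integers(len(colors))], dtype=float)


def _thick_mask(H, W, segments, thickness):
    mask = np.zeros((H, W), dtype=bool)
    for (r0, c0, r1, c1) in segments:
        rr, cc = draw.line(int(r0), int(c0), int(r1), int(c1))
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        mask[rr[ok], cc[ok]] = True
    if thickness > 1:
        mask = ndimage.binary_dilation(mask, iterations=int(thickness) - 1)
    return mask


def _paint(img, mask, rng, colors):
    img[mask] = _pick(rng, colors)


def _motif_reticular_mesh(img, rng, rec):
    H, W = img.shape[:2]
    spacing = max(6, int(12 * rec.scale * min(H, W) / 64))
    amp = spacing / 3
    segs = []
    for r in range(0, H + spacing, spacing):
        pts = np.arange(0, W, 4)
        wav = r + amp * np.sin(pts / spacing + rng.uniform(0, 6.28))
        segs += [(wav[i], pts[i], wav[i + 1], pts[i + 1]) for i in range(len(pts) - 1)]
    for c in range(0, W + spacing, spacing):
        pts = np.arange(0, H, 4)
        wav = c + amp * np.sin(pts / spacing + rng.uniform(0, 6.28))
        segs += [(pts[i], wav[i], pts[i + 1], wav[i + 1]) for i in range(len(pts) - 1)]
    n_keep = int(round(len(segs) * min(rec.density, 1.0)))
    keep = rng.permutation(len(segs))[:n_keep]
    mask = _thick_mask(H, W, [segs[i] for i in keep], max(1, min(H, W) // 64))
    _paint(img, mask, rng, rec.fg_colors)


def _motif_erosion_patch(img, rng, rec):
    H, W = img.shape[:2]
    cy, cx = rng.uniform(0.3, 0.7) * H, rng.uniform(0.3, 0.7) * W
    n = int(round(20 * rec.density))
    for _ in range(n):
        r = rng.uniform(0.06, 0.14) * min(H, W) * rec.scale
        y = cy + rng.normal(0, 0.12 * H)
        x = cx + rng.normal(0, 0.12 * W)
        rr, cc = draw.disk((y, x), r, shape=(H, W))
        img[rr, cc] = _pick(rng, rec.fg_colors)


def _motif_ovoid_blobs(img, rng, rec):
    H, W = img.shape[:2]
    n = max(1, int(round(4 * rec.density)))
    for _ in range(n):
        ry = rng.uniform(0.10, 0.17) * H * rec.scale
        rx = rng.uniform(0.07, 0.12) * W * rec.scale
        y, x = rng.uniform(0.2, 0.8) * H, rng.uniform(0.2, 0.8) * W
        rr, cc = draw.ellipse(y, x, ry, rx, shape=(H, W),
                              rotation=rng.uniform(0, np.pi))
        img[rr, cc] = _pick(rng, rec.fg_colors)


def _motif_scattered_globules(img, rng, rec):
    H, W = img.shape[:2]
    n = int(round(40 * rec.density))
    r = max(1.5, 0.02 * min(H, W) * rec.scale)
    for _ in range(n):
        y, x = rng.uniform(0.05, 0.95) * H, rng.uniform(0.05, 0.95) * W
        rr, cc = draw.disk((y, x), r * rng.uniform(0.7, 1.3), shape=(H, W))
        img[rr, cc] = _pick(rng, rec.fg_colors)


def _motif_leaflets(img, rng, rec):
    H, W = img.shape[:2]
    n = max(1, int(round(6 * rec.density)))
    base = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        ang = base + 2 * np.pi * i / n + rng.normal(0, 0.15)
        cy = H / 2 + 0.38 * H * np.sin(ang)
        cx = W / 2 + 0.38 * W * np.cos(ang)
        lobes = rng.integers(5, 8)
        th = np.linspace(0, 2 * np.pi, lobes, endpoint=False)
        rad = 0.09 * min(H, W) * rec.scale * rng.uniform(0.7, 1.2, lobes)
        rr, cc = draw.polygon(cy + rad * np.sin(th), cx + rad * np.cos(th),
                              shape=(H, W))
        img[rr, cc] = _pick(rng, rec.fg_colors)


def _motif_radial_spokes(img, rng, rec):
    H, W = img.shape[:2]
    cy, cx = rng.uniform(0.35, 0.65) * H, rng.uniform(0.35, 0.65) * W
    rr, cc = draw.disk((cy, cx), 0.05 * min(H, W) * rec.scale, shape=(H, W))
    img[rr, cc] = _pick(rng, rec.fg_colors)
    n = max(3, int(round(12 * rec.density)))
    L = 0.30 * min(H, W) * rec.scale
    segs = []
    for i in range(n):
        ang = 2 * np.pi * i / n + rng.normal(0, 0.08)
        segs.append((cy, cx, cy + L * np.sin(ang), cx + L * np.cos(ang)))
    mask = _thick_mask(H, W, segs, max(1, min(H, W) // 80))
    _paint(img, mask, rng, rec.fg_colors)


def _motif_branching_lines(img, rng, rec):
    H, W = img.shape[:2]
    segs = []

    def grow(y, x, ang, length, depth):
        if depth == 0 or length < 2:
            return
        y2 = y + length * np.sin(ang)
        x2 = x + length * np.cos(ang)
        segs.append((y, x, y2, x2))
        n_child = 2 if rng.random() < 0.6 else 1
        for _ in range(n_child):
            grow(y2, x2, ang + rng.normal(0, 0.5), length * 0.8, depth - 1)

    n_trees = max(1, int(round(3 * rec.density)))
    for _ in range(n_trees):
        edge = rng.integers(4)
        y0 = {0: 0, 1: H - 1}.get(edge, rng.uniform(0, H))
        x0 = {2: 0, 3: W - 1}.get(edge, rng.uniform(0, W))
        ang0 = np.arctan2(H / 2 - y0, W / 2 - x0) + rng.normal(0, 0.3)
        grow(y0, x0, ang0, 0.14 * min(H, W) * rec.scale, 5)
    mask = _thick_mask(H, W, segs, max(1, min(H, W) // 80))
    _paint(img, mask, rng, rec.fg_colors)


_RENDERERS = {
    "reticular_mesh": _motif_reticular_mesh,
    "erosion_patch": _motif_erosion_patch,
    "ovoid_blobs": _motif_ovoid_blobs,
    "scattered_globules": _motif_scattered_globules,
    "leaflets": _motif_leaflets,
    "radial_spokes": _motif_radial_spokes,
    "branching_lines": _motif_branching_lines,
}


def _background(rec, size, rng):
    H, W = size
    img = np.full((H, W, 3), rec.bg_color, dtype=float)
    if rec.noise_sd > 0:
        img += rng.normal(0, rec.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _one_hot(pattern: str) -> np.ndarray:
    lab = np.zeros(len(PATTERN_CLASSES), dtype=int)
    lab[PATTERN_CLASSES.index(pattern)] = 1
    return lab


def make_pattern_image(recipe: PatternRecipe, size=(256, 256), seed: int = 0):
    """Render one single-pattern tile. Returns (image, one-hot label)."""
    H, W = size
    if H < 32 or W < 32:
        raise ValueError(f"tile size must be at least 32x32, got {size}")
    rng = np.random.default_rng(seed)
    img = _background(recipe, size, rng)
    if recipe.density > 0:
        _RENDERERS[recipe.motif](img, rng, recipe)
    return np.clip(img, 0.0, 1.0), _one_hot(recipe.pattern)


def compose_multi_pattern(recipes: Sequence[PatternRecipe], size=(256, 256), seed: int = 0):
    """Render several motifs on one shared background; the label is the
    union of the individual one-hots."""
    if not recipes:
        raise ValueError("need at least one recipe")
    rng = np.random.default_rng(seed)
    img = _background(recipes[0], size, rng)
    label = np.zeros(len(PATTERN_CLASSES), dtype=int)
    for rec in recipes:
        if rec.density > 0:
            _RENDERERS[rec.motif](img, rng, rec)
        label |= _one_hot(rec.pattern)
    return np.clip(img, 0.0, 1.0), label


def make_dataset(
    n_per_pattern: int,
    size=(256, 256),
    seed: int = 0,
    include_nonbcc: bool = True,
    *,
    composite_fraction: float = 0.15,
    benign_fraction: float = 0.15,
    recipes: dict | None = None,
) -> SyntheticDataset:
    """Seeded dataset: ``n_per_pattern`` single-pattern tiles per class,
    plus a fraction of two-pattern composites and (optionally) pattern-free
    benign tiles."""
    if n_per_pattern < 1:
        raise ValueError("n_per_pattern must be at least 1")
    recipes = dict(DEFAULT_RECIPES, **(recipes or {}))
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for pattern in PATTERN_CLASSES:
        for _ in range(n_per_pattern):
            img, lab = make_pattern_image(
                recipes[pattern], size, seed=int(rng.integers(2**31))
            )
            images.append(img)
            labels.append(lab)
    n_single = len(images)
    n_comp = int(round(composite_fraction * n_single))
    for _ in range(n_comp):
        pair = rng.choice(len(PATTERN_CLASSES), size=2, replace=False)
        recs = [recipes[PATTERN_CLASSES[i]] for i in pair]
        img, lab = compose_multi_pattern(recs, size, seed=int(rng.integers(2**31)))
        images.append(img)
        labels.append(lab)
    if include_nonbcc:
        benign = replace(recipes["pigment_network"], density=0.0)
        for _ in range(int(round(benign_fraction * n_single))):
            img, _ = make_pattern_image(benign, size, seed=int(rng.integers(2**31)))
            images.append(img)
            labels.append(np.zeros(len(PATTERN_CLASSES), dtype=int))
    return SyntheticDataset(
        images=images, labels=np.asarray(labels), seed=seed, recipes=recipes
    )


def augment(images: Sequence[np.ndarray], seed: int = 0, labels=None):
    """Quadruple a tile set: each input yields its 4 rotations, each variant
    independently flipped horizontally / vertically with probability 1/2.
    Labels (if given) are duplicated unchanged."""
    rng = np.random.default_rng(seed)
    out, out_labels = [], []
    for i, img in enumerate(images):
        for k in range(4):
            v = np.rot90(img, k)
            if rng.random() < 0.5:
                v = v[:, ::-1]
            if rng.random() < 0.5:
                v = v[::-1, :]
            out.append(np.ascontiguousarray(v))
            if labels is not None:
                out_labels.append(labels[i])
    if labels is not None:
        return out, np.asarray(out_labels)
    return out
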