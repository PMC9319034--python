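"""Perceptual palette learning and image quantization.

The master palette of "main lesion colors" is built in two stages:

1. per-pattern K-means (Euclidean, in a uniform working color space) over
   the pooled pixels of every training tile of that dermoscopic pattern —
   by default 18 centroids per pattern;
2. threshold merging: centroids from different patterns closer than a
   Delta-E threshold are merged (single-linkage connected components,
   weight-weighted means), with the threshold auto-adjusted by bisection
   so that a fixed number of colors (default 20) is retained.

Images are then quantized by nearest-centroid assignment in the working
space, which makes co-occurrence statistics over the palette indices
perceptually meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import colorspace as cs
from .colorspace import ViewingConditions

__all__ = [
    "PATTERN_CLASSES",
    "POSITIVE_PATTERNS",
    "Centroid",
    "Palette",
    "QuantizedImage",
    "cluster_pattern_colors",
    "merge_step",
    "build_master_palette",
    "quantize",
    "render_quantized",
    "read_palette",
    "write_palette",
]

# The seven dermoscopic structures, fixed order. pigment_network is the
# sole negative criterion (its presence argues against BCC).
PATTERN_CLASSES = (
    "pigment_network",
    "ulceration",
    "ovoid_nest",
    "multi_globules",
    "maple_leaf",
    "spoke_wheel",
    "telangiectasia",
)
POSITIVE_PATTERNS = PATTERN_CLASSES[1:]


class PaletteError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class Centroid:
    """One palette color: working-space coordinates, an sRGB rendering for
    display, the pixel mass it represents and the patterns it came from."""

    color: np.ndarray  # 3-vector in the working space
    srgb: np.ndarray  # 3-vector in [0,1], display only
    weight: float
    sources: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "color", np.asarray(self.color, dtype=float))
        object.__setattr__(self, "srgb", np.asarray(self.srgb, dtype=float))
        object.__setattr__(self, "sources", frozenset(self.sources))
        if self.weight <= 0:
            raise PaletteError(f"centroid weight must be positive, got {self.weight}")


@dataclass(frozen=True, eq=False)
class Palette:
    centroids: tuple
    space: str  # 'lab' or 'cam16ucs'
    vc: ViewingConditions = field(default_factory=ViewingConditions)

    def __len__(self):
        return len(self.centroids)

    @property
    def colors(self) -> np.ndarray:
        """(n, 3) array of working-space centroid coordinates."""
        return np.stack([c.color for c in self.centroids])

    @property
    def srgb(self) -> np.ndarray:
        return np.stack([c.srgb for c in self.centroids])

    def distance_table(self) -> np.ndarray:
        """Pairwise Delta-E between palette colors (symmetric, zero diag)."""
        c = self.colors
        return cs.delta_e(c[:, None, :], c[None, :, :], self.space)


@dataclass(frozen=True, eq=False)
class QuantizedImage:
    indices: np.ndarray  # (H, W) integer palette indices
    palette: Palette

    def __post_init__(self):
        idx = np.asarray(self.indices)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.palette)):
            raise PaletteError("quantized indices outside palette range")

    @property
    def shape(self):
        return self.indices.shape


def cluster_pattern_colors(
    pixels: np.ndarray,
    k: int = 18,
    seed: int = 0,
    *,
    source: str | None = None,
    space: str = "cam16ucs",
    vc: ViewingConditions | None = None,
    n_init: int = 10,
    max_iter: int = 300,
) -> list[Centroid]:
    """Stage-1 clustering: K-means over working-space pixels of one pattern.

    ``pixels`` is (N, 3) in the working space. Centroid sRGB renderings are
    taken as the working->sRGB inverse of the centroid color; the weight is
    the cluster pixel count. Deterministic for a given ``seed``.
    """
    pixels = np.asarray(pixels, dtype=float).reshape(-1, 3)
    n_distinct = np.unique(pixels, axis=0).shape[0]
    if n_distinct < k:
        raise PaletteError(
            f"need at least k={k} distinct colors, found only {n_distinct}"
        )
    km = KMeans(
        n_clusters=k, init="random", n_init=n_init, max_iter=max_iter,
        tol=1e-6, random_state=seed,
    ).fit(pixels)
    sources = frozenset() if source is None else frozenset({source})
    vc = vc or ViewingConditions()
    out = []
    for i in range(k):
        mass = int(np.sum(km.labels_ == i))
        color = km.cluster_centers_[i]
        out.append(
            Centroid(
                color=color,
                srgb=cs.working_to_srgb(color, space, vc),
                weight=float(mass),
                sources=sources,
            )
        )
    return out


def _components(dist: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the 'Delta-E < threshold' graph (single
    linkage), ordered by smallest member index."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def _collapse(centroids: Sequence[Centroid], members: Iterable[int], space: str, vc) -> Centroid:
    members = list(members)
    w = np.array([centroids[i].weight for i in members])
    c = np.stack([centroids[i].color for i in members])
    color = (w[:, None] * c).sum(axis=0) / w.sum()
    sources = frozenset().union(*(centroids[i].sources for i in members))
    return Centroid(
        color=color,
        srgb=cs.working_to_srgb(color, space, vc),
        weight=float(w.sum()),
        sources=sources,
    )


def merge_step(
    centroids: Sequence[Centroid], threshold: float, *, space: str = "cam16ucs",
    vc: ViewingConditions | None = None,
) -> list[Centroid]:
    """Merge every group of centroids linked by Delta-E < threshold into its
    weight-weighted mean. Output ordered by first-member original index."""
    if threshold <= 0:
        raise PaletteError("merge threshold must be positive")
    vc = vc or ViewingConditions()
    c = np.stack([x.color for x in centroids])
    dist = cs.delta_e(c[:, None, :], c[None, :, :], space)
    return [_collapse(centroids, comp, space, vc) for comp in _components(dist, threshold)]


def _split_largest(groups: list[list[int]], dist: np.ndarray) -> list[list[int]]:
    """Split the largest multi-member group at its farthest internal pair."""
    sizes = [len(g) for g in groups]
    gi = int(np.argmax(sizes))
    g = groups[gi]
    sub = dist[np.ix_(g, g)]
    a, b = np.unravel_index(np.argmax(sub), sub.shape)
    seed_a, seed_b = g[a], g[b]
    ga = [m for m in g if dist[m, seed_a] <= dist[m, seed_b]]
    gb = [m for m in g if m not in ga]
    out = groups[:gi] + [sorted(ga), sorted(gb)] + groups[gi + 1:]
    return sorted(out, key=lambda grp: grp[0])


def build_master_palette(
    per_pattern: Mapping[str, Sequence[Centroid]],
    target_n: int = 20,
    *,
    space: str = "cam16ucs",
    vc: ViewingConditions | None = None,
    bisection_iters: int = 60,
) -> Palette:
    """Stage-2 merging of all per-pattern centroids to exactly ``target_n``
    colors.

    The merge threshold is found by bisection on Delta-E; when the component
    count jumps past ``target_n`` (tied distances), the largest merged
    component is split at its farthest internal pair until the count is
    exact.  Deterministic.
    """
    vc = vc or ViewingConditions()
    pool: list[Centroid] = []
    for pattern in PATTERN_CLASSES:
        if pattern in per_pattern:
            pool.extend(per_pattern[pattern])
    for pattern in per_pattern:
        if pattern not in PATTERN_CLASSES:
            raise PaletteError(f"unknown pattern class {pattern!r}")
    m = len(pool)
    if m < target_n:
        raise PaletteError(f"cannot retain {target_n} colors from {m} input centroids")
    c = np.stack([x.color for x in pool])
    dist = cs.delta_e(c[:, None, :], c[None, :, :], space)
    if m == target_n:
        groups = [[i] for i in range(m)]
    else:
        lo, hi = 0.0, float(dist.max()) * 1.0001 + 1e-9
        groups = None
        for _ in range(bisection_iters):
            mid = 0.5 * (lo + hi)
            comps = _components(dist, mid)
            if len(comps) == target_n:
                groups = comps
                break
            if len(comps) > target_n:  # threshold too small, merge more
                lo = mid
            else:
                hi = mid
        if groups is None:
            # plateau jump: over-merge slightly, then split back to exact count
            groups = _components(dist, hi)
            while len(groups) < target_n:
                groups = _split_largest(groups, dist)
    centroids = tuple(_collapse(pool, g, space, vc) for g in groups)
    return Palette(centroids=centroids, space=space, vc=vc)


def quantize(image: np.ndarray, palette: Palette) -> QuantizedImage:
    """Nearest-centroid quantization of an sRGB image (H, W, 3) in the
    palette's working space; ties broken toward the lowest index."""
    if len(palette) == 0:
        raise PaletteError("empty palette")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise PaletteError(f"expected (H, W, 3) image, got shape {img.shape}")
    work = cs.srgb_to_working(img.reshape(-1, 3), palette.space, palette.vc)
    d2 = ((work[:, None, :] - palette.colors[None, :, :]) ** 2).sum(axis=-1)
    idx = np.argmin(d2, axis=1).astype(np.int32)
    return QuantizedImage(indices=idx.reshape(img.shape[:2]), palette=palette)


def render_quantized(q: QuantizedImage) -> np.ndarray:
    """Replace every pixel by its centroid's sRGB rendering."""
    return q.palette.srgb[q.indices]


# ---------------------------------------------------------------------------
# JSON serialization

_SCHEMA_SPACES = ("lab", "cam16ucs")


def _palette_to_dict(p: Palette) -> dict:
    return {
        "space": p.space,
        "viewing": {
            "white": [float(x) for x in p.vc.white],
            "L_A": p.vc.L_A,
            "Y_b": p.vc.Y_b,
            "surround": p.vc.surround,
            "discount_illuminant": p.vc.discount_illuminant,
        },
        "centroids": [
            {
                "color": [float(x) for x in c.color],
                "srgb": [float(x) for x in c.srgb],
                "weight": c.weight,
                "sources": sorted(c.sources),
            }
            for c in p.centroids
        ],
    }


def write_palette(p: Palette, path) -> None:
    Path(path).write_text(json.dumps(_palette_to_dict(p), indent=1))


def read_palette(path) -> Palette:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise PaletteError(f"palette file is not valid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise PaletteError("palette: top-level object expected")
    space = doc.get("space")
    if space not in _SCHEMA_SPACES:
        raise PaletteError(f"palette.space: expected one of {_SCHEMA_SPACES}, got {space!r}")
    v = doc.get("viewing", {})
    try:
        vc = ViewingConditions(
            white=np.asarray(v.get("white", D65_DEFAULT), dtype=float),
            L_A=float(v.get("L_A", 64.0)),
            Y_b=float(v.get("Y_b", 20.0)),
            surround=v.get("surround", "average"),
            discount_illuminant=bool(v.get("discount_illuminant", True)),
        )
    except (TypeError, ValueError) as e:
        raise PaletteError(f"palette.viewing: {e}") from e
    cents = doc.get("centroids")
    if not isinstance(cents, list) or not cents:
        raise PaletteError("palette.centroids: non-empty list expected")
    out = []
    for i, c in enumerate(cents):
        try:
            color = np.asarray(c["color"], dtype=float)
            srgb = np.asarray(c["srgb"], dtype=float)
            if color.shape != (3,) or srgb.shape != (3,):
                raise ValueError("color/srgb must be 3-vectors")
            sources = c.get("sources", [])
            bad = [s for s in sources if s not in PATTERN_CLASSES]
            if bad:
                raise ValueError(f"unknown source pattern(s) {bad}")
            out.append(
                Centroid(color=color, srgb=srgb, weight=float(c["weight"]),
                         sources=frozenset(sources))
            )
        except (KeyError, TypeError, ValueError) as e:
            raise PaletteError(f"palette.centroids[{i}]: {e}") from e
    return Palette(centroids=tuple(out), space=space, vc=vc)


D65_DEFAULT = [95.047, 100.0, 108.883]
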