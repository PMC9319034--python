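"""Co-occurrence texture analysis.

Two descriptors are provided:

* the classical gray-level co-occurrence matrix (GLCM) on the L* channel
  of CIELAB, and
* a perceptual *color* co-occurrence matrix (CCM) over the palette indices
  of a quantized image, whose statistics replace the integer bin distance
  |i - j| by the perceptual color difference Delta-E(C_i, C_j) between the
  palette colors.

Five statistics are extracted from either matrix P (n x n, sum 1):

    homogeneity  H   = sum_ij P_ij / (1 + dE(C_i, C_j)^2)
    mean         mu  = sum_ij C_i P_ij              (the image mean color)
    variance     s2  = sum_ij dE(C_i, mu)^2 P_ij    (perceptual contrast)
    correlation  rho = sum_ij dE(C_i,mu_i) dE(C_j,mu_j) P_ij / (s_i s_j)
    entropy      S   = sum_ij -P_ij ln P_ij         (0 for constant images)

For the GLCM, C_i is the bin index and dE is |i - j|, so the formulas
reduce to (variants of) the familiar Haralick statistics.  Because dE is
non-negative, "correlation" here is a non-negative co-dispersion index
rather than a signed correlation; it is implemented exactly as defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import colorspace as cs
from .palette import Palette, QuantizedImage, quantize

__all__ = [
    "OffsetSpec",
    "CooccurrenceMatrix",
    "TextureFeatureVector",
    "compute_glcm",
    "glcm_features",
    "compute_ccm",
    "ccm_distance_table",
    "ccm_features",
    "image_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("homogeneity", "mean_1", "mean_2", "mean_3", "variance",
                 "correlation", "entropy")

# distance-1 offsets at 0, 45, 90, 135 degrees (the Haralick default)
D1_4DIR = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


class TextureError(ValueError):
    pass


@dataclass(frozen=True, eq=False)
class OffsetSpec:
    """Relative pixel displacements (dy, dx) over which pairs are counted."""

    offsets: tuple = D1_4DIR
    symmetric: bool = True

    def __post_init__(self):
        offs = tuple(tuple(int(v) for v in o) for o in self.offsets)
        object.__setattr__(self, "offsets", offs)
        if (0, 0) in offs:
            raise TextureError("(0, 0) is not a valid co-occurrence offset")
        if len(set(offs)) != len(offs):
            raise TextureError("duplicate offsets")


@dataclass(frozen=True, eq=False)
class CooccurrenceMatrix:
    P: np.ndarray  # (n, n), non-negative, sums to 1
    spec: OffsetSpec
    kind: Literal["gray", "color"]
    palette: Palette | None = None  # required when kind == 'color'
    bin_centers: np.ndarray | None = None  # gray-level bin centers (kind='gray')

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True, eq=False)
class TextureFeatureVector:
    homogeneity: float
    mean_color: np.ndarray  # working-space 3-vector (GLCM: (mean, 0, 0))
    variance: float
    correlation: float
    entropy: float
    per_offset: dict | None = None

    def as_record(self) -> dict:
        m = np.atleast_1d(self.mean_color)
        m = np.pad(m.astype(float), (0, 3 - m.size))
        return dict(zip(FEATURE_NAMES,
                        (self.homogeneity, m[0], m[1], m[2],
                         self.variance, self.correlation, self.entropy)))


def _pair_counts(idx: np.ndarray, n: int, spec: OffsetSpec) -> np.ndarray:
    """Accumulate co-occurrence counts of an integer index map over all
    offsets of ``spec`` (transposed pairs added when symmetric)."""
    H, W = idx.shape
    counts = np.zeros((n, n), dtype=np.int64)
    for dy, dx in spec.offsets:
        if abs(dy) >= H or abs(dx) >= W:
            raise TextureError(
                f"offset {(dy, dx)} does not fit a {H}x{W} image"
            )
        ys = slice(max(0, -dy), min(H, H - dy))
        xs = slice(max(0, -dx), min(W, W - dx))
        a = idx[ys, xs]
        b = idx[ys.start + dy: ys.stop + dy, xs.start + dx: xs.stop + dx]
        np.add.at(counts, (a.ravel(), b.ravel()), 1)
    if spec.symmetric:
        counts = counts + counts.T
    return counts


def compute_glcm(
    gray: np.ndarray,
    levels: int = 32,
    value_range: tuple[float, float] = (0.0, 100.0),
    spec: OffsetSpec | None = None,
) -> CooccurrenceMatrix:
    """GLCM of a real-valued image, uniformly binned into ``levels`` bins
    over ``value_range`` (values outside are clipped)."""
    spec = spec or OffsetSpec()
    if levels < 2:
        raise TextureError("need at least 2 gray levels")
    lo, hi = value_range
    if hi <= lo:
        raise TextureError("value_range must satisfy hi > lo")
    g = np.clip(np.asarray(gray, dtype=float), lo, hi)
    idx = np.minimum((levels * (g - lo) / (hi - lo)).astype(np.int64), levels - 1)
    counts = _pair_counts(idx, levels, spec)
    centers = lo + (np.arange(levels) + 0.5) * (hi - lo) / levels
    return CooccurrenceMatrix(
        P=counts / counts.sum(), spec=spec, kind="gray", bin_centers=centers
    )


def compute_ccm(q: QuantizedImage, spec: OffsetSpec | None = None) -> CooccurrenceMatrix:
    """Color co-occurrence matrix over the palette indices of ``q``."""
    spec = spec or OffsetSpec()
    counts = _pair_counts(np.asarray(q.indices, dtype=np.int64), len(q.palette), spec)
    return CooccurrenceMatrix(
        P=counts / counts.sum(), spec=spec, kind="color", palette=q.palette
    )


def ccm_distance_table(palette: Palette) -> np.ndarray:
    """Delta-E between every pair of palette colors (Eq.-appropriate for the
    palette's working space)."""
    return palette.distance_table()


def _five_stats(P, coords, dtable, denominator="sigma_product"):
    """The five statistics for matrix P with per-index 'colors' ``coords``
    ((n, d) array) and pairwise distance table ``dtable``."""
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    homog = float(np.sum(P / (1.0 + dtable**2)))
    mu_row = p_row @ coords
    mu_col = p_col @ coords
    d_row = np.sqrt(np.sum((coords - mu_row) ** 2, axis=1))
    d_col = np.sqrt(np.sum((coords - mu_col) ** 2, axis=1))
    variance = float(np.sum(P * d_row[:, None] ** 2))
    sigma_row = np.sqrt(np.sum(p_row * d_row**2))
    sigma_col = np.sqrt(np.sum(p_col * d_col**2))
    if sigma_row * sigma_col <= 0:
        correlation = 0.0  # constant image: 0/0 guarded by convention
    else:
        denom = (
            sigma_row * sigma_col
            if denominator == "sigma_product"
            else sigma_row**2 * sigma_col**2
        )
        correlation = float(np.sum(P * np.outer(d_row, d_col)) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-np.sum(np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0)))
    # sum_ij C_i P_ij collapses over j, i.e. the row-marginal mean
    return homog, mu_row, variance, correlation, entropy


def glcm_features(m: CooccurrenceMatrix, denominator: str = "sigma_product") -> TextureFeatureVector:
    """Five statistics of a GLCM, with bin index i standing in for C_i and
    |i - j| for Delta-E."""
    if m.kind != "gray":
        raise TextureError(f"expected a gray co-occurrence matrix, got kind={m.kind!r}")
    n = m.n
    i = np.arange(n, dtype=float)[:, None]
    dtable = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
    h, mean, var, rho, ent = _five_stats(m.P, i, dtable, denominator)
    return TextureFeatureVector(
        homogeneity=h, mean_color=np.array([float(mean[0]), 0.0, 0.0]),
        variance=var, correlation=rho, entropy=ent,
    )


def ccm_features(m: CooccurrenceMatrix, denominator: str = "sigma_product") -> TextureFeatureVector:
    """Five Delta-E-weighted statistics of a CCM."""
    if m.kind != "color":
        raise TextureError(f"expected a color co-occurrence matrix, got kind={m.kind!r}")
    if m.palette is None:
        raise TextureError("color co-occurrence matrix has no palette attached")
    coords = m.palette.colors
    dtable = m.palette.distance_table()
    h, mean, var, rho, ent = _five_stats(m.P, coords, dtable, denominator)
    return TextureFeatureVector(
        homogeneity=h, mean_color=np.asarray(mean, dtype=float),
        variance=var, correlation=rho, entropy=ent,
    )


def image_features(
    image: np.ndarray,
    palette: Palette,
    mode: Literal["ccm", "glcm_L"] = "ccm",
    spec: OffsetSpec | None = None,
    levels: int = 32,
    denominator: str = "sigma_product",
) -> dict:
    """End-to-end texture descriptor of an sRGB image.

    Statistics are computed per direction (each direction's matrix is
    accumulated symmetrically) and averaged into one flat record of the
    seven scalars in :data:`FEATURE_NAMES`.
    """
    spec = spec or OffsetSpec()
    if mode == "ccm":
        q = quantize(image, palette)

        def one(off):
            return ccm_features(
                compute_ccm(q, OffsetSpec((off,), spec.symmetric)), denominator
            )
    elif mode == "glcm_L":
        L = cs.xyz_to_lab(cs.srgb_to_xyz(image))[..., 0]

        def one(off):
            return glcm_features(
                compute_glcm(L, levels, (0.0, 100.0), OffsetSpec((off,), spec.symmetric)),
                denominator,
            )
    else:
        raise TextureError(f"unknown mode {mode!r}; expected 'ccm' or 'glcm_L'")
    recs = [one(off).as_record() for off in spec.offsets]
    return {k: float(np.mean([r[k] for r in recs])) for k in FEATURE_NAMES}
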