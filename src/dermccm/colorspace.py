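"""Uniform color spaces and perceptual color differences.

Forward transforms sRGB -> XYZ -> {CIELAB, CIECAM16 -> CAM16-UCS} and the
two Euclidean color-difference metrics used throughout the toolkit:
Delta E*ab in CIELAB and Delta E' in CAM16-UCS.

All transforms are vectorized: every function accepts arrays of shape
``(..., 3)`` (an image is just ``(H, W, 3)``) and scalars fall out as the
``(3,)`` case.  XYZ is kept on the 0-100 scale (Y of the adopted white =
100), matching the CIE worked examples.

The CIECAM16 appearance model follows the CIE 248:2022 / Li et al.
formulation: a sharpened cone transform (the M16 matrix), a von Kries
chromatic adaptation with degree-of-adaptation D, a Michaelis-Menten-type
compressive nonlinearity, and the correlates J (lightness), C (chroma),
h (hue angle), H (hue composition), M (colorfulness), s (saturation) and
Q (brightness).  CAM16-UCS then compresses J and M into J' and M' so that
Euclidean distance over (J', a', b') approximates perceived difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "D65_WHITE",
    "ViewingConditions",
    "CAM16Appearance",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "delta_e_lab",
    "cam16_forward",
    "cam16_to_ucs",
    "ucs_to_srgb",
    "delta_e_ucs",
    "srgb_to_working",
    "working_to_srgb",
]

# D65 white point, 2-degree observer, Y = 100.
D65_WHITE = np.array([95.047, 100.0, 108.883])

# sRGB linear RGB -> XYZ, derived from the IEC 61966-2-1 primary
# chromaticities and balanced so that (1,1,1) maps exactly to D65_WHITE.
def _srgb_matrix() -> np.ndarray:
    xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    prim = np.stack(
        [xy[:, 0] / xy[:, 1], np.ones(3), (1 - xy.sum(axis=1)) / xy[:, 1]], axis=0
    )
    scale = np.linalg.solve(prim, D65_WHITE / 100.0)
    return prim * scale


_RGB2XYZ = _srgb_matrix()
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)

# CAM16 sharpened cone responses.
_M16 = np.array(
    [
        [0.401288, 0.650173, -0.051461],
        [-0.250268, 1.204414, 0.045854],
        [-0.002079, 0.048952, 0.953127],
    ]
)
_M16_INV = np.linalg.inv(_M16)

_SURROUNDS = {
    "average": (1.0, 0.69, 1.0),  # F, c, N_c
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}

# Unique-hue data for hue composition H.
_HUE_H = np.array([20.14, 90.00, 164.25, 237.53, 380.14])
_HUE_E = np.array([0.8, 0.7, 1.0, 1.2, 0.8])
_HUE_Q = np.array([0.0, 100.0, 200.0, 300.0, 400.0])


class InputDomainError(ValueError):
    """Raised when a color lies outside the function's input domain."""


@dataclass(frozen=True, eq=False)
class ViewingConditions:
    """CIECAM16 viewing-condition parameters.

    Parameters
    ----------
    white : array-like
        Adopted white point in XYZ (0-100 scale).
    L_A : float
        Adapting field luminance in cd/m^2.
    Y_b : float
        Relative luminance of the background, in (0, 100].
    surround : {"average", "dim", "dark"}
    discount_illuminant : bool
        If True (default) the degree of adaptation D is fixed at 1, i.e.
        the observer fully discounts the illuminant; otherwise D follows
        the model's exponential formula of L_A (clamped to [0, 1]).
    """

    white: np.ndarray = field(default_factory=lambda: D65_WHITE.copy())
    L_A: float = 64.0
    Y_b: float = 20.0
    surround: Literal["average", "dim", "dark"] = "average"
    discount_illuminant: bool = True

    def __post_init__(self):
        object.__setattr__(self, "white", np.asarray(self.white, dtype=float))
        if self.L_A <= 0:
            raise ValueError(f"adapting luminance L_A must be positive, got {self.L_A}")
        if not (0 < self.Y_b <= 100):
            raise ValueError(f"background luminance Y_b must lie in (0, 100], got {self.Y_b}")
        if self.surround not in _SURROUNDS:
            raise ValueError(f"unknown surround {self.surround!r}")

    # Derived constants, computed lazily and cached on first use.
    def _derived(self):
        if not hasattr(self, "_cache"):
            F, c, N_c = _SURROUNDS[self.surround]
            Y_w = float(self.white[1])
            k = 1.0 / (5.0 * self.L_A + 1.0)
            F_L = 0.2 * k**4 * 5.0 * self.L_A + 0.1 * (1 - k**4) ** 2 * (5.0 * self.L_A) ** (1 / 3)
            n = self.Y_b / Y_w
            z = 1.48 + np.sqrt(n)
            N_bb = 0.725 * (1.0 / n) ** 0.2
            N_cb = N_bb
            if self.discount_illuminant:
                D = 1.0
            else:
                D = F * (1.0 - (1.0 / 3.6) * np.exp((-self.L_A - 42.0) / 92.0))
                D = float(np.clip(D, 0.0, 1.0))
            rgb_w = _M16 @ self.white
            D_rgb = D * Y_w / rgb_w + 1.0 - D
            rgb_wc = D_rgb * rgb_w
            rgb_aw = _adapt_compress(rgb_wc, F_L)
            A_w = (np.array([2.0, 1.0, 0.05]) @ rgb_aw - 0.305) * N_bb
            object.__setattr__(
                self,
                "_cache",
                dict(F=F, c=c, N_c=N_c, F_L=F_L, n=n, z=z, N_bb=N_bb, N_cb=N_cb,
                     D_rgb=D_rgb, A_w=A_w),
            )
        return self._cache


@dataclass(frozen=True, eq=False)
class CAM16Appearance:
    """The seven CIECAM16 appearance correlates (arrays broadcast together)."""

    J: np.ndarray  # lightness, 0-100
    C: np.ndarray  # chroma
    H: np.ndarray  # hue composition, 0-400
    h: np.ndarray  # hue angle, degrees in [0, 360)
    M: np.ndarray  # colorfulness
    s: np.ndarray  # saturation
    Q: np.ndarray  # brightness


def _adapt_compress(rgb: np.ndarray, F_L: float) -> np.ndarray:
    """Post-adaptation compressive nonlinearity (sign-symmetric)."""
    x = F_L * np.abs(rgb) / 100.0
    t = x**0.42
    return np.sign(rgb) * 400.0 * t / (t + 27.13) + 0.1


def _uncompress(rgb_a: np.ndarray, F_L: float) -> np.ndarray:
    x = rgb_a - 0.1
    t = np.abs(x)
    # invert 400 t' / (t' + 27.13); clip keeps the inverse finite at t -> 400
    core = 27.13 * t / np.maximum(400.0 - t, 1e-12)
    return np.sign(x) * (100.0 / F_L) * core ** (1.0 / 0.42)


def srgb_to_xyz(rgb) -> np.ndarray:
    """sRGB (unit-interval, gamma-encoded) to XYZ (D65, 0-100 scale).

    Applies the IEC 61966-2-1 piecewise decode before the linear matrix.
    Raises :class:`InputDomainError` for channels outside [0, 1].
    """
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < -1e-12) or np.any(rgb > 1 + 1e-12):
        raise InputDomainError("sRGB channels must lie in [0, 1]")
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((np.clip(rgb, 0.04045, None) + 0.055) / 1.055) ** 2.4)
    return 100.0 * lin @ _RGB2XYZ.T


def xyz_to_srgb(xyz) -> np.ndarray:
    """Inverse of :func:`srgb_to_xyz`; out-of-gamut values are clipped."""
    lin = (np.asarray(xyz, dtype=float) / 100.0) @ _XYZ2RGB.T
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)


def xyz_to_lab(xyz, white=None) -> np.ndarray:
    """XYZ to CIELAB (L*, a*, b*) relative to `white` (default D65)."""
    xyz = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise InputDomainError("non-finite XYZ input")
    white = D65_WHITE if white is None else np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise InputDomainError("white point must have positive components")
    t = xyz / white
    eps = 216.0 / 24389.0
    kappa = 24389.0 / 27.0
    f = np.where(t > eps, np.cbrt(np.clip(t, eps, None)), (kappa * t + 16.0) / 116.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def lab_to_xyz(lab, white=None) -> np.ndarray:
    """Inverse CIELAB transform (rendering helper)."""
    lab = np.asarray(lab, dtype=float)
    white = D65_WHITE if white is None else np.asarray(white, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    eps = 216.0 / 24389.0
    kappa = 24389.0 / 27.0
    f = np.stack([fx, fy, fz], axis=-1)
    t = np.where(f**3 > eps, f**3, (116.0 * f - 16.0) / kappa)
    return t * white


def delta_e_lab(lab1, lab2) -> np.ndarray:
    """CIE 1976 color difference: Euclidean distance in (L*, a*, b*)."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def cam16_forward(xyz, vc: ViewingConditions | None = None) -> CAM16Appearance:
    """CIECAM16 forward model: XYZ stimulus -> appearance correlates."""
    vc = vc or ViewingConditions()
    p = vc._derived()
    xyz = np.asarray(xyz, dtype=float)
    rgb = xyz @ _M16.T
    rgb_c = p["D_rgb"] * rgb
    rgb_a = _adapt_compress(rgb_c, p["F_L"])
    Ra, Ga, Ba = rgb_a[..., 0], rgb_a[..., 1], rgb_a[..., 2]
    a = Ra - 12.0 * Ga / 11.0 + Ba / 11.0
    b = (Ra + Ga - 2.0 * Ba) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0
    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    A = (2.0 * Ra + Ga + 0.05 * Ba - 0.305) * p["N_bb"]
    J = 100.0 * np.clip(A / p["A_w"], 0.0, None) ** (p["c"] * p["z"])
    Q = (4.0 / p["c"]) * np.sqrt(J / 100.0) * (p["A_w"] + 4.0) * p["F_L"] ** 0.25
    denom = Ra + Ga + (21.0 / 20.0) * Ba
    t = (50000.0 / 13.0) * p["N_c"] * p["N_cb"] * e_t * np.sqrt(a * a + b * b) / np.where(
        np.abs(denom) < 1e-12, 1e-12, denom
    )
    # achromatic snap: rounding noise in the opponent signals leaves t at
    # ~1e-12 for exactly neutral stimuli; without the snap s = 100*sqrt(M/Q)
    # would amplify it to ~1e-5
    t = np.where(np.abs(t) < 1e-8, 0.0, t)
    C = np.clip(t, 0.0, None) ** 0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29 ** p["n"]) ** 0.73
    M = C * p["F_L"] ** 0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        s = 100.0 * np.sqrt(np.where(Q > 0, M / np.where(Q > 0, Q, 1.0), 0.0))
    H = _hue_composition(h)
    return CAM16Appearance(J=J, C=C, H=H, h=h, M=M, s=s, Q=Q)


def _hue_composition(h: np.ndarray) -> np.ndarray:
    hp = np.where(h < _HUE_H[0], h + 360.0, h)
    i = np.clip(np.searchsorted(_HUE_H, hp, side="right") - 1, 0, 3)
    hi, hi1 = _HUE_H[i], _HUE_H[i + 1]
    ei, ei1 = _HUE_E[i], _HUE_E[i + 1]
    num = (hp - hi) / ei
    return _HUE_Q[i] + 100.0 * num / (num + (hi1 - hp) / ei1)


def cam16_to_ucs(app: CAM16Appearance) -> np.ndarray:
    """CAM16 correlates -> CAM16-UCS (J', a', b') coordinates.

    J' = 1.7 J / (1 + 0.007 J);  M' = ln(1 + 0.0228 M) / 0.0228;
    a' = M' cos h,  b' = M' sin h.
    """
    Jp = 1.7 * app.J / (1.0 + 0.007 * app.J)
    Mp = np.log1p(0.0228 * app.M) / 0.0228
    hr = np.radians(app.h)
    return np.stack([Jp, Mp * np.cos(hr), Mp * np.sin(hr)], axis=-1)


def delta_e_ucs(u1, u2) -> np.ndarray:
    """CAM16-UCS color difference: Euclidean distance in (J', a', b')."""
    d = np.asarray(u1, dtype=float) - np.asarray(u2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def ucs_to_xyz(ucs, vc: ViewingConditions | None = None) -> np.ndarray:
    """Inverse CAM16-UCS -> XYZ (rendering helper for palette display)."""
    vc = vc or ViewingConditions()
    p = vc._derived()
    ucs = np.asarray(ucs, dtype=float)
    Jp, ap, bp = ucs[..., 0], ucs[..., 1], ucs[..., 2]
    J = np.clip(Jp, 0.0, None) / (1.7 - 0.007 * np.clip(Jp, 0.0, None))
    Mp = np.sqrt(ap * ap + bp * bp)
    M = np.expm1(0.0228 * Mp) / 0.0228
    h = np.arctan2(bp, ap) % (2 * np.pi)
    C = M / p["F_L"] ** 0.25
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(
            J > 0,
            (C / np.where(J > 0, np.sqrt(J / 100.0), 1.0) / (1.64 - 0.29 ** p["n"]) ** 0.73)
            ** (1.0 / 0.9),
            0.0,
        )
    e_t = 0.25 * (np.cos(h + 2.0) + 3.8)
    A = p["A_w"] * (J / 100.0) ** (1.0 / (p["c"] * p["z"]))
    p2 = A / p["N_bb"] + 0.305
    # solve for the opponent signals a, b given t and the achromatic signal
    p1 = np.where(t > 1e-12, (50000.0 / 13.0) * p["N_c"] * p["N_cb"] * e_t / np.where(t > 1e-12, t, 1.0), np.inf)
    sin_h, cos_h = np.sin(h), np.cos(h)
    big = np.abs(sin_h) >= np.abs(cos_h)
    a = np.zeros_like(p2)
    b = np.zeros_like(p2)
    # |sin| branch
    with np.errstate(divide="ignore", invalid="ignore"):
        p4 = p1 / np.where(sin_h == 0, 1.0, sin_h)
        b1 = (
            p2 * (2.0 + 21.0 / 20.0) * (460.0 / 1403.0)
            / (p4 + (2.0 + 21.0 / 20.0) * (220.0 / 1403.0) * (cos_h / np.where(sin_h == 0, 1.0, sin_h))
               - 27.0 / 1403.0 + (21.0 / 20.0) * (6300.0 / 1403.0))
        )
        a1 = b1 * (cos_h / np.where(sin_h == 0, 1.0, sin_h))
        p5 = p1 / np.where(cos_h == 0, 1.0, cos_h)
        a2 = (
            p2 * (2.0 + 21.0 / 20.0) * (460.0 / 1403.0)
            / (p5 + (2.0 + 21.0 / 20.0) * (220.0 / 1403.0)
               - (27.0 / 1403.0 - (21.0 / 20.0) * (6300.0 / 1403.0)) * (sin_h / np.where(cos_h == 0, 1.0, cos_h)))
        )
        b2 = a2 * (sin_h / np.where(cos_h == 0, 1.0, cos_h))
    chromatic = t > 1e-12
    a = np.where(chromatic, np.where(big, a1, a2), 0.0)
    b = np.where(chromatic, np.where(big, b1, b2), 0.0)
    Ra = (460.0 * p2 + 451.0 * a + 288.0 * b) / 1403.0
    Ga = (460.0 * p2 - 891.0 * a - 261.0 * b) / 1403.0
    Ba = (460.0 * p2 - 220.0 * a - 6300.0 * b) / 1403.0
    rgb_c = _uncompress(np.stack([Ra, Ga, Ba], axis=-1), p["F_L"])
    rgb = rgb_c / p["D_rgb"]
    return rgb @ _M16_INV.T


def ucs_to_srgb(ucs, vc: ViewingConditions | None = None) -> np.ndarray:
    return xyz_to_srgb(ucs_to_xyz(ucs, vc))


def srgb_to_working(rgb, space: str, vc: ViewingConditions | None = None) -> np.ndarray:
    """Map sRGB to the chosen working space: ``lab`` -> (L*, a*, b*),
    ``cam16ucs`` -> (J', a', b')."""
    xyz = srgb_to_xyz(rgb)
    if space == "lab":
        return xyz_to_lab(xyz)
    if space == "cam16ucs":
        return cam16_to_ucs(cam16_forward(xyz, vc))
    raise ValueError(f"unknown working space {space!r}; expected 'lab' or 'cam16ucs'")


def working_to_srgb(coords, space: str, vc: ViewingConditions | None = None) -> np.ndarray:
    """Inverse of :func:`srgb_to_working` (display rendering only)."""
    if space == "lab":
        return xyz_to_srgb(lab_to_xyz(coords))
    if space == "cam16ucs":
        return ucs_to_srgb(coords, vc)
    raise ValueError(f"unknown working space {space!r}; expected 'lab' or 'cam16ucs'")


def delta_e(c1, c2, space: str) -> np.ndarray:
    """Working-space color difference (Euclidean in either uniform space)."""
    if space not in ("lab", "cam16ucs"):
        raise ValueError(f"unknown working space {space!r}")
    d = np.asarray(c1, dtype=float) - np.asarray(c2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))
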