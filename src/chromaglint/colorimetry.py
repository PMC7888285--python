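"""CIE LCH / Lab / XYZ / sRGB conversions, gamut boundaries, and saturation.

All display colors in this package live in the 8-bit-style companded sRGB
encoding; perceptual coordinates live in CIE 1976 L*a*b* and its cylindrical
form LCH (L* lightness, C*ab chroma, hab hue angle in degrees).  Saturation is
the chroma-to-lightness ratio C*/L*.

Two reference-white conventions are supported for the Lab <-> XYZ leg:

``"d65"`` (default)
    Lab is referenced directly to the sRGB display white (D65, 2° observer).
    This convention reproduces the published stimulus triplets, e.g.
    LCH (60, 60, 39.999°) -> sRGB (0.91, 0.42, 0.31) at two decimals.
``"d50-bradford"``
    Lab referenced to D50 with a Bradford chromatic adaptation to D65 before
    entering the sRGB matrix, the default behaviour of some colorimetry
    libraries.

Conversions never clip silently: an out-of-gamut result raises
:class:`GamutError` carrying the raw channel values, unless the opt-in clip
mode is requested (which records the clipping magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "LCHColor",
    "RGBColor",
    "GamutBoundary",
    "GamutError",
    "lch_to_srgb",
    "srgb_to_lch",
    "in_gamut",
    "max_chroma",
    "gamut_boundary",
    "saturation",
]

WhitePoint = Literal["d65", "d50-bradford"]

#: CIE XYZ of the reference whites (2° observer), Y normalised to 1.
WHITE_D65 = np.array([0.95047, 1.0, 1.08883])
WHITE_D50 = np.array([0.96422, 1.0, 0.82521])

# Linear sRGB <-> XYZ matrices derived at full precision from the IEC
# 61966-2-1 primaries and the D65 white, so that rgb (1, 1, 1) maps exactly
# onto the reference white (equal channels are exactly achromatic in Lab).
_PRIMARIES_xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])


def _rgb_to_xyz_matrix(primaries_xy: np.ndarray, white: np.ndarray) -> np.ndarray:
    xyz = np.array(
        [[x / y, 1.0, (1.0 - x - y) / y] for x, y in primaries_xy]
    ).T
    scale = np.linalg.solve(xyz, white)
    return xyz * scale


_RGB_TO_XYZ = _rgb_to_xyz_matrix(_PRIMARIES_xy, WHITE_D65)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

# Bradford cone-response matrix, used for the D50 -> D65 adaptation.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)


def _bradford_adaptation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    cs = _BRADFORD @ src
    cd = _BRADFORD @ dst
    return np.linalg.inv(_BRADFORD) @ np.diag(cd / cs) @ _BRADFORD


_ADAPT_D50_D65 = _bradford_adaptation(WHITE_D50, WHITE_D65)

#: Chroma below this is treated as achromatic (hue undefined -> reported as 0).
ACHROMATIC_TOL = 1e-9

#: Channel slack when testing gamut membership, to absorb float round-off.
GAMUT_EPS = 1e-9


class GamutError(ValueError):
    """A conversion produced sRGB channels outside [0, 1].

    Attributes
    ----------
    channels : tuple of float
        The raw, unclipped companded channel values.
    """

    def __init__(self, message: str, channels: tuple[float, float, float]):
        super().__init__(message)
        self.channels = channels


@dataclass(frozen=True)
class LCHColor:
    """A CIE LCH coordinate: L* in [0, 100], C* >= 0, hue in [0, 360) degrees."""

    L: float
    C: float
    H: float

    def __post_init__(self):
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")
        if self.C < 0.0:
            raise ValueError(f"C* must be >= 0, got {self.C}")
        object.__setattr__(self, "H", float(self.H) % 360.0)

    @property
    def is_achromatic(self) -> bool:
        return self.C < ACHROMATIC_TOL

    @property
    def saturation(self) -> float:
        return saturation(self.C, self.L)


@dataclass(frozen=True)
class RGBColor:
    """A companded (display-referred) sRGB triplet with channels in [0, 1].

    ``clip_delta`` records the largest absolute channel excursion removed by
    the opt-in clip mode (0 when no clipping occurred).
    """

    r: float
    g: float
    b: float
    space: str = "sRGB"
    clip_delta: float = field(default=0.0, compare=False)

    def __iter__(self):
        return iter((self.r, self.g, self.b))

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b])


# ---------------------------------------------------------------------------
# Vectorised conversion primitives (arrays in, arrays out, no validation).
# ---------------------------------------------------------------------------

def _lab_to_xyz(L, a, b, white: np.ndarray) -> np.ndarray:
    L, a, b = np.broadcast_arrays(*np.atleast_1d(L, a, b))
    fy = (np.asarray(L, float) + 16.0) / 116.0
    fx = fy + np.asarray(a, float) / 500.0
    fz = fy - np.asarray(b, float) / 200.0
    delta = 6.0 / 29.0

    def finv(t):
        return np.where(t > delta, t**3, 3.0 * delta**2 * (t - 4.0 / 29.0))

    return np.stack([finv(fx), finv(fy), finv(fz)], axis=-1) * white


def _xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    t = np.asarray(xyz, float) / white
    delta = 6.0 / 29.0

    def f(u):
        return np.where(u > delta**3, np.cbrt(u), u / (3.0 * delta**2) + 4.0 / 29.0)

    fx, fy, fz = f(t[..., 0]), f(t[..., 1]), f(t[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def srgb_compand(c: np.ndarray) -> np.ndarray:
    """Linear -> companded sRGB transfer function (sign-preserving)."""
    c = np.asarray(c, float)
    a = np.abs(c)
    out = np.where(a <= 0.0031308, 12.92 * a, 1.055 * a ** (1.0 / 2.4) - 0.055)
    return np.sign(c) * out


def srgb_decompand(c: np.ndarray) -> np.ndarray:
    """Companded -> linear sRGB transfer function (sign-preserving)."""
    c = np.asarray(c, float)
    a = np.abs(c)
    out = np.where(a <= 0.04045, a / 12.92, ((a + 0.055) / 1.055) ** 2.4)
    return np.sign(c) * out


def lch_to_rgb_array(L, C, H, white_point: WhitePoint = "d65") -> np.ndarray:
    """Raw companded sRGB channels for LCH arrays; may fall outside [0, 1].

    This is the unguarded workhorse behind :func:`lch_to_srgb`,
    :func:`in_gamut` and the gamut scans.
    """
    L, C, H = np.broadcast_arrays(*np.atleast_1d(L, C, H))
    h = np.radians(np.asarray(H, float))
    a = np.asarray(C, float) * np.cos(h)
    b = np.asarray(C, float) * np.sin(h)
    if white_point == "d65":
        xyz = _lab_to_xyz(L, a, b, WHITE_D65)
    elif white_point == "d50-bradford":
        xyz = _lab_to_xyz(L, a, b, WHITE_D50) @ _ADAPT_D50_D65.T
    else:
        raise ValueError(f"unknown white-point convention: {white_point!r}")
    linear = xyz @ _XYZ_TO_RGB.T
    return srgb_compand(linear)


def rgb_to_lch_array(rgb, white_point: WhitePoint = "d65") -> np.ndarray:
    """Inverse of :func:`lch_to_rgb_array`; returns stacked (L, C, H) arrays."""
    rgb = np.atleast_2d(np.asarray(rgb, float))
    xyz = srgb_decompand(rgb) @ _RGB_TO_XYZ.T
    if white_point == "d65":
        lab = _xyz_to_lab(xyz, WHITE_D65)
    elif white_point == "d50-bradford":
        lab = _xyz_to_lab(xyz @ np.linalg.inv(_ADAPT_D50_D65).T, WHITE_D50)
    else:
        raise ValueError(f"unknown white-point convention: {white_point!r}")
    L = lab[..., 0]
    C = np.hypot(lab[..., 1], lab[..., 2])
    H = np.degrees(np.arctan2(lab[..., 2], lab[..., 1])) % 360.0
    H = np.where(C < ACHROMATIC_TOL, 0.0, H)
    return np.stack([L, C, H], axis=-1)


def in_gamut(L, C, H, white_point: WhitePoint = "d65", eps: float = GAMUT_EPS):
    """Elementwise test that (L*, C*, h) maps inside the sRGB unit cube."""
    rgb = lch_to_rgb_array(L, C, H, white_point)
    ok = np.all((rgb >= -eps) & (rgb <= 1.0 + eps), axis=-1)
    return bool(ok) if ok.shape == (1,) else ok


# ---------------------------------------------------------------------------
# Scalar, validated API.
# ---------------------------------------------------------------------------

def lch_to_srgb(
    color: LCHColor,
    white_point: WhitePoint = "d65",
    mode: Literal["error", "clip"] = "error",
) -> RGBColor:
    """Convert an LCH coordinate to companded sRGB.

    The chain is LCH -> Lab -> XYZ -> linear RGB -> companded RGB under the
    requested white-point convention.  Out-of-gamut results raise
    :class:`GamutError` (default) or, in ``mode="clip"``, are clipped with the
    excursion recorded on ``RGBColor.clip_delta``.
    """
    raw = lch_to_rgb_array(color.L, color.C, color.H, white_point)[0]
    lo, hi = raw.min(), raw.max()
    if lo < -GAMUT_EPS or hi > 1.0 + GAMUT_EPS:
        if mode == "error":
            raise GamutError(
                f"LCH ({color.L}, {color.C}, {color.H}) maps outside sRGB: "
                f"raw channels {tuple(np.round(raw, 6))}",
                tuple(raw),
            )
        clipped = np.clip(raw, 0.0, 1.0)
        delta = float(np.max(np.abs(raw - clipped)))
        return RGBColor(*map(float, clipped), clip_delta=delta)
    clipped = np.clip(raw, 0.0, 1.0)  # remove sub-eps float dust only
    return RGBColor(*map(float, clipped))


def srgb_to_lch(color: RGBColor, white_point: WhitePoint = "d65") -> LCHColor:
    """Exact functional inverse of :func:`lch_to_srgb` (up to float tolerance).

    Achromatic inputs (C* ~ 0) report hue 0 by convention; check
    ``LCHColor.is_achromatic``.
    """
    for name, v in (("r", color.r), ("g", color.g), ("b", color.b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"channel {name}={v} outside [0, 1]")
    L, C, H = rgb_to_lch_array([color.r, color.g, color.b], white_point)[0]
    return LCHColor(float(np.clip(L, 0.0, 100.0)), float(C), float(H))


def saturation(C, L):
    """Saturation as the chroma-to-lightness ratio C*/L*.

    Vectorised; L* = 0 yields NaN (undefined) rather than raising.
    """
    C = np.asarray(C, float)
    L = np.asarray(L, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(L > 0.0, C / np.where(L > 0.0, L, 1.0), np.nan)
    if s.shape == ():
        return float(s)
    return s


# ---------------------------------------------------------------------------
# Gamut boundary scans.
# ---------------------------------------------------------------------------

#: Upper bound of the chroma scan; no sRGB color exceeds C*ab ~ 134.
_CHROMA_SCAN_MAX = 200.0


def max_chroma(
    L: float,
    H: float,
    step: float = 0.25,
    white_point: WhitePoint = "d65",
    refine_iters: int = 20,
) -> float:
    """Largest displayable chroma at (L*, h), resolved to within ``step``.

    A coarse upward scan at ``step`` resolution locates the boundary bracket,
    which bisection then refines well below a just-noticeable chroma
    difference.  Returns 0 when even C* = step is out of gamut.
    """
    if not 0.0 <= L <= 100.0:
        raise ValueError(f"L* must lie in [0, 100], got {L}")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(0.0, _CHROMA_SCAN_MAX + step, step)
    mask = in_gamut(L, grid, H, white_point)
    mask = np.atleast_1d(mask)
    if not mask[0]:  # L* itself not representable (never true for sRGB whites)
        return 0.0
    out_idx = np.argmin(mask) if not mask.all() else None
    if out_idx is None or out_idx == 0:
        return float(grid[-1])
    lo = float(grid[out_idx - 1])
    hi = float(grid[out_idx])
    for _ in range(refine_iters):
        mid = 0.5 * (lo + hi)
        if in_gamut(L, mid, H, white_point):
            lo = mid
        else:
            hi = mid
    return lo


@dataclass(frozen=True)
class GamutBoundary:
    """Per-lightness maximum chroma and saturation for one hue angle.

    ``table`` holds 101 rows for L* = 0..100 at unit steps with columns
    ``L``, ``maxC``, ``maxS``; maxS = maxC/L* with NaN at L* = 0.
    """

    hue: float
    table: pd.DataFrame
    white_point: str = "d65"

    def __post_init__(self):
        if len(self.table) != 101:
            raise ValueError("gamut boundary must have 101 rows (L* = 0..100)")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "hue", self.hue)
        out.to_csv(path, index=False)


def gamut_boundary(
    H: float, step: float = 0.25, white_point: WhitePoint = "d65"
) -> GamutBoundary:
    """Scan the sRGB gamut boundary over L* = 0..100 at a fixed hue angle."""
    Ls = np.arange(101, dtype=float)
    maxC = np.array([max_chroma(L, H, step, white_point) for L in Ls])
    maxS = saturation(maxC, Ls)
    table = pd.DataFrame({"L": Ls, "maxC": maxC, "maxS": maxS})
    return GamutBoundary(hue=float(H) % 360.0, table=table, white_point=white_point)
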