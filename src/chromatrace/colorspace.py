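"""Pixel-level color representations, conversions, and derived scalar metrics.

All conversions assume sRGB primaries with a D65 white point and the 2-degree
standard observer — the dominant convention for consumer cameras.  Channel
inputs are 8-bit-scaled intensities in ``[0, 255]`` (integer or real); all
internal arithmetic is floating point, and rounding to integers happens only
at presentation time.

The scalar metrics are the workhorses of color-based reaction monitoring:

* ``delta_e_1976`` — the CIE 1976 color difference, i.e. the Euclidean
  distance between two colors in L*a*b* space.  Computed per video frame
  against a reference frame it yields a hue-agnostic "magnitude of color
  change" trace.
* ``rgb_sum_response`` — ``765 - (R + G + B)``, a brightness-loss scalar
  useful when a colored species fades toward colorless/white.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rgb_to_hsv",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e_1976",
    "rgb_sum_response",
]

# sRGB -> XYZ (linear RGB in [0,1], D65), IEC 61966-2-1 matrix.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# Reference white = image of (1,1,1): guarantees sRGB white maps exactly to
# L*=100, a*=b*=0 regardless of matrix rounding.
_WHITE_XYZ = _SRGB_TO_XYZ @ np.ones(3) * 100.0


def _as_rgb(c) -> np.ndarray:
    """Validate and return an RGB array of shape (..., 3), dtype float."""
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3 channels, got shape {arr.shape}")
    if np.any(arr < 0.0) or np.any(arr > 255.0):
        raise ValueError("RGB channel values must lie in [0, 255]")
    return arr


def rgb_to_hsv(c) -> np.ndarray:
    """Convert RGB in [0,255] to HSV with h in degrees [0,360), s and v in [0,255].

    Standard hexcone conversion: ``v = max``, ``s = 255*(max-min)/max``
    (``s = 0`` when ``max = 0``), hue by the sector formula.  Achromatic
    inputs (``r = g = b``) have hue 0 by convention.  Accepts a single
    triple or an array of shape (..., 3); returns the same shape, unrounded.
    """
    rgb = _as_rgb(c)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.maximum.reduce([r, g, b])
    mn = np.minimum.reduce([r, g, b])
    delta = mx - mn

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(mx > 0, 255.0 * delta / mx, 0.0)
        # sector formula; r takes priority on max ties, then g, then b
        h_r = 60.0 * np.mod((g - b) / delta, 6.0)
        h_g = 60.0 * ((b - r) / delta + 2.0)
        h_b = 60.0 * ((r - g) / delta + 4.0)
    h = np.where(mx == r, h_r, np.where(mx == g, h_g, h_b))
    h = np.where(delta == 0, 0.0, h)
    h = np.mod(h, 360.0)
    return np.stack([h, s, mx], axis=-1)


def _inverse_compand(u: np.ndarray) -> np.ndarray:
    # IEC 61966-2-1 piecewise sRGB gamma, u in [0,1] -> linear light
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def rgb_to_xyz(c) -> np.ndarray:
    """Convert sRGB in [0,255] to CIE XYZ (D65), Y normalized so white has Y=100."""
    rgb = _as_rgb(c) / 255.0
    linear = _inverse_compand(rgb)
    return 100.0 * linear @ _SRGB_TO_XYZ.T


def xyz_to_lab(c) -> np.ndarray:
    """Convert CIE XYZ (D65, Y_white = 100) to CIE 1976 L*a*b*."""
    xyz = np.asarray(c, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"expected 3 components, got shape {xyz.shape}")
    t = xyz / _WHITE_XYZ
    eps = (6.0 / 29.0) ** 3
    f = np.where(t > eps, np.cbrt(t), t / (3.0 * (6.0 / 29.0) ** 2) + 4.0 / 29.0)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(c) -> np.ndarray:
    """sRGB in [0,255] -> CIE L*a*b* (D65), composing ``rgb_to_xyz`` and ``xyz_to_lab``."""
    return xyz_to_lab(rgb_to_xyz(c))


def lab_to_rgb(c, clip: bool = True) -> np.ndarray:
    """CIE L*a*b* (D65) -> sRGB in [0,255]; the inverse of :func:`rgb_to_lab`.

    Out-of-gamut results are clipped to [0, 255] unless ``clip`` is False.
    Used mainly to synthesize color programs that are linear in Lab.
    """
    lab = np.asarray(c, dtype=float)
    if lab.shape[-1] != 3:
        raise ValueError(f"expected 3 components, got shape {lab.shape}")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    delta = 6.0 / 29.0
    t = np.where(f > delta, f**3, 3.0 * delta**2 * (f - 4.0 / 29.0))
    xyz = t * _WHITE_XYZ
    linear = (xyz / 100.0) @ np.linalg.inv(_SRGB_TO_XYZ).T
    linear_c = np.clip(linear, 0.0, None)
    srgb = np.where(
        linear_c <= 0.0031308,
        12.92 * linear_c,
        1.055 * linear_c ** (1.0 / 2.4) - 0.055,
    )
    srgb = np.where(linear < 0, 0.0, srgb) * 255.0
    return np.clip(srgb, 0.0, 255.0) if clip else srgb


def delta_e_1976(c1, c2) -> np.ndarray:
    """CIE 1976 color difference: Euclidean distance between two Lab triples.

    ``sqrt((L2-L1)^2 + (a2-a1)^2 + (b2-b1)^2)``.  Symmetric, non-negative,
    zero iff the triples are identical.  Broadcasts over leading axes.
    """
    a1 = np.asarray(c1, dtype=float)
    a2 = np.asarray(c2, dtype=float)
    return np.sqrt(np.sum((a2 - a1) ** 2, axis=-1))


def rgb_sum_response(c) -> np.ndarray:
    """Brightness-loss scalar ``765 - (R + G + B)``; 0 for white, 765 for black."""
    rgb = _as_rgb(c)
    return 765.0 - rgb.sum(axis=-1)
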