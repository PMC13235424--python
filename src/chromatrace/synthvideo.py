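"""Seedable synthetic frame-sequence generators with known ground truth.

Three generators emulate the study conditions the analysis pipeline assumes,
so every stage is testable without recorded footage:

* :func:`gen_reaction` — a single vessel undergoing a homogeneous color
  transition between two endpoint colors, following first-order
  ``f(t) = 1 - exp(-k t)`` or second-order ``f(t) = k t / (1 + k t)``
  progress, with i.i.d. Gaussian per-channel camera noise clipped to
  [0, 255].
* :func:`gen_mixing` — a dye blob homogenizing in a stirred vessel: a scalar
  concentration field advected by a differential vortex (angular velocity
  decaying with radius, so the blob is sheared into a filament) and relaxed
  by 5-point-stencil diffusion, rendered as a linear blend between solvent
  and dye colors.  Operator splitting: advect, then diffuse.  With zero
  swirl, the diffusion step conserves total concentration exactly
  (reflecting boundaries) and contracts the spatial variance every step.
* :func:`gen_plate` — a multi-well plate where each circular well runs its
  own color program with a per-well rate constant, for parallel kinetic
  screening tests.

All generators are bit-reproducible given their spec (the seed is an
explicit field, never global state) and return the ground truth alongside
the frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from . import colorspace
from .regions import Frame, ROISet, plate_layout

__all__ = [
    "ReactionSpec",
    "MixingSpec",
    "PlateSpec",
    "gen_reaction",
    "gen_mixing",
    "gen_plate",
]


def _progress(model: str, k: float, t: np.ndarray) -> np.ndarray:
    if model == "first_order":
        return 1.0 - np.exp(-k * t)
    if model == "second_order":
        return k * t / (1.0 + k * t)
    raise ValueError(f"unknown kinetic model {model!r}")


@dataclass
class ReactionSpec:
    """Single-vessel color transition with kinetic ground truth.

    ``k`` is the rate constant (1/s for first order); ``noise_sigma`` the
    Gaussian channel noise standard deviation in 8-bit units.
    """

    color_start: tuple = (250, 240, 60)
    color_end: tuple = (40, 30, 30)
    model: str = "first_order"
    k: float = 0.05
    duration: float = 300.0
    fps: float = 2.0
    noise_sigma: float = 0.0
    height: int = 32
    width: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.k <= 0 or self.fps <= 0 or self.duration <= 0:
            raise ValueError("k, fps and duration must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        _progress(self.model, self.k, np.zeros(1))  # validates model name


@dataclass
class MixingSpec:
    """Stirred-vessel dye homogenization on a square lattice.

    ``diffusion`` is the explicit-scheme diffusion number (stable up to
    0.25); ``swirl`` the peak angular displacement per step in radians.
    ``absorbance`` controls the Beer-Lambert-style concentration-to-color
    mapping (blend fraction ``1 - exp(-absorbance * c)``): a concentrated
    blob looks saturated rather than proportionally darker, so the spatial
    mean color evolves as the dye disperses — as it does on camera.
    """

    grid: tuple[int, int] = (64, 64)
    dye_color: tuple = (20, 40, 160)
    solvent_color: tuple = (245, 245, 245)
    blob_center: Optional[tuple[float, float]] = None  # default: off-center
    blob_radius: float = 8.0
    diffusion: float = 0.05
    swirl: float = 0.6
    absorbance: float = 4.0
    steps: int = 300
    fps: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.diffusion <= 0.25:
            raise ValueError("diffusion must be in (0, 0.25] for stability")
        H, W = self.grid
        if self.blob_center is None:
            self.blob_center = (H / 2.0, W * 0.3)
        cy, cx = self.blob_center
        r = self.blob_radius
        if cy - r < 0 or cx - r < 0 or cy + r > H or cx + r > W:
            raise ValueError("blob must lie inside the grid")


@dataclass
class PlateSpec:
    """Multi-well plate; each well runs its own first-order color program."""

    rows: int = 4
    cols: int = 6
    k_values: Optional[np.ndarray] = None  # shape rows*cols; default log-spaced
    color_start: tuple = (90, 40, 150)
    color_end: tuple = (240, 240, 235)
    model: str = "first_order"
    duration: float = 300.0
    fps: float = 1.0
    noise_sigma: float = 0.0
    well_radius: float = 6.0
    pitch: float = 16.0
    margin: float = 10.0
    background: tuple = (30, 30, 30)
    seed: int = 0

    def __post_init__(self):
        n = self.rows * self.cols
        if self.k_values is None:
            self.k_values = np.geomspace(0.01, 0.1, n)
        self.k_values = np.asarray(self.k_values, dtype=float)
        if self.k_values.shape != (n,):
            raise ValueError(f"k_values must have {n} entries")
        if np.any(self.k_values <= 0):
            raise ValueError("all k values must be positive")

    @property
    def canvas(self) -> tuple[int, int]:
        H = int(round(2 * self.margin + (self.rows - 1) * self.pitch)) + 1
        W = int(round(2 * self.margin + (self.cols - 1) * self.pitch)) + 1
        return H, W

    @property
    def centers(self) -> list[tuple[float, float]]:
        return [
            (self.margin + r * self.pitch, self.margin + c * self.pitch)
            for r in range(self.rows)
            for c in range(self.cols)
        ]


def _noisy_frames(clean: np.ndarray, t: np.ndarray, sigma: float, seed: int) -> list[Frame]:
    rng = np.random.default_rng(seed)
    frames = []
    for i, ti in enumerate(t):
        px = clean[i]
        if sigma > 0:
            px = np.clip(px + rng.normal(0.0, sigma, px.shape), 0.0, 255.0)
        frames.append(Frame(pixels=px, t=float(ti), index=i))
    return frames


def gen_reaction(spec: ReactionSpec) -> tuple[list[Frame], dict]:
    """Uniform-color frames following the spec's kinetic program, plus ground truth.

    The color program interpolates linearly in L*a*b* between the start and
    end colors (a perceptually steady transition), so the noiseless dE trace
    is exactly the endpoint color difference scaled by the progress curve
    ``f(t)`` and a rate fit on clean output recovers ``k`` exactly.  Ground
    truth contains the true ``k``, ``f(t)``, and the analytic dE(t).
    """
    n = int(round(spec.duration * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    f = _progress(spec.model, spec.k, t)
    lab_start = colorspace.rgb_to_lab(np.asarray(spec.color_start, dtype=float))
    lab_end = colorspace.rgb_to_lab(np.asarray(spec.color_end, dtype=float))
    lab = lab_start + f[:, None] * (lab_end - lab_start)
    colors = colorspace.lab_to_rgb(lab)
    clean = np.broadcast_to(
        colors[:, None, None, :], (n, spec.height, spec.width, 3)
    ).copy()
    frames = _noisy_frames(clean, t, spec.noise_sigma, spec.seed)
    de_end = float(colorspace.delta_e_1976(lab_start, lab_end))
    truth = {
        "model": spec.model,
        "k": spec.k,
        "t": t,
        "progress": f,
        "delta_e": de_end * f,
        "delta_e_endpoints": de_end,
    }
    return frames, truth


def _advect_swirl(c: np.ndarray, swirl: float) -> np.ndarray:
    """Semi-Lagrangian rotation about the grid center with radius-dependent rate.

    Angular displacement per step is ``swirl * exp(-(r/r0)^2)`` with
    ``r0 = 0.45 * min(H, W)``: fast near the core, still at the walls, so a
    blob is sheared into a spiral filament, as in an impeller-stirred vessel.
    """
    H, W = c.shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    r0 = 0.45 * min(H, W)
    theta = swirl * np.exp(-((r / r0) ** 2))
    # back-trace: sample the field at the pre-rotation position
    cos_t, sin_t = np.cos(-theta), np.sin(-theta)
    src_y = cy + cos_t * dy - sin_t * dx
    src_x = cx + sin_t * dy + cos_t * dx
    return map_coordinates(c, [src_y, src_x], order=1, mode="nearest")


def _diffuse(c: np.ndarray, d: float) -> np.ndarray:
    """One explicit 5-point-stencil diffusion step with reflecting boundaries.

    Reflecting (zero-flux) boundaries make the step exactly
    mass-conserving: every pairwise exchange is antisymmetric.
    """
    p = np.pad(c, 1, mode="edge")
    lap = p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * c
    return c + d * lap


def gen_mixing(spec: MixingSpec) -> tuple[list[Frame], dict]:
    """Dye-mixing frame sequence plus the ground-truth concentration fields.

    Returns the rendered frames and a dict with the per-step concentration
    fields (``fields``, shape (steps+1, H, W)) and timestamps.  Rendering
    blends solvent toward dye color by ``1 - exp(-absorbance * c)``.
    """
    H, W = spec.grid
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = spec.blob_center
    # Gaussian-edged footprint (sigma = radius/2): injected dye is already
    # partially dispersed, never a perfectly sharp disc
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    c = np.exp(-r2 / (2.0 * (spec.blob_radius / 2.0) ** 2))
    fields = [c.copy()]
    for _ in range(spec.steps):
        if spec.swirl != 0.0:
            c = _advect_swirl(c, spec.swirl)
        c = _diffuse(c, spec.diffusion)
        fields.append(c.copy())
    fields = np.array(fields)
    dye = np.asarray(spec.dye_color, dtype=float)
    solvent = np.asarray(spec.solvent_color, dtype=float)
    t = np.arange(spec.steps + 1) / spec.fps
    frames = []
    for i in range(spec.steps + 1):
        blend = 1.0 - np.exp(-spec.absorbance * fields[i])
        px = solvent + blend[..., None] * (dye - solvent)
        frames.append(Frame(pixels=np.clip(px, 0, 255), t=float(t[i]), index=i))
    return frames, {"fields": fields, "t": t}


def gen_plate(spec: PlateSpec) -> tuple[list[Frame], ROISet, dict]:
    """Well-plate frame sequence, the matching ROISet, and per-well true rate constants."""
    H, W = spec.canvas
    layout = plate_layout(spec.rows, spec.cols, spec.centers, spec.well_radius, (H, W))
    n = int(round(spec.duration * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    lab_start = colorspace.rgb_to_lab(np.asarray(spec.color_start, dtype=float))
    lab_end = colorspace.rgb_to_lab(np.asarray(spec.color_end, dtype=float))
    bg = np.asarray(spec.background, dtype=float)
    clean = np.empty((n, H, W, 3))
    clean[:] = bg
    for roi, k in zip(layout, spec.k_values):
        f = _progress(spec.model, k, t)
        # same Lab-linear color program as gen_reaction, per well
        colors = colorspace.lab_to_rgb(lab_start + f[:, None] * (lab_end - lab_start))
        clean[:, roi.mask, :] = colors[:, None, :]
    frames = _noisy_frames(clean, t, spec.noise_sigma, spec.seed)
    truth = {"k": spec.k_values.copy(), "wells": layout.names, "t": t}
    return frames, layout, truth
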