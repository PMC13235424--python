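"""Regions of interest over video frames and per-frame spatial color averages.

A :class:`Frame` is one decoded image with a timestamp.  An :class:`ROI` is a
named boolean mask; an :class:`ROISet` is an ordered, uniquely named group of
ROIs sharing a frame geometry.  Three layouts are supported: plain rectangles,
regular grid partitions of a rectangle (for spatially segmented mixing
analysis), and circular wells on a plate lattice (for parallel kinetic
screening).

Coordinates are 0-based, row-major, origin at the top-left; rectangles are
half-open ``[top, top+height) x [left, left+width)``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Frame",
    "ROI",
    "ROISet",
    "GeometryError",
    "make_rect_roi",
    "grid_partition",
    "plate_layout",
    "spatial_mean",
    "roiset_from_config",
]


class GeometryError(ValueError):
    """An ROI does not fit the frame geometry."""


@dataclass
class Frame:
    """One H x W x 3 image of channel intensities in [0,255] plus a timestamp.

    Attributes
    ----------
    pixels : ndarray, shape (H, W, 3)
        RGB channel intensities, stored as float in [0, 255].
    t : float
        Seconds from recording start.
    index : int
        0-based frame number in the source sequence.
    """

    pixels: np.ndarray
    t: float
    index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be (H, W, 3), got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("frame must have at least one pixel")

    @property
    def geometry(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ROI:
    """A named boolean pixel mask of one of the kinds {rect, grid_cell, well}."""

    name: str
    mask: np.ndarray
    kind: str = "rect"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} has an empty mask")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(top, left, height, width) of the tight bounding box of the mask."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return (
            int(rows[0]),
            int(cols[0]),
            int(rows[-1] - rows[0] + 1),
            int(cols[-1] - cols[0] + 1),
        )


@dataclass
class ROISet:
    """Ordered collection of ROIs with unique names over a shared geometry."""

    rois: list[ROI] = field(default_factory=list)
    geometry: tuple[int, int] = (0, 0)

    def __post_init__(self):
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        for r in self.rois:
            if r.mask.shape != tuple(self.geometry):
                raise GeometryError(
                    f"ROI {r.name!r} mask shape {r.mask.shape} does not match "
                    f"geometry {self.geometry}"
                )

    def __iter__(self):
        return iter(self.rois)

    def __len__(self):
        return len(self.rois)

    def __getitem__(self, name: str) -> ROI:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]


def make_rect_roi(
    top: int,
    left: int,
    height: int,
    width: int,
    geometry: tuple[int, int],
    name: str = "roi",
) -> ROI:
    """Build a rectangular ROI with half-open extent [top, top+height) x [left, left+width).

    Raises :class:`GeometryError` if the rectangle is not fully inside the frame.
    """
    H, W = geometry
    if height < 1 or width < 1:
        raise GeometryError("height and width must be >= 1")
    if top < 0 or left < 0 or top + height > H or left + width > W:
        raise GeometryError(
            f"rectangle ({top},{left},{height},{width}) exceeds frame {geometry}"
        )
    mask = np.zeros((H, W), dtype=bool)
    mask[top : top + height, left : left + width] = True
    return ROI(name=name, mask=mask, kind="rect")


def grid_partition(parent: ROI, rows: int, cols: int) -> ROISet:
    """Partition a rectangular ROI into a rows x cols grid of cells "r{i}c{j}".

    Cells are pairwise disjoint and their union is exactly the parent
    rectangle.  When a dimension does not divide evenly, the remainder pixels
    are assigned to the last row/column of cells.
    """
    top, left, height, width = parent.bounding_box()
    if parent.mask.sum() != height * width:
        raise GeometryError("grid_partition requires a rectangular parent ROI")
    if rows < 1 or cols < 1:
        raise GeometryError("rows and cols must be >= 1")
    if rows > height or cols > width:
        raise GeometryError(
            f"{rows}x{cols} grid exceeds parent pixel dimensions {height}x{width}"
        )
    geometry = parent.mask.shape
    rh, ch = height // rows, width // cols
    cells = []
    for i in range(rows):
        r0 = top + i * rh
        r1 = top + height if i == rows - 1 else r0 + rh
        for j in range(cols):
            c0 = left + j * ch
            c1 = left + width if j == cols - 1 else c0 + ch
            mask = np.zeros(geometry, dtype=bool)
            mask[r0:r1, c0:c1] = True
            cells.append(ROI(name=f"r{i}c{j}", mask=mask, kind="grid_cell"))
    return ROISet(rois=cells, geometry=geometry)


def _well_names(rows: int, cols: int) -> list[str]:
    # "A1".."H12"-style labels, row letters then column numbers
    letters = string.ascii_uppercase
    return [f"{letters[i]}{j + 1}" for i in range(rows) for j in range(cols)]


def plate_layout(
    rows: int,
    cols: int,
    centers: list[tuple[float, float]],
    radius: float,
    geometry: tuple[int, int],
) -> ROISet:
    """Circular well masks on a plate, named "A1".."H12"-style.

    A pixel belongs to a well when the Euclidean distance from its (row, col)
    center coordinate to the well center is <= radius.  Overlapping wells emit
    a warning (tightly packed plates are legitimate); a well extending outside
    the frame is a :class:`GeometryError`.
    """
    if rows * cols != len(centers):
        raise GeometryError(f"{rows}x{cols} plate needs {rows * cols} centers, got {len(centers)}")
    if radius < 1:
        raise GeometryError("radius must be >= 1")
    H, W = geometry
    rr, cc = np.mgrid[0:H, 0:W]
    rois = []
    for name, (cy, cx) in zip(_well_names(rows, cols), centers):
        if cy - radius < -0.5 or cx - radius < -0.5 or cy + radius > H - 0.5 or cx + radius > W - 0.5:
            raise GeometryError(f"well {name} at ({cy},{cx}) radius {radius} extends outside frame")
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        rois.append(ROI(name=name, mask=mask, kind="well"))
    total = np.zeros(geometry, dtype=int)
    for r in rois:
        total += r.mask
    if (total > 1).any():
        warnings.warn("plate wells overlap; shared pixels contribute to multiple wells")
    return ROISet(rois=rois, geometry=geometry)


def spatial_mean(frame: Frame, roi: ROI) -> np.ndarray:
    """Arithmetic per-channel mean of frame pixels under the ROI mask, unrounded."""
    if roi.mask.shape != frame.geometry:
        raise GeometryError(
            f"ROI geometry {roi.mask.shape} does not match frame {frame.geometry}"
        )
    return frame.pixels[roi.mask].mean(axis=0)


def roiset_from_config(spec, geometry: tuple[int, int]) -> ROISet:
    """Build an ROISet from a config mapping (parsed YAML).

    Recognized entries (a list under the key ``rois``, or a bare list):

    * ``{name, rect: [top, left, height, width]}`` — one rectangle;
    * ``{grid: {rect: [...], rows, cols}}`` — a grid partition;
    * ``{plate: {rows, cols, pitch, origin: [row, col], radius}}`` — a regular
      well lattice with the given center-to-center pitch.
    """
    if isinstance(spec, dict):
        spec = spec.get("rois", [])
    rois: list[ROI] = []
    for i, entry in enumerate(spec):
        if "rect" in entry:
            t, l, h, w = entry["rect"]
            rois.append(make_rect_roi(t, l, h, w, geometry, name=entry.get("name", f"roi{i}")))
        elif "grid" in entry:
            g = entry["grid"]
            parent = make_rect_roi(*g["rect"], geometry, name="_parent")
            rois.extend(grid_partition(parent, g["rows"], g["cols"]).rois)
        elif "plate" in entry:
            p = entry["plate"]
            oy, ox = p["origin"]
            pitch = p["pitch"]
            centers = [
                (oy + r * pitch, ox + c * pitch)
                for r in range(p["rows"])
                for c in range(p["cols"])
            ]
            rois.extend(
                plate_layout(p["rows"], p["cols"], centers, p["radius"], geometry).rois
            )
        else:
            raise ValueError(f"unrecognized ROI entry: {entry!r}")
    return ROISet(rois=rois, geometry=geometry)
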