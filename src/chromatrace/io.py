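"""Frame ingestion and emission.

Videos are treated as frame sequences: either a container file decodable by
imageio (timestamps from the container frame rate) or a directory of
lexicographically ordered still images with a configured fps.  Channel order
is fixed to RGB at this boundary regardless of decoder convention; all
downstream math assumes RGB.  Stills are written as PNG (lossless, so a
write/read round trip is pixel-identical and codec color shifts cannot leak
into the analysis).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .regions import Frame

__all__ = ["read_frames", "write_frames"]

_STILL_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:  # grayscale still: replicate channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return arr.astype(float)


def read_frames(
    path, sample_every: int = 1, fps: Optional[float] = None
) -> list[Frame]:
    """Decode a video file or a directory of numbered stills into Frames.

    ``sample_every`` retains every k-th frame at decode time (frame-rate
    pruning).  For still directories ``fps`` is required to assign
    timestamps; for containers the container frame rate is used unless
    ``fps`` overrides it.
    """
    if sample_every < 1:
        raise ValueError("sample_every must be >= 1")
    path = Path(path)
    if path.is_dir():
        stills = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _STILL_SUFFIXES
        )
        if not stills:
            raise IOError(f"no still images found in {path}")
        if fps is None:
            raise ValueError(
                f"reading stills from {path} requires a configured fps"
            )
        frames = []
        for i, p in enumerate(stills[::sample_every]):
            idx = i * sample_every
            frames.append(Frame(pixels=_to_rgb(iio.imread(p)), t=idx / fps, index=idx))
        return frames

    if not path.exists():
        raise IOError(f"no such video file: {path}")
    try:
        meta = iio.immeta(path)
        container_fps = fps if fps is not None else meta.get("fps")
        if container_fps is None:
            raise ValueError(f"{path}: container reports no frame rate; pass fps")
        frames = []
        for i, arr in enumerate(iio.imiter(path)):
            if i % sample_every:
                continue
            frames.append(
                Frame(pixels=_to_rgb(np.asarray(arr)), t=i / container_fps, index=i)
            )
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot decode video container {path}: {exc}") from exc
    if not frames:
        raise IOError(f"no frames decoded from {path}")
    return frames


def write_frames(frames: Sequence[Frame], outdir) -> list[Path]:
    """Write frames as numbered PNG stills (frame_000000.png, ...); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = outdir / f"frame_{i:06d}.png"
        iio.imwrite(p, np.clip(np.round(f.pixels), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths
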