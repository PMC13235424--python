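"""Per-ROI color traces and kinetic analysis.

A :class:`ColorTrace` carries, per retained frame, the spatially averaged
color of one ROI in RGB, HSV, and CIE L*a*b*, plus two derived scalars: the
CIE 1976 color difference dE against a reference frame (first frame by
default) and the brightness-loss RGB sum response.  From the dE series this
module extracts:

* onset time — the earliest time the smoothed rate of color change exceeds a
  threshold;
* plateau (end-point) time — the earliest time the rate stays below a
  threshold, guarded by a minimum total excursion so the unreacted start is
  never flagged;
* rate constants — nonlinear least-squares fits of first-order
  ``A*(1 - exp(-k*t))`` or second-order ``A*k*t/(1 + k*t)`` progress curves
  (the second-order form fixes the initial concentration scale to 1: only the
  product ``k*c0`` is identifiable from a unitless color trace);
* correlation with sparse offline measurements via nearest-in-time pairing
  and a histogram mutual-information estimator that captures nonlinear
  dependence.

Rate-of-change estimation uses centered finite differences on a
boxcar-smoothed trace; the smoothing window is a parameter of the onset and
plateau detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import colorspace
from .regions import Frame, ROI, spatial_mean

__all__ = [
    "ColorTrace",
    "KineticSummary",
    "OfflineSeries",
    "build_trace",
    "resample_trace",
    "detect_onset",
    "detect_plateau",
    "fit_rate",
    "mutual_information",
    "align_offline",
    "trace_to_frame",
]

#: dE changes below ~2 sit within the instrumental noise floor, so the
#: plateau guard defaults a little above that.
DEFAULT_MIN_EXCURSION = 3.0


@dataclass
class ColorTrace:
    """Time series of color coordinates and derived scalars for one ROI."""

    roi_name: str
    t: np.ndarray
    rgb: np.ndarray
    hsv: np.ndarray
    lab: np.ndarray
    delta_e: np.ndarray
    rgb_sum: np.ndarray
    reference_index: int = 0
    frame_index: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.t)
        for name in ("rgb", "hsv", "lab", "delta_e", "rgb_sum"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length != time axis length {n}")
        if self.frame_index is None:
            self.frame_index = np.arange(n)

    def __len__(self):
        return len(self.t)


@dataclass
class KineticSummary:
    """Fitted kinetic quantities and end-point markers for one ROI."""

    roi_name: str = ""
    model: str = "first_order"
    k: float = float("nan")
    amplitude: float = float("nan")
    rss: float = float("nan")
    onset_time: Optional[float] = None
    plateau_time: Optional[float] = None
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "roi": self.roi_name,
            "model": self.model,
            "k": self.k,
            "amplitude": self.amplitude,
            "rss": self.rss,
            "onset_time_s": self.onset_time,
            "plateau_time_s": self.plateau_time,
            "converged": self.converged,
            "message": self.message,
        }


@dataclass
class OfflineSeries:
    """Sparse offline measurements (e.g. conversion from NMR) at known times."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError("offline times must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("offline values must be finite")

    @classmethod
    def from_csv(cls, path) -> "OfflineSeries":
        df = pd.read_csv(path)
        return cls(t=df.iloc[:, 0].to_numpy(), value=df.iloc[:, 1].to_numpy())


def build_trace(
    frames: Sequence[Frame], roi: ROI, reference_index: int = 0
) -> ColorTrace:
    """Reduce a frame sequence to a per-ROI color trace.

    Each frame is averaged over the ROI mask; the mean RGB is converted to HSV
    and L*a*b*, and dE is the 1976 color difference of each sample's Lab
    against the Lab of the reference sample (first frame by default — the
    reference is a parameter because the dE trace is sensitive to it).
    """
    if len(frames) < 2:
        raise ValueError("build_trace requires at least 2 frames")
    if not 0 <= reference_index < len(frames):
        raise ValueError(f"reference_index {reference_index} out of range")
    t = np.array([f.t for f in frames], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame timestamps must be strictly increasing")
    rgb = np.array([spatial_mean(f, roi) for f in frames])
    hsv = colorspace.rgb_to_hsv(rgb)
    lab = colorspace.rgb_to_lab(rgb)
    delta_e = colorspace.delta_e_1976(lab, lab[reference_index])
    rgb_sum = colorspace.rgb_sum_response(rgb)
    return ColorTrace(
        roi_name=roi.name,
        t=t,
        rgb=rgb,
        hsv=hsv,
        lab=lab,
        delta_e=delta_e,
        rgb_sum=rgb_sum,
        reference_index=reference_index,
        frame_index=np.array([f.index for f in frames]),
    )


def resample_trace(trace: ColorTrace, keep_every: int) -> ColorTrace:
    """Keep samples 0, k, 2k, ... — emulating a lower acquisition frame rate.

    The dE reference is re-anchored to the retained sample nearest in time to
    the original reference, and dE is recomputed against it.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    if keep_every == 1:
        return trace
    sl = slice(None, None, keep_every)
    kept = np.arange(len(trace))[sl]
    new_ref = int(np.argmin(np.abs(kept - trace.reference_index)))
    lab = trace.lab[sl]
    if kept[new_ref] == trace.reference_index:
        # reference sample survived thinning: its dE values are still valid
        delta_e = trace.delta_e[sl]
    else:
        # dE is a distance, not a coordinate: recompute against the new anchor
        delta_e = colorspace.delta_e_1976(lab, lab[new_ref])
    return ColorTrace(
        roi_name=trace.roi_name,
        t=trace.t[sl],
        rgb=trace.rgb[sl],
        hsv=trace.hsv[sl],
        lab=lab,
        delta_e=delta_e,
        rgb_sum=trace.rgb_sum[sl],
        reference_index=new_ref,
        frame_index=trace.frame_index[sl],
    )


def _smoothed_rate(trace: ColorTrace, window: int) -> np.ndarray:
    """Centered finite-difference rate (dE/s) of a boxcar-smoothed dE series.

    Even window sizes are rounded up to the next odd length so the boxcar
    stays centered (an even kernel would shift the rate estimate by half a
    sample spacing).
    """
    if window < 2:
        raise ValueError("window must be >= 2 samples")
    if window > len(trace):
        raise ValueError(f"window {window} longer than trace ({len(trace)} samples)")
    w = window | 1
    half = w // 2
    kernel = np.ones(w) / w
    padded = np.pad(trace.delta_e, half, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return np.gradient(smoothed, trace.t)


def detect_onset(
    trace: ColorTrace, window: int = 5, eps: float = 0.1
) -> Optional[float]:
    """Earliest time the smoothed rate of color change first exceeds ``eps`` (dE/s).

    Returns None when the rate never exceeds the threshold (no detectable
    reaction start).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    rate = _smoothed_rate(trace, window)
    above = np.flatnonzero(rate > eps)
    if len(above) == 0:
        return None
    return float(trace.t[above[0]])


def detect_plateau(
    trace: ColorTrace,
    window: int = 5,
    eps: float = 0.05,
    min_run: int = 3,
    min_excursion: float = DEFAULT_MIN_EXCURSION,
) -> Optional[float]:
    """End-point detection: earliest time the rate of color change settles below ``eps``.

    A plateau at sample ``i`` requires the smoothed centered-difference rate
    to stay below ``eps`` for ``min_run`` consecutive windows (i.e.
    ``min_run * window`` samples) starting at ``i``, and the accumulated color
    change ``delta_e[i]`` to have reached ``min_excursion`` — the guard that
    prevents flagging the flat unreacted start of a trace.  Returns None when
    no such time exists.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    rate = _smoothed_rate(trace, window)
    n = len(trace)
    run_len = min(min_run * window, n)
    below = rate < eps
    for i in range(n - run_len + 1):
        if below[i : i + run_len].all() and trace.delta_e[i] >= min_excursion:
            return float(trace.t[i])
    return None


def _first_order(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def _second_order(t, A, k):
    # c0 fixed to 1: only k*c0 is identifiable from a unitless trace
    return A * k * t / (1.0 + k * t)


_MODELS = {"first_order": _first_order, "second_order": _second_order}


def fit_rate(trace: ColorTrace, model: str = "first_order") -> KineticSummary:
    """Least-squares fit of the dE progress curve; returns rate constant and diagnostics.

    The initializer is deterministic: ``A0 = max(delta_e)`` and ``k0`` from
    the time to half-maximal dE, so repeated fits of the same trace are
    identical.  Non-convergence is reported in the summary (``converged``
    False), never raised.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}")
    if len(trace) < 10:
        raise ValueError("fit_rate requires at least 10 samples")
    t = trace.t - trace.t[0]
    y = trace.delta_e
    A0 = float(y.max())
    if A0 <= 0:
        raise ValueError("degenerate trace: delta_e has no excursion")
    half = np.flatnonzero(y >= A0 / 2)
    t_half = float(t[half[0]]) if len(half) and t[half[0]] > 0 else float(t[-1]) / 2
    k0 = np.log(2.0) / t_half if model == "first_order" else 1.0 / t_half
    fn = _MODELS[model]
    try:
        popt, _ = curve_fit(
            fn,
            t,
            y,
            p0=[A0, k0],
            bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
        A, k = float(popt[0]), float(popt[1])
        rss = float(np.sum((y - fn(t, A, k)) ** 2))
        return KineticSummary(
            roi_name=trace.roi_name, model=model, k=k, amplitude=A, rss=rss
        )
    except RuntimeError as exc:
        return KineticSummary(
            roi_name=trace.roi_name,
            model=model,
            converged=False,
            message=str(exc),
        )


def mutual_information(x, y, bins: int = 16) -> float:
    """Histogram plug-in mutual information of two sample vectors, in nats.

    ``MI = sum_ij p_ij * ln(p_ij / (p_i * p_j))`` over an equal-width
    ``bins x bins`` grid, with ``0 * ln(0) = 0``.  Captures both linear and
    nonlinear dependence; always non-negative.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 20:
        raise ValueError("mutual_information requires at least 20 samples")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    counts, _, _ = np.histogram2d(x, y, bins=bins)
    p = counts / counts.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def align_offline(trace: ColorTrace, offline: OfflineSeries):
    """Pair each offline measurement with the nearest-in-time dE sample.

    Ties between two equally distant samples resolve to the earlier one.
    Offline points outside the trace time span are dropped with a warning.
    Returns ``(delta_e_values, offline_values)`` ready for correlation or
    :func:`mutual_information`.
    """
    de, vals = [], []
    t0, t1 = trace.t[0], trace.t[-1]
    for ti, vi in zip(offline.t, offline.value):
        if ti < t0 or ti > t1:
            warnings.warn(
                f"offline time {ti} s outside trace span [{t0}, {t1}] s; dropped"
            )
            continue
        d = np.abs(trace.t - ti)
        idx = int(np.argmin(d))  # argmin takes the first (earlier) on ties
        de.append(trace.delta_e[idx])
        vals.append(vi)
    return np.asarray(de), np.asarray(vals)


def trace_to_frame(trace: ColorTrace) -> pd.DataFrame:
    """Tidy per-sample table: frame_index, t_seconds, roi, R..b, delta_e, rgb_sum."""
    return pd.DataFrame(
        {
            "frame_index": trace.frame_index,
            "t_seconds": trace.t,
            "roi": trace.roi_name,
            "R": trace.rgb[:, 0],
            "G": trace.rgb[:, 1],
            "B": trace.rgb[:, 2],
            "H": trace.hsv[:, 0],
            "S": trace.hsv[:, 1],
            "V": trace.hsv[:, 2],
            "L": trace.lab[:, 0],
            "a": trace.lab[:, 1],
            "b": trace.lab[:, 2],
            "delta_e": trace.delta_e,
            "rgb_sum": trace.rgb_sum,
        }
    )
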