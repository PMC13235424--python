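# chromatrace

Video colorimetry for reaction monitoring. `chromatrace` turns a video of a
color-changing chemical or biochemical process — a catalyst darkening, a dye
decolorizing, a well plate of parallel reactions, a vessel being stirred —
into time-resolved kinetic data: per-region color traces, reaction onset and
end-point times, fitted rate constants, and spatially resolved mixing
metrics. It is aimed at chemists and process engineers who want quantitative
kinetics from an ordinary camera instead of qualitative "it turned dark
around 3 pm" lab-book notes, and at anyone building colorimetric assays
(e.g. plate-based screening) who needs the analysis chain to be testable
end to end without recorded footage.

## What it computes

Each frame is spatially averaged over user-defined regions of interest
(rectangles, grid cells, or circular plate wells) and the mean RGB is
converted to HSV and CIE L\*a\*b\* (sRGB primaries, D65 white). The central
observable is the CIE 1976 color difference of frame *t* against a reference
frame (the first, by default):

ΔE(t) = √[(L\*ₜ−L\*₀)² + (a\*ₜ−a\*₀)² + (b\*ₜ−b\*₀)²]

a hue-agnostic magnitude of color change. From the ΔE trace the package
extracts:

- **onset / plateau times** — the earliest times the boxcar-smoothed rate of
  color change rises above / settles below a threshold ε (ΔE/s), the plateau
  guarded by a minimum excursion so an unreacted flat start is never flagged;
- **rate constants** — nonlinear least squares of first-order
  *A*(1−e^(−kt)) or second-order *A·kt*/(1+*kt*) progress curves;
- **offline correlation** — nearest-in-time pairing of the trace with sparse
  offline measurements (e.g. NMR conversion) and a histogram
  mutual-information estimator for nonlinear dependence;
- **mixing metrics** — per frame, *Contact* (the count of 4-adjacent pixel
  pairs that differ after RGB thresholding: an interfacial perimeter that
  peaks at maximum heterogeneity) and gray-level co-occurrence matrix (GLCM)
  texture features: ASM = Σp², entropy = −Σp·log₂p, homogeneity = Σp/(1+|i−j|).

A seedable synthetic-video module generates single-vessel reactions,
advection–diffusion dye mixing, and multi-well plates with known ground
truth, so every stage of the pipeline is testable offline.

## Worked example

```python
import numpy as np
from chromatrace import (
    ReactionSpec, gen_reaction, make_rect_roi, build_trace,
    fit_rate, detect_onset, detect_plateau,
)

spec = ReactionSpec(
    color_start=(250, 240, 60),   # yellow solution
    color_end=(40, 30, 30),       # dark product
    model="first_order", k=0.02,  # 1/s
    duration=400, fps=1, noise_sigma=2.0, seed=7,
)
frames, truth = gen_reaction(spec)

roi = make_rect_roi(4, 4, 24, 24, frames[0].geometry, name="vessel")
trace = build_trace(frames, roi)

summary = fit_rate(trace, "first_order")
onset = detect_onset(trace, window=5, eps=0.1)
plateau = detect_plateau(trace, window=5, eps=0.05, min_excursion=5)

print(f"final dE      : {trace.delta_e[-1]:.1f}")
print(f"fitted k      : {summary.k:.4f} 1/s   (true {truth['k']})")
print(f"amplitude A   : {summary.amplitude:.1f} dE units")
print(f"onset time    : {onset:.0f} s")
print(f"plateau time  : {plateau:.0f} s")
```

prints

```
final dE      : 115.0
fitted k      : 0.0200 1/s   (true 0.02)
amplitude A   : 114.9 dE units
onset time    : 0 s
plateau time  : 210 s
```

The yellow-to-dark transition spans ~115 ΔE units (a complete colorimetric
transformation; changes below ~2 are within camera noise). Despite 2 units
of per-channel pixel noise, the fitted rate constant matches the generator's
ground truth, the reaction is detected as already running at *t* = 0, and
the end-point lands where the analytic rate *A·k·e^(−kt)* crosses ε.

The same analysis runs from the shell on real footage (any imageio-readable
video, or a directory of PNG stills):

```bash
chromatrace simulate reaction.yaml --out stills/   # or use your own video
chromatrace analyze run.yaml                       # traces CSV + summaries JSON + log
chromatrace report rundir/
```

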