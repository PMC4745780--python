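# organotrack

Automated tracking and morphometry of tumor-organoid / fibroblast 3D
co-cultures from live-cell microscopy.

Prostate-cancer organoids grown in extracellular matrix together with
cancer-associated fibroblasts (CAFs) form microtissues whose drug response
differs sharply from monocultures. Quantifying those experiments means
measuring, over weeks of hourly two-channel time-lapse imaging and end-point
confocal stacks, how the stromal cohorts grow, move and branch, and how the
tumor organoids grow and change shape. `organotrack` implements that
measurement pipeline for image analysts and quantitative biologists working
with such co-cultures, and ships synthetic phantoms with exact ground truth
so every stage is testable without microscope data.

## What it computes

- **Stabilization** — camera jitter removed by phase correlation: the
  normalized cross-power spectrum T(u) = F·G*/(|F|·|G|) = e^{2πiu·Δ}
  inverse-transforms to a peak at the inter-frame translation Δ; frames are
  compensated against frame 0 and cropped to the common field. A
  gradient-based variant handles defocused movies.
- **CAF cohort segmentation** — local adaptive thresholding: foreground iff
  p(x,y) − κ exceeds the Gaussian-weighted neighborhood mean
  T(x,y) = Σ f(x−i, y−j) w(i,j), with w(i,j) ∝ e^{−(i²+j²)/σ²}; small
  regions removed, cluster boundaries traced, area per frame as the growth
  read-out (growth rate = area_t / area_0).
- **Motility** — Farnebäck dense optical flow: each pixel neighborhood is a
  quadric f(x) = xᵀAx + bᵀx + c and a translation d of the surface solves
  d = −½A⁻¹(b₂ − b₁); motility per frame is the mean flow magnitude over
  the segmentation mask.
- **Branching** — convex hull + convexity defects of each cohort contour;
  defects deeper than a threshold count as cellular extensions, with the
  point-to-hull-chord distance as the extension size.
- **Tumor segmentation** — cascaded non-local means + mean-shift denoising,
  adaptive thresholding, morphological smoothing, and subtraction of the
  fibroblast mask so the two compartments never double-count a pixel.
- **Confocal MRF segmentation** — three labels (in-focus cells, cell
  shadow, background) by minimizing E(x) = Σ θ_{i;l} + Σ θ_{ij;lk} with
  mixture-model unaries θ_{i;l} = −log f_l(z_i) and contrast-sensitive
  Potts pairwise terms λ₀ + λ₁e^{−½β‖z_i−z_j‖²}, solved by α-expansion
  graph cuts; per-channel labelings overlay into a co-localization map.
- **Organoid morphometrics** — per-object Area, Roundness (4πA/P²),
  FiltRound, Density, AppNumber/MaxApp/MedApp (skeleton-branch appendage
  count and lengths), CellNumber; Mann–Whitney U or Welch t statistics vs a
  control with Bonferroni correction; log₂ fold-change heatmap matrices;
  growth curves normalized to the vehicle control (final control point =
  100%, inhibition = 100·(1 − treated/control)).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

An 8-frame two-channel co-culture phantom with known jitter (≤3 px), 10%
per-frame cohort growth, (1,1) px/frame cohort motion and a 6-branch cohort:

```python
import numpy as np
from organotrack.synth import generate_coculture_sequence
from organotrack.stabilize import stabilize_sequence, apply_shifts
from organotrack.fibro import (segment_sequence, fibroblast_area_series,
                               growth_rate_series)
from organotrack.motion import motion_series
from organotrack.shape import branching_series

phase, fluor, truth = generate_coculture_sequence(
    8, jitter_amplitude=3, growth_per_frame=0.1, n_branches=6,
    noise_sigma=5.0, seed=42, shape=(320, 320), base_radius=30,
    motion_per_frame=(1.0, 1.0))

stab_phase, crop, shifts = stabilize_sequence(phase, subpixel=False)
stab_fluor, _ = apply_shifts(fluor, shifts)   # registered channel
masks = segment_sequence(stab_fluor)
growth = growth_rate_series(fibroblast_area_series(masks))
motility = motion_series(stab_fluor, masks)
counts, sizes = branching_series(masks)
```

Output:

```
estimated jitter (dy, dx): [[-1, -3], [2, -1], [-1, 2], [0, 2], [0, 3], [3, -1], [-3, 0]]
true jitter      (dy, dx): [[-1, -3], [2, -1], [-1, 2], [0, 2], [0, 3], [3, -1], [-3, 0]]
growth rate: [1.0, 1.093, 1.206, 1.334, 1.468, 1.61, 1.773, 1.948]
ideal 1.1^i: [1.0, 1.1, 1.21, 1.331, 1.464, 1.611, 1.772, 1.949]
mean motion per frame (px): [1.66, 1.65, 1.58, 1.76, 1.72, 1.74, 1.74]
mean extensions per cohort: [6.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0, 6.0]
```

Shifts are estimated on the phase channel (whose organoid and matrix are
static) and recover the injected jitter exactly; the growth-rate curve
tracks the geometric 1.1^i law within ~2%; the motility read-out combines
the √2 ≈ 1.41 px/frame translation with the cohort's spreading edge; the
branch count is exact on every frame.

The same stages are available from a shell:

```bash
organotrack simulate --out sim/ --n-frames 8 --jitter 3 --seed 42
organotrack stabilize --in sim/phase.tif --out stab/
organotrack segment-fibro --in sim/fluor.tif --out seg/
organotrack branch --masks seg/fibro_mask.tif --out branch/
```

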