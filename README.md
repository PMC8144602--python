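# srskit

A toolkit for hyperspectral stimulated-Raman-scattering (SRS) microscopy in
the fingerprint window (1550–1750 cm⁻¹), where chemically specific but weak
and crowded Raman bands make single-shot acquisitions extremely noisy. It is
aimed at people building or evaluating computational pipelines for
spectral-focusing SRS platforms: it simulates realistic low-SNR
hyperspectral stacks of cell-like phantoms, restores them with a
spatial-spectral residual network, decomposes them into chemical maps with
pixel-wise LASSO unmixing, calibrates the spectral axis of a delay-line
scanner, and scores everything with standard restoration metrics — all
runnable end to end on generated data, with no microscope required.

## What is inside

- **`srskit.delayline`** — delay-line geometry (`L·sin θ·tan α` path span of
  a Littrow-grating scan, mm → ps conversion) and linear least-squares
  calibration of acquisition sample index → Raman shift (cm⁻¹), with R².
- **`srskit.simulate`** — Lorentzian band spectra under a 10 cm⁻¹ Gaussian
  instrument response (amide I 1650, acyl C=C 1655, sterol C=C 1669,
  limonene 1645/1678, pinene 1660 cm⁻¹); disk/annulus/rod phantoms; the
  bilinear forward model `D = C·S` plus a smooth baseline; Gaussian noise
  scaled to a target SNR (default 1.4); raw/ground-truth training pairs via
  `n`-frame averaging (100 frames ⇒ ~10× SNR).
- **`srskit.ssresnet`** — the SS-ResNet denoiser: a U-net encoder-decoder
  whose levels stack SS-Conv blocks (parallel 1×3×3 spatial and 3×1×1
  spectral convolutions, summed), spatial-only pooling, skip connections,
  and a zero-initialized linear residual head, trained with Adam on MSE
  between prediction and frame-averaged ground truth. Implemented in pure
  NumPy (hand-written backprop, gradient-checked); no GPU or deep-learning
  framework needed.
- **`srskit.unmix`** — per-pixel sparse unmixing
  `argmin_c ½‖d − c·S‖² + β‖c‖₁` by vectorized cyclic coordinate descent
  with soft-thresholding, optional non-negativity, and a crosstalk-based β
  tuner.
- **`srskit.metrics`** — NRMSE and SSIM after percentile (0.3/99.7) dynamic
  range normalization, and SNR as signal-mean over background-σ.
- **`srskit.io` / `srskit.pipeline` / `srskit.cli`** — float32 multi-page
  TIFF stacks with CSV axis sidecars, provenance metadata, and a `srskit`
  command with `simulate`, `calibrate`, `train`, `finetune`, `denoise`,
  `unmix`, `evaluate`, and `run` subcommands.

See `docs/methods.md` for the models, defaults, and their assumptions.

## Worked example

```python
import numpy as np
from srskit.delayline import (DelayGeometry, effective_delay_length,
                              delay_length_to_time, fit_linear_calibration)
from srskit.simulate import (default_library, fingerprint_axis,
                             random_cell_scene, build_phantom,
                             render_clean_stack, make_pair)
from srskit.metrics import snr_measure
from srskit.unmix import UnmixConfig, unmix_stack

# Delay-line geometry: a 20 mm scan line, grating rotated 20 deg, 30 deg blaze.
geom = DelayGeometry(scan_line_length_mm=20, grating_rotation_deg=20,
                     blaze_angle_deg=30)
span = effective_delay_length(geom)
print(f"delay span: {span:.3f} mm -> "
      f"{delay_length_to_time(span, geom.round_trip_factor):.1f} ps")

# Spectral-axis calibration from 11 known peaks.
idx = np.arange(11.0) * 11.7
shifts = 1.5625 * idx + 1548.0 + np.random.default_rng(0).normal(0, 0.4, 11)
cal = fit_linear_calibration(idx, shifts)
print(f"calibration: slope={cal.slope:.4f} cm-1/sample, R^2={cal.r_squared:.4f}")

# A synthetic cell field: raw single-shot frame plus 100-frame ground truth.
axis = fingerprint_axis(32)
library = default_library(("bsa", "triglyceride", "cholesterol"), axis)
scene = random_cell_scene((64, 64), 3, np.random.default_rng(7))
maps = build_phantom(scene, 3)
clean = render_clean_stack(maps, library, scene.baseline_amplitude)
mask = maps.sum(axis=2) > 0
pair = make_pair(clean, n_avg=100, target_snr=1.4, seed=7, signal_mask=mask)
ch = clean.axis.nearest_channel(1650.0)
print(f"raw SNR at 1650 cm-1: {snr_measure(pair.raw.data, ch, mask, ~mask):.2f}")
print(f"GT SNR at 1650 cm-1:  {snr_measure(pair.ground_truth.data, ch, mask, ~mask):.2f}")

# Chemical maps from the ground truth.
result = unmix_stack(pair.ground_truth, library,
                     UnmixConfig(beta=0.01, nonnegative=True))
for name in library.names:
    print(f"mean {name} abundance in cells: {result.component(name)[mask].mean():.3f}")
```

Output:

```
delay span: 3.949 mm -> 26.3 ps
calibration: slope=1.5598 cm-1/sample, R^2=1.0000
raw SNR at 1650 cm-1: 1.19
GT SNR at 1650 cm-1:  11.68
mean bsa abundance in cells: 0.560
mean triglyceride abundance in cells: 0.249
mean cholesterol abundance in cells: 0.164
```

The single raw frame sits near the SNR ≈ 1.4 single-shot regime (measured
here at the 1650 cm⁻¹ channel, slightly off the reference channel used to
set the noise), the 100-frame average recovers roughly the √100 = 10-fold
gain, and unmixing the averaged stack attributes most in-cell intensity to
protein with smaller lipid and cholesterol fractions, as the scene was
drawn. Training and applying the denoiser works the same way through
`srskit.ssresnet.train_denoiser` / `denoise`, or from the shell:

```sh
srskit run --seed 3 --out runs/demo          # full pipeline, tiny defaults
srskit simulate --out data --seed 1          # just the generator
srskit unmix --stack data/pair00_gt.tif --library data/library.csv \
             --beta 0.01 --nonnegative --out maps
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline from scratch at the given seed — generating
phantoms and training pairs, training the denoiser, denoising a held-out
stack, unmixing it, and scoring the result — and writes the results JSON to
the given path.
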