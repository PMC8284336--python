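# retdecode

How faithfully do retinal ganglion cells (RGCs) relay a visual pattern when
the stimulus arrives through a subretinal electrical implant instead of the
photoreceptors — and what does that mean for the speed and acuity of
prosthetic vision? `retdecode` is a Python implementation of the analysis
chain for that question: single-cell encoding models, a noise-ratio
estimator built on spike-triggered-average correlation curves, and an
ensemble template decoder for Landolt-C orientation, together with a
ground-truth synthetic retina that makes every estimator testable by
parameter recovery.

It is aimed at retinal electrophysiologists and prosthetic-vision modelers
who record spike trains against spatiotemporal binary white noise (visual:
30 Hz frames, 60 µm pixels; electrical: 20 Hz, 70 µm) and want to quantify
response fidelity at the cell and population level.

## The models and statistics

**Encoding.** Each cell is fit with a linear–nonlinear (LN) model

    R(s) = N(w · s)

where `w` is the spike-triggered average (STA) on the training segment
(denoised to its best space–time separable rank-1 approximation) and `N` a
monotone lookup estimated from quantile-binned drives, and with a
convolutional network — two blocks of (conv → parametric ReLU → batch norm
→ dropout) followed by a dense readout — trained with Adam on the Poisson
likelihood with L2 weight and L1 output regularization:

    L = (1/N) Σᵢ (R̂ᵢ − Rᵢ log R̂ᵢ) + (α/2) Σⱼ ‖Wⱼ‖²_F + (β/N) Σᵢ |R̂ᵢ|

Because white-noise recordings have no repeats, predictions and observed
spikes are both broadened with a Gaussian (σ = 2 frames) before the Pearson
correlation, on a contiguous 20/20/60 train/test/discard split (five-fold
cross-validated variant included).

**Noise ratio.** With `F(i)` the cropped (3 px × 3 px × 4 frame) stimulus
window before spike `i`, the partial STA over the first `n` of `N` spikes
is `STA(n/N) = (1/n) Σ F(i)`; the characteristic correlation curve and its
area are

    CCC(n/N) = Corr(STA(1), STA(n/N)),   AUC = ∫₀¹ CCC(n/N) d(n/N).

A perfectly repeatable responder has AUC = 1; purely spontaneous firing
follows the √(n/N) noise curve. Injecting noise into a low-noise reference
cell — replacing a fraction NR of its spikes with Poisson-timed ones at the
same mean rate — yields a family of (NR, AUC) pairs; an unknown cell's NR
is read off by matching its AUC into the family.

**Decoding.** A pixelated Landolt C (gap = 1/5 of the letter diameter,
8 grey levels, 19 dark + 5 bright frames) is dotted with each cell's STA to
give a target input strength `w · ŝ`; the white-noise recording is scanned
for the 500 blocks `s` minimizing `|w·s − w·ŝ|`, and the cell's mean firing
in the 30 ms after those blocks (5 ms bins) is its expected letter
response. Concatenated across cells these form four orientation templates;
trials are Poisson draws from the true template (summed over flashes) and
are decoded by the highest template correlation.

## Worked example: recovering an injected noise ratio

```python
import numpy as np
from retdecode import (GroundTruthCell, generate_white_noise, simulate_cell,
                       inject_noise, compute_ccc, compute_auc,
                       build_noise_family, match_noise_ratio)

movie = generate_white_noise((18_000, 12, 12), frame_rate=30.0, seed=1)
cell = GroundTruthCell(cell_id="ref", center_um=(360.0, 360.0))
clean = simulate_cell(cell, movie, seed=2)
print(f"reference cell: {clean.n_spikes} spikes at {clean.rate:.1f} Hz")

family = build_noise_family(clean, movie, nr_grid=(0, 0.2, 0.4, 0.6, 0.8, 1.0),
                            n_seeds=5, seed=3)
for nr, auc in zip(family.nr_grid, family.aucs):
    print(f"  family NR={nr:.1f}  AUC={auc:.3f}")

noisy = inject_noise(clean, 0.65, seed=4)     # the "unknown" cell
curve = compute_ccc(noisy, movie)
print(f"query AUC = {compute_auc(curve):.3f}")
print(f"estimated noise ratio = {match_noise_ratio(curve, family):.3f}  (injected 0.65)")
```

Output:

```
reference cell: 15491 spikes at 25.8 Hz
  family NR=0.0  AUC=0.974
  family NR=0.2  AUC=0.968
  family NR=0.4  AUC=0.954
  family NR=0.6  AUC=0.928
  family NR=0.8  AUC=0.817
  family NR=1.0  AUC=0.468
query AUC = 0.904
estimated noise ratio = 0.644  (injected 0.65)
```

The family AUC falls as more spikes are replaced by random timing; the
query cell's AUC of 0.904 sits between the 0.6 and 0.8 rungs and
interpolates to an estimated NR of 0.64, recovering the injected 0.65.

A complete small experiment — stimulus, population simulation, STAs and
selection, LN fits, noise ratios, decoding, report — runs from the shell:

```bash
retdecode demo --seed 0 --out demo_out
```

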