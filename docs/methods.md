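# Methods

This note records what the package computes, the assumptions behind the
synthetic retina used to validate it, the numerical conventions, and the
places where the design was genuinely open.

## Stimuli

White-noise movies are time-major `(T, H, W)` arrays of independent
Bernoulli pixels (bright probability 0.5 by default), presented at 30 Hz
with 60 µm pixels for visual stimulation and 20 Hz with 70 µm pixels for
subretinal electrical stimulation. Intensities live in [0, 1].

The Landolt C is rendered as a continuous figure before pixelization: a
ring whose stroke width and gap both equal 1/5 of the letter diameter
(Sloan/Landolt convention), rasterized at 16× supersampling, block-averaged
onto the stimulus grid and quantized to 8 evenly spaced grey levels (ties
round half-up). Keeping the gap continuous rather than rounding it to whole
pixels preserves the exact 1:5 gap-to-letter ratio at every size and
reproduces the physically important regime below 5 px, where the gap is not
resolved but encoded as an intermediate grey shade. The letter's bounding
box is snapped to the pixel grid (nearest-to-centre position), so a size-s
letter darkens exactly s pixel rows and columns; it stays at one position
for all five bright frames, after 19 dark frames. Within bright frames the
background sits at maximum intensity and the ring at minimum, with the gap
at background level; both levels are configurable, since the assignment of
"bright" between ring and background is a presentation choice.

## Synthetic retina

Ground-truth cells are space–time separable LN-Poisson units:

* spatial filter: difference of Gaussians (centre σ = 55 µm, surround
  σ = 110 µm, surround weight 0.25) — centre sizes in the range reported
  for rat RGCs at these pixel pitches;
* temporal filter: biphasic, peaking 2.5 frames before the spike with an
  opposing trough at 5.5 frames (visual); the electrical preset is faster
  (1.2 / 2.8 frames) with lower gain and a higher baseline, emulating the
  faster, weaker STAs seen under electrical stimulation;
* nonlinearity: rectifier `rate = gain · max(w·(s−0.5) − θ, 0) + baseline`,
  with unit-L2 kernel, gain 120 Hz per unit drive, θ = 0, baseline 2 Hz.
  These defaults give ~25 Hz mean rates on binary noise, so a 5–10 min
  synthetic recording yields the 5 000–15 000 spikes the estimators need.
  An OFF cell's kernel is the negated ON kernel. Spiking is Poisson per
  frame with uniform within-frame jitter; an optional absolute dead time
  (1.5 ms) exists so the contamination filter can be exercised, but is off
  by default.

Noise injection removes exactly `round(nr·N)` spikes uniformly at random
and adds `Poisson(removed)` spikes uniformly over the whole recording, so
the mean rate is preserved in expectation while the stimulus-locked STA
contrast scales by `1 − nr`. Replacement over the full duration is the
natural reading of a homogeneous "spontaneous" process.

Population presets mirror the two retina types studied: "LE" (healthy)
retinas draw their size from {49, 49, 21, 20} cells with a jittered-grid
mosaic over the field and a low spontaneous fraction (NR 0.1); "RCS"
(degenerate) retinas draw from {19, 14, 13, 9}, confine their RF centres to
a central implant-sized disc, and default to NR 0.78 — the mean noise level
estimated for degenerate retinas under electrical stimulation.

What the generator does *not* emulate: cell-type diversity beyond ON/OFF,
adaptation and history dependence, spike-sorting errors, correlated
(network) noise, and recording drift. Passing parameter-recovery tests
therefore shows the estimators are correct for LN-Poisson cells with
independent spontaneous contamination, not that real recordings satisfy
those assumptions.

## Preprocessing

Raw 20 kHz single-electrode traces are handled in three steps: (1) the
first 8.25 ms after each stimulation pulse is replaced with Gaussian noise
matched to the electrode's off-pulse level (robust MAD × 1.4826 scale,
centred at the off-pulse median); overlapping windows merge with a warning.
(2) A 7th-order polynomial is least-squares fit per inter-pulse segment,
excluding the blanked head, and subtracted; the blanked head is re-centred
by the fit's boundary value rather than by backward extrapolation, which
keeps detection invariant to constant offsets. The fit span is per-segment
by default and configurable. (3) Local negative minima below 3× the robust
RMS (about the median) are spikes; candidates within 1 ms merge, keeping
the deeper one.

Contamination is estimated as the observed fraction of inter-spike
intervals shorter than 1.5 ms divided by the fraction expected from a
rate-matched Poisson process, clipped to [0, 1]. This is a documented
convention chosen for testability: it scores 0 for a dead-time-respecting
cell and ≈ c for a fraction-c admixture of an independent refractory train.
Cells above 10 % contamination, or with STA time-course SNR below 3, are
excluded; SNR is |time-course peak| over the RMS of the 10 earliest lags
(the lags farthest from the spike) of the 24-frame window. The
axon-direction and electrophysiological-image exclusions used on real
arrays need full-array geometry and are represented by a no-op filter slot.

Polarity is the sign of the time-course lobe nearest the spike; under
electrical stimulation of the *healthy* retina the label is inverted
(anodic subretinal pulses depolarize photoreceptor terminals, acting like a
visual OFF step), while degenerate-retina electrical labels are reported as
measured.

## STA and crop conventions

The STA is the mean of the 24 stimulus frames up to and including the spike
frame; spikes without a full preceding window are skipped. The peak voxel
is the arg-max of |kernel − stimulus mean| with ties broken by earliest lag
then row-major order; the analysis crop is the (4 frame, 3 px, 3 px) box
around it, clipped to bounds. The time course defaults to the single peak
pixel (a 3×3 spatial average is available).

## Encoding models

The LN filter is the training-segment STA, mean-subtracted and denoised to
its best rank-1 space–time separable approximation (top SVD component) —
the standard cleanup for white-noise STAs, and necessary at desk-scale
spike counts, where raw per-voxel estimator noise over a 24×12×12 kernel
otherwise dominates. The nonlinearity uses 25 quantile bins of the filter
drive with linear interpolation and constant extrapolation. Train/test
segments are contiguous blocks from the recording start (20 % / 20 %, 60 %
discarded); drift handling is out of scope, so the split is fixed and
documented. The five-fold variant cuts the recording into equal fifths.

The CNN is implemented in numpy: two blocks of valid 2-D convolution
(stimulus frames as input channels) → parametric ReLU (learnable slope,
init 0.25) → channel-wise batch normalization (momentum 0.5) → dropout,
then flatten and a dense layer with a softplus output that keeps rates
positive for the Poisson likelihood. Training uses Adam on the Poisson
negative log-likelihood `R̂ − R log R̂` plus L2 on conv/dense weights and
L1 on the output. Thirteen hyperparameters (per-block filter count, size,
stride and rectifier slope; learning rate; L2; L1; batch size; dropout) are
exposed to a bounded random search (default 10 trials, log-uniform for the
rates), a desk-scale stand-in for a large managed search. Default
architectures: visual stimulation uses 8 filters of 13×13 then 16 of 9×9;
electrical uses 16 of 5×5 then 32 of 5×5. Tests use smaller configurations
sized to their synthetic movies.

Windowing: visual inputs are 20 consecutive frames (≈0.67 s at 30 Hz) with
the spike count of the following frame (33 ms) as target. Electrical movies
are up-sampled to 250 Hz by linear interpolation; windows span 5 original
frames and targets are 4 ms bins, with predictions averaged back into 50 ms
frames before scoring. Evaluation broadens both prediction and observed
counts with a Gaussian of σ = 2 frames (truncated at 4σ) and reports the
Pearson correlation; it is invariant to affine rescaling of the prediction
and returns NaN on zero-variance traces.

## Noise-ratio estimation

Partial STAs are accumulated with a prefix sum over chronologically ordered
spikes (O(N · crop) total) and the curve is evaluated on a logarithmic
subsample of at most 200 spike counts, always including n = N, where the
correlation is 1 by definition; a brute-force re-averaging oracle is kept
in the tests. The AUC trapezoid extends the curve from its smallest n/N to
zero with its first value (extension to 0 is switchable; applied uniformly
it does not affect matching). The reference cell is the one with median
AUC (lower median on even counts). Families average several injection
seeds per NR rung; matching interpolates linearly between the two
bracketing rungs (nearest-rung mode is available for strict replication),
and queries outside the family's AUC range clamp to the boundary with a
warning.

Two empirical caveats, both visible in the tests: the pure-noise √(n/N)
law holds for a *selection-independent* crop and sparse spikes — choosing
the crop at the peak of a signal-free STA conditions on a noise extremum
and inflates the curve, and dense trains (inter-spike spacing comparable to
the 4-frame crop span) share stimulus frames between windows and depress
it. The family's NR = 1 rung is therefore validated against a
matched-density random-train oracle rather than the ideal square root.

## Ensemble decoding

Matching is per cell: each cell's own mean-subtracted STA defines its
target strength `w·ŝ` (using the trailing 24 frames of the letter movie on
the cell's own stimulus grid) and its 500 best white-noise blocks, which
may overlap in time (stride 1; a disjoint option exists). Responses are the
30 ms after each block's end in 5 ms bins (6 bins/cell), averaged over
blocks and concatenated across cells. Trials are Poisson draws from the
true orientation's template; multiple flashes sum independent draws (the
combination rule is not dictated by the procedure; summing counts is the
Poisson-natural choice). Decoding is arg-max Pearson correlation over the
four templates, with exact ties — and zero-variance trials — broken
uniformly at random from the trial's seed stream. Raw count vectors are
correlated (rate normalization is a trivial rescale and does not change
correlations).

Experiment axes: cell count (cells added in rank order of independent
single-cell accuracy, letter fixed at 14 px), letter size, and flash count,
with 10 000 trials of uniformly random orientations by default. Every grid
point consumes a named substream of the experiment seed and is
independently reproducible.

The acceptance-level size experiment uses four independent 20-cell model
retinas under prosthetic-level noise (NR 0.55) on a 20×20 field with the
letter interior to the canvas, 3 000 trials per size, and treats retinas as
replicates when testing the plateau slope — the appropriate error term,
since mosaic realization dominates the retina-to-retina variation. The
cells-versus-flashes comparison contrasts a 49-cell NR 0.1 retina with a
10-cell NR 0.78 retina on a geometric flash grid. Problem sizes throughout
(5–10 min movies, 12–20 px fields) were chosen as the smallest at which the
estimators are comfortably converged.

## Pipeline

`run_pipeline` executes requested stages in dependency order, derives one
deterministic substream per stage from the master seed (SHA-256 of
`seed:stage`, reduced below 2³¹), and writes a manifest with config echo,
per-stage seeds and timings, and SHA-256 hashes of every artifact; rerunning
an identical config reproduces identical hashes for all non-CNN stages.
Spike trains interchange as CSV `(cell_id, spike_time_s)`, arrays as HDF5.

## Known limitations

* The CNN trains on CPU at desk scale; reproducing full-scale fitted
  weights or GPU-scale searches is out of scope.
* Recorded-data quantities (population correlation levels, recorded-retina
  noise ratios, exact accuracy curves) require the original recordings and
  are not reproduced; the package validates the *estimators* by parameter
  recovery on the synthetic retina instead.
* The decoder assumes translational symmetry (fixed letter position, no eye
  movements) and ignores stimulus correlations absent from white noise.
* Spike sorting proper (clustering, electrophysiological images, axonal
  trajectories) is replaced by single-electrode threshold detection plus a
  contamination statistic.
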