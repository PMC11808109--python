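# Methods

## The system being modeled

In an optical time-stretch (OTS) imaging flow cytometer, each broadband
laser pulse illuminates one cross-flow line of the microfluidic channel.
The line's spatial profile is encoded in the pulse spectrum, the
spectrum is stretched in time by a dispersive element, and a single
fast photodetector reads the line out serially: one pulse = one 64-pixel
image line covering a 30 µm cross-flow field of view. Cells flowing past
the line at speed `v` are rebuilt as 2-D images by stacking consecutive
lines; the along-flow row pitch is `v / f_rep` per pulse (0.0125 µm at
1 m/s with `f_rep = 80 MHz`), times the skip factor after decimation.

The digitizer runs at `f_s = 10.24 GS/s` (four interleaved ADCs), i.e.
128 samples per pulse period, of which a 64-sample window (duty ≤ 1/2)
carries the image line at 16-bit depth. The raw output, `2 f_s` bytes/s
≈ 20 GB/s, must be reduced below the sustained host-link rate
(5.6 GB/s) in real time. `otstream` reproduces that reduction chain in
software and verifies its arithmetic and its information loss.

## Processing chain

1. **Block averaging.** Samples arrive as 32-sample blocks; the
   per-pulse window mean (AOP, "average of pulse") is computed by a
   balanced pairwise summation tree with integer partial sums, so it
   equals the exact arithmetic mean (`block_average`).
2. **Baseline and trigger.** The first `calibration_pulses` (default
   64) are assumed cell-free; their AOP mean initializes a background
   baseline and their per-pixel mean gives the line background. The
   baseline then follows non-triggered pulses by an exponential moving
   average with `alpha = 1/256`; triggered pulses freeze it so cells do
   not drag it down. A pulse triggers when the AOP falls at least
   `threshold` below the baseline (ties trigger). The default threshold
   is `max(8 · 1.4826 · MAD(calibration AOP), 1)` count — eight robust
   standard deviations of the calibration noise, floored at one LSB so
   noise-free streams remain triggerable. Triggered runs are extended by
   `guard_pulses` (default 2) on each side and runs separated by at most
   `merge_gap` (default 2) pulses are merged. A `large_window` mode
   instead cuts fixed multi-cell windows (default 1600 pulses ≈ 20 µs)
   for dense samples and counts threshold-crossing runs per window.
3. **Line formation.** Synchronous clock: line *i* is samples
   `[128 i + 32, 128 i + 96)` — two 32-sample blocks at a fixed window
   phase. Asynchronous clock (sample clock off by `offset_ppm`): a
   3-block, 96-sample region is captured around the predicted window
   position and the window is re-aligned to the first sample crossing
   the pulse amplitude threshold (default `full_scale / 4`), tracking
   the drift pulse by pulse.
4. **Reduction.** Per-pixel background subtraction and 16→8-bit
   requantization: `pixel' = clip(round((bg − pixel) · 2^gain_shift /
   256), 0, 255)`. Stored images are absorbance-positive (cell bright on
   a zero background). Decimation keeps the first line of each group of
   `skip`, phase reset at each ROI start, so `ceil(n / skip)` lines
   survive.
5. **Framing.** Each ROI's decimated lines are packed into frames of
   exactly `n_seg` rows (default `ceil(fov_flow · f_rep / (v · skip))`
   with `fov_flow = 30 µm`); remainders are zero-padded (`padded` flag),
   long ROIs split (`split` flag). Constant frame size is the storage
   contract.
6. **Morphometry.** From the 8-bit frame: binary mask, area
   `A = Σ B(x,y)`, equivalent circular diameter
   `d = 2 √(A · pitch_cross · pitch_flow / π)` (pixels are anisotropic:
   `pitch_cross = fov_cross / 64`, `pitch_flow = v · skip / f_rep`),
   opacity `I_total = Σ I·B`, and granularity `G = k (N_x + N_y)` where
   `N_x`/`N_y` count inflection points of the masked mean-intensity
   profiles along each axis. The default header mask is a fixed
   threshold at 1 count (any absorbing pixel belongs to the cell),
   which emulates the hardware's single-threshold masking and keeps the
   recovered diameter faithful to the full object footprint; Otsu is
   available for noisy data, but on a smoothly tapered object it cuts
   mid-taper and systematically under-sizes by ~10 %.

## Rate accounting conventions

All byte rates use MiB = 2^20 bytes; this is the unique convention that
reproduces the 4888.3 (full 80.09 MHz pulse stream × 64 px × 8 bit),
4000 (40,960 fps × 1600 pulses × 64 px) and 366/732 MiB/s figures
simultaneously. Two pulses-per-image modes coexist: `exact`
(`fov · f_rep / (v · skip)`, used in rate arithmetic, e.g. 37.5 at the
853-fold reduction point) and `ceil` (used by frame assembly — a
segment cannot hold a fractional row, hence 38). The data-reduction
proportion multiplies four retained fractions — window duty (≤ 1/2),
trigger occupancy, 8/16 bit fold, and 1/skip — and is checked against
the 18/25 minimum required for sustained transfer. Motion blur is
handled analytically as `v × 5.5 ns` exposure displacement, reported
absolutely and as a fraction of the 780 nm optical resolution; it is
not simulated within a pulse.

## Image quality metrics

SSIM is the standard luminance/contrast/structure product over sliding
Gaussian-weighted local windows (window 7, sigma 1.5, k1 = 0.01,
k2 = 0.03, population statistics, edges cropped). VIF is implemented in
the pixel domain (four dyadic scales, Gaussian windows of
`2^(4−s+1)+1` taps with sigma = width/5, neural-noise variance 2): per
scale the distorted image is modeled locally as gain × reference +
noise, and VIF is the ratio of summed `log10` channel informations;
`vif(x, x) = 1` by construction. The wavelet-domain VIF variant is not
provided. Skip-factor curves decimate the skip-1 reference by `k` and
restore the row count by nearest-row replication — deliberately not
interpolation, so the curve isolates the information removed by
decimation.

## Synthetic phantoms: what they do and do not represent

Scenes are 2-D transmittance maps in [0, 1] on an isotropic grid
(default 0.2 µm) with exact ground truth. Cells are cosine-tapered
absorbing disks (full absorbance out to 0.8 R, cosine to zero at R, peak
absorbance default 0.5) — the taper avoids hard-edge aliasing and gives
bright-field-like smooth objects; an optional band-limited multiplicative
speckle (grain ≈ 2 sigma of the smoothing kernel) provides nonzero
granularity ground truth. Populations place objects along the flow axis
with exponential edge-to-edge gaps; an optional hard-core minimum gap
(shifted exponential) emulates the coincidence-free spacing of a sample
diluted for single-cell imaging. Bar targets provide alternating
opaque/clear lines at exactly half duty for resolution checks.

The phantoms are stand-ins, not biophysical models: no point-spread
function, no refractive/phase effects, no 3-D structure, no detector
bandwidth limits, and vertical sampling is a nearest-row lookup (row i
spans `[i, i+1) · pitch`) with no interpolation or intra-pulse blur.
Passing tests therefore demonstrate the correctness of the *data path* —
triggering, reduction, framing, feature arithmetic, formats — under
controlled inputs, not imaging performance on real cells.

All randomness derives from one integer seed per generator call through
counter-based splitting (`SeedSequence([seed, counter])`), so identical
calls are byte-identical and adding draws never perturbs earlier ones.

## Numerical and format choices

- Trigger tie at threshold triggers (`>=`); trigger statistic is the
  deviation below the EMA baseline (the instrument's "temporal
  difference" detection is not formalized; this stand-in matches the
  amplitude-difference principle).
- Requantization divides by 256 with a configurable `gain_shift` rather
  than adaptive scaling — bit-exact and hardware-faithful.
- Inflection points are strict sign changes of the second finite
  difference after a 3-point moving average (edge-replicated); zero runs
  are skipped. Mean curves are masked means over the mask bounding box;
  empty rows/columns are dropped.
- Segments are little-endian: magic `OTS1`, u32 frame index, u64 start
  pulse, u16 skip / rows / pixels / flags, u16 size×100, u16
  granularity×100, u32 opacity — a 32-byte header, then `n_seg × 64`
  payload bytes; constant length per file, magic checked at every
  boundary, read order restored by frame index. The buffered store is a
  correctness contract (bounded FIFO queue, multiple consumers, block or
  counted-drop overflow), not a performance emulation.

## Problem sizes

The test suite and the acceptance script use a 100-object, 8 µm phantom
stream at 10 m/s (~48 k pulses, ~6 M samples), a single 12 µm phantom at
2.4 m/s for size recovery and quality curves, and closed-form rate
checks; the whole suite runs in seconds on one CPU.

## Known limitations

- Asynchronous re-alignment assumes the first window pixels stay above
  the amplitude threshold (true while cells do not fill the full
  cross-flow FOV) and that clock drift per pulse is small against the
  16-sample search margin.
- Fast-axis (within-pulse) triggering is out of scope; events are
  triggered on the slow axis only.
- The group-vote classifier ships with a logistic aggregate-feature
  scorer as a placeholder; any per-group callable (e.g. a CNN) can be
  plugged in. No claim is made about clinical classification
  performance.
- Header fixed-point fields cap size at 655.35 µm and granularity at
  655.35; far beyond any single-cell value.
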