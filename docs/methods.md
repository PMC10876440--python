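# Methods

This note records the models implemented in `ciliakit`, the defaults and
why they were chosen, the numerical decisions that were genuinely open, and
what the synthetic-data tests do and do not demonstrate about real
recordings.

## Synthetic IFT movies

`simulate_ift_movie` renders bidirectional IFT trains on a straight 1D
ciliary track. Anterograde trains enter at the base and move tip-ward at a
fixed speed; retrograde trains enter at the tip and move base-ward. When a
retrograde train crosses an anterograde one it pauses with probability
`pause_prob`; anterograde trains never pause. Each train is a boxcar of its
length convolved with a Gaussian PSF (closed form via the error function),
placed on a Gaussian transverse profile; Poisson photon noise and optional
Gaussian read noise are applied last. Ground truth records every train's
per-frame position, its pause events, and every encounter with its outcome.

Defaults and their rationale:

- frame interval 0.12 s — the live-imaging cadence of the recordings the
  generator emulates (120 ms between frames);
- pixel size 0.13 um/px — live-imaging pixel size is not printed in the
  source protocol (only the fixed-imaging 80–200 nm range is); 0.13 um is
  a typical spinning-disc value and is configurable;
- speeds 0.22 / 1.2 um/s and mean lengths 358 / 237 nm (SD 60 nm) for the
  anterograde / retrograde populations — the measured study values;
- pause probability 0.76 — the measured fraction of retrograde trains that
  pause on encountering an anterograde train;
- pause duration 1.2 s — no characteristic duration is reported; 10 frames
  makes a pause clearly resolvable at the frame rate while staying short
  against a 4 s retrograde transit. It is a free parameter;
- injection rates 0.06 / 0.08 trains/s — not reported; chosen so a 60 s
  movie carries a handful of trains per direction, the density the study's
  example kymographs show;
- photon budget: `photons_per_train` (2000) is the expected count for a
  train of the mean anterograde length, and each train's brightness scales
  linearly with its length — fluorophore content follows the number of IFT
  particles, so the longer anterograde trains are brighter in total (as the
  recordings show) while every train has the same brightness per unit
  length; with the default background of 20 counts the peak SNR is ~8–10.

The path is planar and straight; there is no photobleaching and no 3D
geometry. Trains never merge or split. These simplifications mean the
recovery tests certify the analysis chain (kymograph, Fourier separation,
tracking, statistics) against a known kinematic model — they do not certify
robustness to curved cilia, focus drift, or motile backgrounds in real
movies.

## Kymograph analysis

`build_kymograph` samples the movie along the ciliary path at 1 px arc
spacing, taking the maximum over a 3 px transverse band (maximum rather
than mean preserves dim trains). Arc coordinate 0 is the base; anterograde
means increasing arc coordinate.

`separate_directions` removes the static component as the per-column
temporal median, then splits the remainder by 2D Fourier quadrant
filtering: a rightward-moving feature occupies the half-plane
sign(f_t)·sign(f_s) < 0, a leftward-moving one the opposite pair, and the
zero-frequency and Nyquist lines (directionless) are split evenly so that a
space-axis flip swaps the two outputs exactly. The array is reflect-padded
to twice its size before Hann windowing so the data sit in the window's
well-conditioned centre; without the padding, dividing the filtered result
by the window amplifies the rows and columns near the image edge and
manufactures spurious static streaks there. Negative values are clipped
after the inverse transform. The three components sum to the input (before
clipping) by construction.

`extract_tracks` thresholds each directional kymograph at its mean +
2 SD and takes 8-connected components. Three pruning rules keep artefacts
out:

1. *dominance*: a component must average at least half of the opposite
   direction's local-maximum intensity over its own pixels. The quadrant
   filter leaks ringing sidelobes of a bright streak into the
   wrong-direction kymograph, slightly displaced from the streak; genuine
   trains pass this test, displaced ringing does not;
2. *size*: components under 8 px are discarded before linking;
3. *coverage*: a finished track must have samples in at least half the
   frames it spans — speckle chains stitched across gaps are sparse,
   whereas real trains are visible nearly every frame, pauses included.

Components are linked across gaps of up to 20 frames when the next
fragment either continues in place (a pause) or along the fragment's own
velocity (an occlusion), never backwards along the travel direction.
Per-frame positions are intensity-weighted centroids (midpoint on an exact
plateau), smoothed with a 5-sample running median.

*Stalls.* The directional reconstruction of a paused sub-resolution train
is not perfectly stationary: the filter renders it as slowed motion
drifting at ~0.15–0.2 um/s. A fixed low threshold therefore cannot detect
pauses on fast tracks, and the stall criterion is adaptive: an inter-sample
speed (central difference over ±1 sample) counts as stalled when below
max(0.05 um/s, 0.25 × the track's own travel speed), with runs of at least
3 frames kept. Travel speed and stall set are co-estimated by a short
fixed-point iteration, seeded from the upper quartile of window speeds so
that a pause-laden track's low chord slope cannot hide its own pauses.

*Velocity.* Least absolute deviations (LAD) fit, Nelder–Mead on the sum of
absolute residuals seeded from least squares. Samples inside stalls are
excluded, and each contiguous moving segment is fitted separately; the
track speed is the duration-weighted median of segment slopes. A single
line through pause-separated segments would return the chord slope — the
average including pauses — which underestimates the speed while moving by
tens of percent on pause-rich retrograde tracks.

*Train length.* Per sampled frame, the FWHM of the background-subtracted
(row-median) spatial profile through the track position, found by linear
interpolation inside a 20 px window; frames whose profile never falls below
half maximum are skipped, and the per-frame widths are averaged. Whether
the manual "thickness" measurements the analysis mirrors correspond to
FWHM or to full visible extent is not documented; FWHM is the reproducible
choice and is monotone in the true length at fixed PSF, which is what the
recovery tests certify.

*Encounters.* Retro–antero track pairs are interpolated onto common
frames; a sign change of their separation (or a near-touch within 2 px)
defines one event at the interpolated crossing. Crossings at a track's
first or last sample, or involving tracks spanning under 10 frames, are
rejected — truncated stubs at the movie and cilium boundaries otherwise
produce spurious events. The outcome is *pause* when a stall overlaps the
crossing within ±(2 + 4) frames — the 4-frame widening absorbs the
systematic onset delay of stall detection — or when the retrograde track
locally moves at less than half its travel speed in the ±5 frames around
the crossing (this catches pauses whose stall run fell below the
minimum-length cut). Both printed velocities being medians or means is not
documented; `summarize_trains` reports both.

With these settings, synthetic recovery at the study conditions returns
per-direction median velocities within 2% of truth, ≥ 95% of a single
train's energy in the correct directional kymograph, and encounter pause
fractions within the binomial 95% CI of truth for pause probabilities
0.25–0.76 (about 200 encounters per setting, pooled over ~30 one-minute
movies). Residual biases of a few percent remain at high pause loads:
physically superimposed trains are unresolvable, and a crossing drags the
centroid of the through-going train for a few frames.

## Antennal mechanics

`simulate_thermal_trace` integrates the underdamped Langevin equation
m·x'' = −Ks·x − γ·x' + a·F_th(t) with Ks = m(2πf0)², γ = m·2πf0/Q and
one-sided thermal force PSD 4γkBT, scaled by the active factor a
(fluctuation energy scales as a²; a = 1 is a passive receiver in
equilibrium). The integrator is semi-implicit (symplectic) Euler at
dt = 1/(50·f0) — implemented as the equivalent linear recursion via
`scipy.signal.lfilter`, so a 60 s trace costs milliseconds — then decimated
to the output rate (≥ 20·f0 enforced). At the default settings the sample
variance matches the equipartition value kBT/Ks within ~1%.

`displacement_psd` uses Welch's method (Hann window, 50% overlap, segment
length chosen for ≤ 2 Hz resolution with ≥ 8 averaged segments); velocity
traces are converted to displacement in the spectral domain (division by
ω², f = 0 excluded). The analysis band defaults to 100–1500 Hz.

`fit_sho` fits log-PSD with uniform weights (balancing the decades of
dynamic range on and off resonance) for (F0, f0, Q), initialized from the
band argmax and the half-power width; Ks and γ are derived. Mass defaults
to 50 ng; temperature defaults to 298 K (not stated in the protocol).

*Fluctuation energy.* E = Ks·⟨X²⟩ in kB·T units with
kB = 1.380649e-23 J/K, equivalently (Ks/K)·kBT with the effective
stiffness K = kBT/⟨X²⟩. ⟨X²⟩ is the trapezoid integral of the *measured*
PSD over the analysis band, extrapolated to the full spectrum by the
fitted model's band coverage (the fraction of the model's total variance
inside the band, ~0.88 at f0 = 300 Hz, Q = 2). The correction matters: the
raw band integral underestimates ⟨X²⟩ by the missing low-frequency plateau
and would bias a passive receiver's energy to ~0.89 kBT, breaking the
equipartition identity the estimator exists to test. The uncorrected
in-band value and the fitted model's full integral are both reported
alongside for comparison. The energy is reported in kBT units (the natural
scale for the equipartition comparison).

`gain_curve` is exact arithmetic: gain = displacement·2πf_eigen/SPV per
level, sensitivity = gain_max/gain_min. The forced-response generator
interpolates the gain sigmoidally on log-SPV between gain_max and gain_min
over the default 17-level, 96 dB ladder (6 dB steps), with the sigmoid
width set so the sweep ends saturate within 0.3%.

## Intensity quantification

The marker channel is segmented by Otsu threshold and 26-connected
components (minimum 30 voxels); target intensity is averaged per region,
then per volume (per antenna), then normalized to the *median* of the
control group of the same batch — the summary statistic for the control is
not documented in the protocol being mirrored, and the median is the robust
choice. Group comparison is the two-sided Mann–Whitney U test: exact null
distribution when both groups have ≤ 8 untied values, normal approximation
with tie correction otherwise (`scipy.stats.mannwhitneyu`); the test suite
checks it against a brute-force enumeration oracle for group sizes ≤ 6.
Dilation positivity uses background mean + 2 SD (the factor is not
documented; 2 SD is the conventional detection limit). The bending angle
is measured between the principal axes (SVD) of the dendrite and cilium
point sets, folded to [0°, 90°] as deviation from collinear continuation —
the reference axis convention is not documented.

The volume generator lays cilium-like 3×L×3-voxel regions on a jittered
grid with ≥ 2 empty planes between rows (so 26-connectivity cannot merge
them), gives the knockdown group a (1 − reduction) target level, and adds
per-volume lognormal staining variability (CV 4%, a plausible
between-antenna repeatability after batch normalization) plus voxel noise.
At 9% reduction and n = 10 volumes per group, the normalized knockdown
median recovers 0.91 and the Mann–Whitney test flags the difference —
which certifies the quantification chain, not the biological effect size.

## Orchestration and determinism

Every generator consumes a single integer seed; the pipeline expands its
global seed into independent per-stage streams (inserting a stage does not
perturb the others). All CSV output is comma-separated, '.'-decimal, UTF-8
with a header row; movies travel as ImageJ-compatible TIFF with calibration
metadata (explicit arguments override metadata on read). Each run writes a
manifest listing every output file with its SHA-256; identical
configuration and seed reproduce identical tables. Floating-point movie
data are written as float32 (the ImageJ TIFF format has no float64);
integer data round-trip losslessly.

## Problem sizes

The test suite and the acceptance script use one-minute 500-frame movies
(9×~60 px), 60 s mechanics traces at 6 kHz, and 16×48×48-voxel volumes;
pause statistics pool ~200 encounters per setting from ~30 movies. These
sizes give the recovery statistics quoted above while keeping a full run
in the minutes range on a single core.

## Known limitations

- Physically superimposed trains (same direction, near-simultaneous entry)
  are recovered as one track; their encounters and pauses are partially
  ambiguous even in principle.
- The pause/pass classifier inherits a small (few percent) bias from
  crossing-induced centroid drag; it is within the binomial CI at the
  tested settings but not zero.
- Train length is reported as measured FWHM, i.e., convolution-widened;
  no PSF deconvolution is attempted.
- The SHO fit assumes a single resonance in the band; receivers with
  secondary modes will need a restricted band.
- Mann–Whitney exact p-values are not computed in the presence of ties
  (the tie-corrected normal approximation is used instead).
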