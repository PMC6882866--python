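# Methods

## Signal model and MUA estimate

The raw input is the unfiltered field potential (UFP, µV) of each electrode,
sampled at ~5 kHz for at least several minutes.  Multi-unit activity is
estimated spectrally: the 200–1500 Hz content of the extracellular signal
scales with the aggregate spiking of cells near the electrode tip, while the
Down-state residual in that band reflects only the acquisition chain.  The
estimate is

    MUA(t) = mean_{f_lo <= f <= f_hi}  PSD(t, f) / median_t' PSD(t', f)

with the per-frequency median taken over the whole session.  Because the
median is robust to the (minority of) high-power Up windows, it tracks the
noise floor, and the MUA is a dimensionless ratio: invariant under gain
changes, with log(MUA) < 0 meaning below-median spectral content.

Spectrogram settings: 5 ms windows (25 samples at 5 kHz), **non-overlapping**
(a 200 Hz MUA rate), **rectangular** taper — tapering a 25-sample window
costs bandwidth for no practical variance gain; a Hann option exists.  The
window mean is removed before the FFT so that high-amplitude low-frequency
content (the LFP itself, or drifts) does not leak into the 200–1500 Hz band
through the short window.  With these defaults the in-band bins are 200,
400, …, 1400 Hz: m = 7 bins, DC and Nyquist excluded.  The trailing partial
window is discarded.  Hop, taper and band are configurable.

For state-independent white noise the in-band periodogram bins are i.i.d.
exponential, so MUA is Gamma(m)-distributed up to scale and the Down-state
log(MUA) width is exactly `sqrt(trigamma(m))` (0.3918 for m = 7).  The
synthetic generator and the recovery tests use this closed form.

## Down-peak fit, tail, alerts, threshold

The log(MUA) histogram uses Freedman–Diaconis bin widths with a 50-bin
floor, normalized to unit area.  The Down peak is fitted with a single
Gaussian by nonlinear least squares, restricted to the **peak core**: bins
within [center − 1.5·s, center + 1·s], where the initial center is the
histogram mode and s is a robust width (the 68% quantile of the left-flank
deviations, mirrored); the fit is iterated twice with the window recentred
on the fitted parameters.  Two deliberate choices:

- the **+1·s right cap** keeps the Up-state tail out of the fit;
- the **−1.5·s left cap** (rather than a long left window) matters because
  the Down-state log(MUA) is mildly left-skewed (log of a band-averaged
  power); fitting far down the left flank inflates the width estimate by
  3–5%, while the core window recovers the analytic width of pure-noise
  channels to within ~1% (measured on generator channels where
  `sqrt(trigamma(m))` is the truth).

The **tail** is the positive excess of the histogram over the fitted
Gaussian, renormalized into a distribution; its mass (tail area), third
standardized moment (skewness γ), mean/median/mode feed the alert battery:
weak bimodality (tail area < 10%), positive/negative skewness (γ beyond
±1), right peak (histogram mode above the midpoint of the central 98% range
with the tail mean below the fitted center), large threshold (threshold
above the tail mean), few transitions (< 3).  Right peak, few transitions
and a failed fit are blocking; the rest are recorded notes.  A
two-Gaussian mixture fit is deliberately not used: across channels the
high-rate regime takes many shapes and is treated as a generic tail.

The state threshold is `mu + k*sigma` of the fitted peak with k = 2 — a
fixed one-sided false-positive rate per bin of `1 − Φ(2) ≈ 2.28%` — or a
fixed level by configuration.

## Binarization, debounce, trigger times

`log(MUA) > threshold` gives the binary state sequence.  The k = 2 design
implies ~2.3% of genuine Down bins exceed the threshold *by construction*;
with independent 5 ms windows that is several spurious crossings per second.
The pipeline therefore applies a minimum-state-length debounce of 4 bins
(20 ms) by default: an order of magnitude below physiological state
durations (~0.1–2 s), it suppresses isolated exceedances (probability
~0.023^4 per bin) without touching real states.  The primitive itself
defaults to no debounce; the operating value is a pipeline-level setting
and every merge is reflected in the binary sequence it returns.

Each surviving 0↔1 boundary is refined below the bin width by fitting a
cubic through the four log(MUA) samples bracketing the crossing and solving
it for the threshold inside the central interval (nearest root to the
interval midpoint; ties take the earlier time).  Boundaries within one bin
of the recording edge fall back to linear interpolation.  First and last
(incomplete) states are excluded from all duration statistics.  States
spanning a discontinuity stitch are flagged.

## Observables

- Durations from consecutive trigger times; a UD cycle is a Down state plus
  its following Up state, so each `d_UD` decomposes exactly.  Medians
  represent channels (the distributions are strongly skewed).
- Transition-triggered average waveforms: snippets aligned at the MUA bin
  nearest `t0` (no sub-bin resampling — the 5 ms grid already bounds the
  alignment error), with mean/SD/SEM per time point.
- Front slopes: cubic least squares on the average **log(MUA)** waveform
  over [−25, +10] ms (downward) or [−10, +25] ms (upward) around `t0`;
  the slope is the derivative at `t0`.  Whether slopes should be taken on
  log or linear MUA is genuinely open; log is the default and a linear
  option exists via the waveform `signal` argument.
- Peak MUA `p`: maximum of the average **linear** MUA waveform in
  (t0, t0 + 250 ms] after the upward transition (flagged if the window is
  truncated).
- Channel frequency `f = 1/mean(d_UD)` (the arithmetic-mean convention;
  per-cycle `1/d_UD` values remain available through the duration lists).

## Stability screen and exclusions

Fitted sigmas are pooled across channels and sessions (pooling, not
per-session fencing, is the default — the screen exists to enforce a
comparable acquisition chain across the whole collection).  Quartiles use
linearly interpolated order statistics ("type 7"; configurable, since
borderline fence membership depends on the estimator).  Only the **upper**
fence `Q3 + 1.5·IQR` excludes: a too-wide peak means a noisy channel, while
an unusually narrow one is merely noted.  The exclusion ledger combines
stability outliers with blocking-alert channels, with deterministic
reasons; weak bimodality and discontinuities are notes, not exclusions.
A reference ledger for an 11-session, 32-channel benchmark acquisition
(15 session-level exclusions plus 12 stability-screen outliers, 27 total)
is bundled for bookkeeping tests.

## Statistics

Per-subject area values are medians of the pooled retained-channel values
(durations pool all cycles of the area's channels).  Because
between-subject variability dominates area effects, each subject's values
are divided by the arithmetic mean across its areas before subjects are
combined; the mean of normalized values is exactly 1 per subject.  The
normalization factor of a sign-carrying observable (the downward slope) is
negative; dividing through preserves the identity, and only a zero factor
is an error.

Pairwise comparisons use the two-sided Wilcoxon rank-sum test: exact null
enumeration when both groups have ≤ 10 observations and no ties, otherwise
the normal approximation with midranks, tie-corrected variance and
continuity correction.  Each observable's matrix is one Benjamini–Hochberg
family (10 area pairs; up to 496 electrode pairs).  Electrode-level
inter-session tests compare across-subject normalized samples per electrode
pair; pairs with fewer than 4 subjects on either side are undefined and
excluded from the family.  Core nodes are the three electrodes with the
most `p_adj < alpha` partners; ties break toward the lower electrode index
so reports are deterministic.

## Maps

The mesh grid spans the electrode bounding box with 50×90 steps; on the
bundled layout (6×10 positions at a 0.550 mm step) the grid step is
0.055 mm = array step / 10.  The default interpolator is piecewise-linear
on the Delaunay triangulation of the retained electrodes: node-exact, no
overshoot beyond the input range, masked outside the convex hull.  A
thin-plate RBF option gives smoother contours at the price of those
guarantees.  Excluded electrodes take no part in the interpolation and are
exported for open-marker rendering.  Marker sizes are inversely
proportional to the across-subject SD at the electrode, affinely clipped
into bounds (`sd = 0` → maximal marker): a large marker means a consistent
value across subjects.  (Descriptions of this convention sometimes state
the opposite mapping; this package implements strict inverse
proportionality.)

## Synthetic sessions

The generator emulates exactly the features the detector relies on:

- a two-state semi-Markov sequence with lognormal dwell times (skewed,
  positive; exponential available), defaults `d_Down` median 0.6 s and
  `d_Up` median 0.4 s, shape 0.4 — Down-dominant (the fit targets the
  dominant low-rate peak) and ~0.9 Hz slow-oscillation frequency, as under
  deep anesthesia;
- white Gaussian noise whose SD follows the state: 5 µV (Down) vs 15 µV
  (Up), an in-band power contrast of 9 — comfortably separable so that
  recovery tests measure algorithmic error, not borderline SNR;
- sigmoidal fronts: the binary state is convolved with a logistic-derivative
  kernel of steepness 4/τ (τ = 10 ms ≈ the 10–90% rise time), applied to
  the noise SD; the kernel is symmetric, so the **true transition time is
  exactly the front midpoint** — the detector's target;
- optional per-area multipliers on the Down-duration median (planted
  spatial gradients), planted flat drop-outs, and per-channel RNG
  substreams spawned from the session seed (bit-reproducible sessions).

What the generator does *not* emulate: 1/f background and LFP content,
spike waveforms, temporal correlation of the in-band power within a state,
travelling-wave timing offsets between channels, and non-stationarity.
Passing recovery tests therefore demonstrates correctness of the estimator
chain under the stated noise model, not robustness to every property of in
vivo data.  One visible consequence: the synthetic Up-state tail is
left-skewed (log of a band-averaged power plus front smearing), so the
negative-skewness *note* fires on most synthetic channels, whereas in vivo
tails typically skew right.

Typical problem sizes in the tests and the acceptance script — 32 channels
× 60 s per session, 11 subjects for the inter-session studies — give every
channel ~50–60 complete cycles, enough for 5%-level recovery of medians
while keeping a full run in tens of seconds.

## Numerical details and degenerate inputs

- Histogram fit requires ≥ 20 non-empty bins; non-convergence marks the
  channel blocked rather than raising.
- Cubic root finding uses the centered polynomial; a boundary with no real
  root in the bracket (possible only through numerics) falls back to
  linear interpolation.
- Flat-run excision: runs of |Δx| ≤ tol (default exactly 0 µV) lasting
  ≥ 0.2 s; retained samples are never altered; reports keep the original
  clock while analysis runs on the stitched clock.
- All-identical map values produce a constant map; fewer than 3 retained
  electrodes, or a collinear layout, are errors.
- Wilcoxon pairs with a group of < 2 values (or < 4 subjects at the
  electrode level) are NaN and excluded from the BH family.

## Known limitations

- The MUA estimator assumes a stationary noise floor per channel; slow gain
  drift biases the median baseline.
- The debounce bound trades a small blindness to genuine < 20 ms states for
  robustness of the duration statistics; channels whose dynamics are that
  fast need a different operating point.
- Front slopes from a cubic over a fixed 35 ms window underestimate
  derivative magnitudes when the true rise is much faster than the window.
- Area-level tests use one value per subject per area (n = number of
  subjects); pooling channels instead would change the effective n and is
  intentionally not done.
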