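# slowwave

Detection and spatial statistics of cortical **slow oscillations** (Up/Down
states, ≲1 Hz) from multi-electrode extracellular recordings.

Under deep anesthesia and NREM sleep the cortical network alternates between
**Up** states (high multi-unit firing) and **Down** states (near-quiescence).
`slowwave` takes raw, unfiltered field-potential traces (e.g. 32-channel
micro-ECoG sampled at 5 kHz), estimates multi-unit activity (MUA) per
channel, detects the state alternation, extracts state/transition
observables, screens channels for stability, and compares cortical areas
and electrode sites statistically — including interpolated cortical maps of
each observable.  It is aimed at systems neurophysiologists who want a
reproducible raw-data-to-statistics path for slow-wave activity, and at
modellers who need the same observables from simulated traces.  A bundled,
ground-truthed synthetic-session generator makes the whole pipeline testable
without any real recording.

## Method

Per channel, with signal `x(t)` sampled at `fs`:

1. **Spectrogram** over 5 ms moving windows (non-overlapping by default).
2. **Median baseline**: for each frequency bin `f`, the median over all
   windows of PSD(t, f) estimates the acquisition noise floor.
3. **MUA**: `MUA(t) = mean over f in [200, 1500] Hz of PSD(t, f) / baseline(f)`;
   the band-mean of the median-normalized power is a proxy for the collective
   firing rate around the electrode tip.  `log(MUA)` maps Down states to a
   narrow peak and Up states to a positive tail.
4. **Peak fit**: a Gaussian `N(mu, sigma^2)` is fitted to the Down-state peak
   of the log(MUA) histogram; the excess over the fit is the Up-state
   **tail** (mass, skewness, location).
5. **Alerts**: weak bimodality (tail < 10%), tail skewness beyond ±1,
   right-shifted peak, large threshold, fewer than 3 transitions.  Blocking
   alerts exclude the channel.
6. **Threshold & binarization**: `UD_THRESHOLD = mu + 2*sigma` (≈2.3%
   false-positive rate per bin); `log(MUA) > threshold` defines the binary
   state sequence.
7. **Transitions**: each threshold crossing is refined below the 5 ms bin by
   a local cubic through the four bracketing samples, giving the trigger
   time `t0`.
8. **Observables**: state durations `d_Down`, `d_Up`, the Down-then-Up cycle
   `d_UD` (median per channel — the distributions are skewed), front slopes
   `s_Up`, `s_Down` (cubic fit over 35 ms around `t0`), peak MUA `p` in the
   first 250 ms of the Up state, and frequency `f = 1/⟨d_UD⟩`.

Across channels and subjects: fitted `sigma` values are pooled and channels
beyond `Q3 + 1.5·IQR` are excluded; per subject each observable is
normalized by its across-area mean; areas and electrode pairs are compared
with the two-sided Wilcoxon rank-sum test, Benjamini–Hochberg corrected per
matrix; the three electrodes with the most significant partners are the
**core nodes**; per-electrode values are interpolated onto a 50×90 mesh grid
(step = array step / 10) for contour maps.

## Worked example

```python
from slowwave import (PipelineConfig, SynthConfig, default_geometry,
                      generate_session, run_single_session)

geom = default_geometry()                      # bundled 32-electrode layout
rec, truth = generate_session(SynthConfig(duration=60.0, seed=1), geom,
                              session_id="demo")
res = run_single_session(rec, geom, PipelineConfig())
print(f"usable channels: {len(res.usable_channels)}/{len(res.channels)}")
r = res.channels["1"]
print(f"channel 1: mu={r.fit.mu:.3f}, sigma={r.fit.sigma:.3f}, "
      f"threshold={r.threshold:.3f}, tail area={r.fit.tail_area:.2f}, "
      f"{r.seq.n_transitions} transitions")
print(res.observable_table()[["channel", "median_d_down", "median_d_up",
                              "median_d_ud", "f"]].head(3).round(3))
```

prints

```
usable channels: 32/32
channel 1: mu=-0.421, sigma=0.394, threshold=0.367, tail area=0.46, 111 transitions
channel  median_d_down  median_d_up  median_d_ud     f
      1          0.525        0.470        1.050 0.927
      2          0.568        0.373        1.034 0.972
      3          0.581        0.333        0.978 0.988
```

The fitted Down-peak width (0.394) matches the analytic width of the
generator's Down-state noise (`sqrt(trigamma(7)) ≈ 0.392` for the 7 in-band
frequency bins), the threshold sits 2σ above the peak, and the recovered
cycle medians (~1.0 s, `f` ≈ 0.93 Hz) match the planted duration
distributions.

The same workflow is available from the shell:

```sh
slowwave simulate --out s1.h5 --duration 60 --seed 5 --session-id s1
slowwave analyze s1.h5 --out-dir a1
slowwave summary a1/session.pkl a2/session.pkl --out-dir summ
slowwave map summ/summary.pkl --observable d_ud --out map.csv
```

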