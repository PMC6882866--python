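"""Multi-unit activity (MUA) estimation from the raw field potential.

The MUA proxy for the collective firing rate r(t) around an electrode is the
high-frequency content of the unfiltered field potential: a spectrogram is
computed over short moving windows (5 ms by default), each per-frequency
power value is normalized by the session-wide median of that frequency bin,
and the MUA at a window is the mean of the normalized power over the
200-1500 Hz band.  Its natural logarithm maps Down (quiescent) states to a
narrow peak and Up (active) states to a positive tail, which is what the
detection stage thresholds.

Because of the median normalization the MUA is dimensionless: log(MUA) < 0
means spectral content below the session median, > 0 above it, and the
estimate is invariant under rescaling of the raw voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass
class SpectrogramConfig:
    """Settings of the moving-window spectral estimate.

    window_s: window length in seconds (5 ms default, 25 samples at 5 kHz).
    band: (f_lo, f_hi) in Hz, bins with f_lo <= f <= f_hi enter the MUA.
    taper: "rect" (default; tapering is costly in bandwidth for 25-sample
        windows) or "hann".
    hop_s: hop between windows; None means non-overlapping (hop = window).
    """

    window_s: float = 0.005
    band: tuple[float, float] = (200.0, 1500.0)
    taper: str = "rect"
    hop_s: float | None = None

    def validate(self, fs: float) -> None:
        f_lo, f_hi = self.band
        if not (0 < f_lo < f_hi <= fs / 2):
            raise ValueError(f"band {self.band} outside (0, fs/2] for fs={fs}")
        if round(self.window_s * fs) < 2:
            raise ValueError("window shorter than 2 samples")
        if self.taper not in ("rect", "hann"):
            raise ValueError(f"unknown taper {self.taper!r}")


@dataclass
class MUATrace:
    """Per-channel MUA time series at the spectrogram window rate."""

    t: np.ndarray          # window-center times (s)
    mua: np.ndarray        # dimensionless band-mean of normalized PSD
    log_mua: np.ndarray    # natural log of mua
    baseline: np.ndarray   # median PSD per frequency bin (whole session)
    freqs: np.ndarray      # Hz
    band: tuple[float, float] = (200.0, 1500.0)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.t))) if len(self.t) > 1 else np.nan


def compute_spectrogram(
    signal: np.ndarray, fs: float, cfg: SpectrogramConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moving-window power spectral density of a raw trace.

    Returns (times, freqs, psd) with one PSD row per window; the trailing
    partial window is discarded.
    """
    cfg = cfg or SpectrogramConfig()
    cfg.validate(fs)
    nperseg = int(round(cfg.window_s * fs))
    if len(signal) < nperseg:
        raise ValueError(f"signal ({len(signal)} samples) shorter than one window ({nperseg})")
    hop = nperseg if cfg.hop_s is None else int(round(cfg.hop_s * fs))
    window = "boxcar" if cfg.taper == "rect" else "hann"
    freqs, times, psd = sps.spectrogram(
        np.asarray(signal, dtype=np.float64),
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=nperseg - hop,
        detrend="constant",  # window-mean removal stops low-frequency leakage
        scaling="density",
        mode="psd",
    )
    return times, freqs, psd.T.copy()


def compute_baseline(psd: np.ndarray) -> np.ndarray:
    """Per-frequency median of the PSD over all windows of the session.

    The median (midpoint convention for even counts) is robust to the Up
    states' excess power, so it tracks the acquisition-chain noise floor.
    """
    psd = np.asarray(psd)
    if psd.ndim != 2 or psd.shape[0] < 1:
        raise ValueError("psd must be a (n_windows, n_freqs) matrix with >= 1 window")
    return np.median(psd, axis=0)


def band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    f_lo, f_hi = band
    return (freqs >= f_lo) & (freqs <= f_hi)


def compute_mua(
    psd: np.ndarray,
    baseline: np.ndarray,
    band: tuple[float, float],
    times: np.ndarray,
    freqs: np.ndarray,
) -> MUATrace:
    """Band-mean of the median-normalized PSD, and its natural log."""
    mask = band_mask(freqs, band)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    bad = np.flatnonzero(mask & (baseline <= 0))
    if bad.size:
        raise ValueError(
            f"zero/negative baseline at in-band bin(s) {freqs[bad].tolist()} Hz "
            "(degenerate channel)"
        )
    mua = np.mean(psd[:, mask] / baseline[mask], axis=1)
    return MUATrace(
        t=np.asarray(times, dtype=float),
        mua=mua,
        log_mua=np.log(mua),
        baseline=np.asarray(baseline, dtype=float),
        freqs=np.asarray(freqs, dtype=float),
        band=band,
    )


def mua_trace(signal: np.ndarray, fs: float, cfg: SpectrogramConfig | None = None) -> MUATrace:
    """Full MUA estimate for one channel: spectrogram, median baseline, band mean."""
    cfg = cfg or SpectrogramConfig()
    times, freqs, psd = compute_spectrogram(signal, fs, cfg)
    baseline = compute_baseline(psd)
    return compute_mua(psd, baseline, cfg.band, times, freqs)


def bandpass_trace(signal: np.ndarray, fs: float, band: tuple[float, float] = (200.0, 1500.0), order: int = 4) -> np.ndarray:
    """Band-passed field potential, for display next to the MUA (not used in detection)."""
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64))
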