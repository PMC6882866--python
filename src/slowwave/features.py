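"""State and transition observables of one channel.

From the transition list of a channel the module derives: state durations
(Down, Up, and the Down-then-Up cycle whose duration estimates the slow
oscillation period), transition-triggered average waveforms, cubic front
fits whose derivative at the trigger time gives the transition slope, the
maximum MUA shortly after the upward transition ("peak"), and the channel
summary used by the area-level statistics.  Durations are represented by
their median because the per-channel distributions are strongly skewed;
the channel frequency is 1/mean(d_UD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import DOWNWARD, UPWARD, StateSequence
from .mua import MUATrace

#: cubic-fit windows around the trigger time, seconds relative to t0
FRONT_WINDOWS = {
    DOWNWARD: (-0.025, 0.010),
    UPWARD: (-0.010, 0.025),
}


@dataclass
class DurationSet:
    """Per-channel lists of Down, Up and UD-cycle durations (seconds)."""

    d_down: np.ndarray
    d_up: np.ndarray
    d_ud: np.ndarray


@dataclass
class TransitionWaveform:
    """Aligned snippets around transitions of one direction, plus summaries."""

    direction: str
    rel_t: np.ndarray        # time relative to t0 (s), shared grid
    snippets: np.ndarray     # (n, len(rel_t))
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray
    n: int
    n_dropped: int = 0       # transitions whose window fell off the recording


@dataclass
class FrontFit:
    """Cubic fit of the average transition front; slope is d/dt at t0."""

    direction: str
    window: tuple[float, float]
    coeffs: np.ndarray       # np.polyfit order (highest power first)
    slope_at_t0: float


@dataclass
class ChannelSummary:
    channel: str
    median_d_down: float
    median_d_up: float
    median_d_ud: float
    s_up: float
    s_down: float
    p: float                 # max MUA after the upward transition (a.u.)
    f: float                 # 1 / mean(d_ud), Hz


def compute_durations(seq: StateSequence) -> DurationSet:
    """State durations from consecutive trigger times (complete states only).

    The first and last states lack one boundary and are always dropped; a
    UD cycle is a Down state followed by its Up state, so each cycle
    duration is exactly the sum of its two constituents.
    """
    if seq.n_transitions < 3:
        raise ValueError(f"need >= 3 transitions, got {seq.n_transitions}")
    t = np.array([tt for tt, _ in seq.transitions])
    dirs = [d for _, d in seq.transitions]
    gaps = np.diff(t)
    d_down, d_up, d_ud = [], [], []
    for k, g in enumerate(gaps):
        # state between transitions k and k+1 is Down iff entered downward
        if dirs[k] == DOWNWARD:
            d_down.append(g)
            if k + 1 < len(gaps):  # its Up partner completes the cycle
                d_ud.append(g + gaps[k + 1])
        else:
            d_up.append(g)
    return DurationSet(
        d_down=np.asarray(d_down), d_up=np.asarray(d_up), d_ud=np.asarray(d_ud)
    )


def average_waveform(
    trace: MUATrace,
    seq: StateSequence,
    direction: str,
    window: tuple[float, float] = (0.25, 0.30),
    signal: str = "log",
) -> TransitionWaveform:
    """Transition-triggered average of the MUA around t0.

    Snippets are aligned on the MUA grid at the bin nearest each trigger
    time (the 5 ms bins already bound the residual timing error); windows
    extending beyond the recording are dropped and counted.  ``signal``
    selects log(MUA) (front/slope analysis) or linear MUA (peak analysis).
    """
    y = trace.log_mua if signal == "log" else trace.mua
    dt = trace.dt
    pre, post = window
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    rel_t = np.arange(-n_pre, n_post + 1) * dt
    t0s = seq.times(direction)
    if t0s.size == 0:
        raise ValueError(f"no {direction} transitions")
    snippets = []
    dropped = 0
    for t0 in t0s:
        c = int(round((t0 - trace.t[0]) / dt))
        if c - n_pre < 0 or c + n_post >= len(y):
            dropped += 1
            continue
        snippets.append(y[c - n_pre : c + n_post + 1])
    if not snippets:
        raise ValueError("zero usable snippets (all windows off the recording)")
    snippets = np.asarray(snippets)
    mean = snippets.mean(axis=0)
    sd = snippets.std(axis=0, ddof=1) if len(snippets) > 1 else np.zeros_like(mean)
    sem = sd / np.sqrt(len(snippets))
    return TransitionWaveform(
        direction=direction, rel_t=rel_t, snippets=snippets,
        mean=mean, sd=sd, sem=sem, n=len(snippets), n_dropped=dropped,
    )


def fit_front_slope(wf: TransitionWaveform, window: tuple[float, float] | None = None) -> FrontFit:
    """Cubic least-squares fit of the average front; slope = derivative at t0.

    Default windows: [-25, +10] ms for downward fronts, [-10, +25] ms for
    upward fronts (35 ms around the trigger time).
    """
    window = window or FRONT_WINDOWS[wf.direction]
    lo, hi = window
    sel = (wf.rel_t >= lo - 1e-12) & (wf.rel_t <= hi + 1e-12)
    if sel.sum() < 4:
        raise ValueError(f"fewer than 4 waveform points inside the fit window {window}")
    coeffs = np.polyfit(wf.rel_t[sel], wf.mean[sel], 3)
    slope = float(np.polyval(np.polyder(coeffs), 0.0))
    return FrontFit(direction=wf.direction, window=window, coeffs=coeffs, slope_at_t0=slope)


def compute_peak_mua(wf_up: TransitionWaveform, span_s: float = 0.250) -> tuple[float, bool]:
    """Maximum of the average (linear-MUA) waveform in (t0, t0 + span].

    Returns (peak, truncated); ``truncated`` is True when the waveform's
    post-trigger span is shorter than requested and the maximum was taken
    on the available part.
    """
    sel = (wf_up.rel_t > 0) & (wf_up.rel_t <= span_s + 1e-12)
    if not sel.any():
        raise ValueError("no waveform samples after the trigger time")
    truncated = wf_up.rel_t[-1] < span_s - 1e-12
    return float(np.max(wf_up.mean[sel])), truncated


def summarize_channel(
    channel: str,
    durations: DurationSet,
    front_up: FrontFit,
    front_down: FrontFit,
    peak: float,
) -> ChannelSummary:
    """Per-channel observable summary: duration medians, slopes, peak, frequency."""
    if len(durations.d_ud) == 0:
        raise ValueError("no complete UD cycles")
    return ChannelSummary(
        channel=channel,
        median_d_down=float(np.median(durations.d_down)),
        median_d_up=float(np.median(durations.d_up)),
        median_d_ud=float(np.median(durations.d_ud)),
        s_up=front_up.slope_at_t0,
        s_down=front_down.slope_at_t0,
        p=peak,
        f=float(1.0 / np.mean(durations.d_ud)),
    )
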