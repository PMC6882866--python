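"""Ground-truthed synthetic sessions for end-to-end pipeline testing.

Each channel is a two-state semi-Markov process: Down and Up dwell times
are drawn from lognormal distributions (skewed and strictly positive, as
the measured duration distributions are), and the raw 5 kHz trace is
white Gaussian noise whose standard deviation follows the state
(sigma_down in Down, sigma_up in Up), with a sigmoidal cross-fade of
time-constant tau at every transition.  Since the MUA estimate is the
band-mean of the normalized power, the in-band power contrast between
states is (sigma_up/sigma_down)^2, and for white noise the Down-state
log(MUA) width is analytically sqrt(trigamma(m)) with m in-band bins —
which makes every downstream recovery test quantitative.

The true transition time of every front is the midpoint of the cross-fade
(the detector's target); the ground-truth ledger records all interior
transition times, directions and state durations exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import polygamma

from .detection import DOWNWARD, UPWARD
from .io import ArrayGeometry, Recording


@dataclass
class SynthConfig:
    """Study conditions of a synthetic session.

    Durations are lognormal: ``*_median`` is the distribution median in
    seconds and ``*_shape`` the log-scale SD.  ``tau`` is the front
    cross-fade time constant (~10-90% rise time).  ``area_down_multipliers``
    scales the Down-duration median per cortical area to plant spatial
    gradients.  ``discontinuities`` lists (start_s, end_s) intervals
    overwritten with a flat value, emulating acquisition drop-outs.
    """

    fs: float = 5000.0
    duration: float = 60.0
    down_median: float = 0.6
    down_shape: float = 0.4
    up_median: float = 0.4
    up_shape: float = 0.4
    sigma_down: float = 5.0      # uV
    sigma_up: float = 15.0       # uV
    tau: float = 0.01            # s
    duration_dist: str = "lognormal"   # or "exponential"
    area_down_multipliers: dict[str, float] = field(default_factory=dict)
    discontinuities: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not (self.sigma_up > self.sigma_down > 0):
            raise ValueError("need sigma_up > sigma_down > 0")
        if min(self.down_median, self.up_median) <= 0:
            raise ValueError("duration medians must be positive")
        if self.duration_dist not in ("lognormal", "exponential"):
            raise ValueError(f"unknown duration distribution {self.duration_dist!r}")


@dataclass
class GroundTruth:
    """Exact transition times/directions and state durations per channel."""

    transitions: dict[str, list[tuple[float, str]]]
    durations: dict[str, dict[str, np.ndarray]]     # channel -> {d_down, d_up, d_ud}
    params: dict[str, dict] = field(default_factory=dict)

    def times(self, channel: str, direction: str | None = None) -> np.ndarray:
        return np.array(
            [t for t, d in self.transitions[channel] if direction is None or d == direction]
        )


def expected_log_mua_width(n_band_bins: int = 7) -> float:
    """Analytic Down-state log(MUA) SD for white noise: sqrt(trigamma(m))."""
    return float(np.sqrt(polygamma(1, n_band_bins)))


def _draw_durations(rng: np.random.Generator, median: float, shape: float, n: int, dist: str) -> np.ndarray:
    if dist == "exponential":
        return rng.exponential(scale=median / np.log(2), size=n)
    return rng.lognormal(mean=np.log(median), sigma=shape, size=n)


def _state_boundaries(cfg: SynthConfig, rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    """Alternating state boundary times covering the session, starting Down."""
    mean_cycle = cfg.down_median + cfg.up_median
    n_guess = int(np.ceil(cfg.duration / mean_cycle * 2)) + 8
    downs = _draw_durations(rng, cfg.down_median, cfg.down_shape, n_guess, cfg.duration_dist)
    ups = _draw_durations(rng, cfg.up_median, cfg.up_shape, n_guess, cfg.duration_dist)
    durs = np.empty(2 * n_guess)
    durs[0::2] = downs
    durs[1::2] = ups
    while durs.sum() < cfg.duration:
        extra_d = _draw_durations(rng, cfg.down_median, cfg.down_shape, n_guess, cfg.duration_dist)
        extra_u = _draw_durations(rng, cfg.up_median, cfg.up_shape, n_guess, cfg.duration_dist)
        extra = np.empty(2 * n_guess)
        extra[0::2] = extra_d
        extra[1::2] = extra_u
        durs = np.r_[durs, extra]
    bounds = np.cumsum(durs)
    keep = bounds < cfg.duration
    bounds = bounds[keep]
    # state entered at boundary k: Up for even k (Down->Up), Down for odd
    directions = [UPWARD if k % 2 == 0 else DOWNWARD for k in range(len(bounds))]
    return bounds, directions


def _front_kernel(tau: float, fs: float) -> np.ndarray:
    """Normalized logistic-derivative kernel; steepness 4/tau (10-90% ~ 1.1*tau)."""
    a = 4.0 / tau
    half = int(np.ceil(3 * tau * fs))
    t = np.arange(-half, half + 1) / fs
    k = a * np.exp(-a * t) / (1 + np.exp(-a * t)) ** 2
    return k / k.sum()


def generate_channel(cfg: SynthConfig, rng: np.random.Generator | None = None) -> tuple[np.ndarray, GroundTruth]:
    """One synthetic raw voltage trace plus its exact truth ledger."""
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.seed)
    if cfg.duration < 2 * (cfg.down_median + cfg.up_median):
        import warnings

        warnings.warn("session shorter than two mean cycles; few transitions expected")
    n = int(round(cfg.duration * cfg.fs))
    bounds, directions = _state_boundaries(cfg, rng)

    # binary state per sample (1 = Up); session starts Down
    state = np.zeros(n, dtype=float)
    idx = np.round(bounds * cfg.fs).astype(int)
    interior = (idx > 0) & (idx < n)  # a boundary snapping to an edge is not a transition
    idx = idx[interior]
    directions = [d for d, keep in zip(directions, interior) if keep]
    for k in range(len(idx)):
        lo = idx[k]
        hi = idx[k + 1] if k + 1 < len(idx) else n
        if directions[k] == UPWARD:
            state[lo:hi] = 1.0
    # smooth fronts: convolve with a symmetric kernel so the cross-fade
    # midpoint sits exactly at the boundary time
    if cfg.tau > 0:
        pad = len(_front_kernel(cfg.tau, cfg.fs)) // 2
        padded = np.r_[np.full(pad, state[0]), state, np.full(pad, state[-1])]
        g = fftconvolve(padded, _front_kernel(cfg.tau, cfg.fs), mode="same")[pad:-pad]
    else:
        g = state
    sd = cfg.sigma_down + (cfg.sigma_up - cfg.sigma_down) * g
    trace = rng.standard_normal(n) * sd

    for s, e in cfg.discontinuities:
        trace[int(round(s * cfg.fs)) : int(round(e * cfg.fs))] = 0.0

    # truth: interior transitions at snapped boundary times, alternating
    t_true = idx / cfg.fs
    transitions = [(float(t), d) for t, d in zip(t_true, directions)]
    durations = _truth_durations(transitions)
    truth = GroundTruth(
        transitions={"0": transitions},
        durations={"0": durations},
        params={"0": {"config": cfg}},
    )
    return trace, truth


def _truth_durations(transitions: list[tuple[float, str]]) -> dict[str, np.ndarray]:
    t = np.array([tt for tt, _ in transitions])
    dirs = [d for _, d in transitions]
    gaps = np.diff(t)
    d_down, d_up, d_ud = [], [], []
    for k, g in enumerate(gaps):
        if dirs[k] == DOWNWARD:
            d_down.append(g)
            if k + 1 < len(gaps):
                d_ud.append(g + gaps[k + 1])
        else:
            d_up.append(g)
    return {
        "d_down": np.asarray(d_down),
        "d_up": np.asarray(d_up),
        "d_ud": np.asarray(d_ud),
    }


def generate_session(
    cfg: SynthConfig, geometry: ArrayGeometry, session_id: str = "synth"
) -> tuple[Recording, GroundTruth]:
    """One synthetic channel per electrode, with per-area duration multipliers.

    Each channel uses an independent substream spawned from the session
    seed, so single channels are reproducible and the whole session is
    bit-identical under the same config and seed.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(len(geometry.electrodes))
    signals: dict[str, np.ndarray] = {}
    transitions: dict[str, list[tuple[float, str]]] = {}
    durations: dict[str, dict[str, np.ndarray]] = {}
    params: dict[str, dict] = {}
    for child, eid in zip(children, geometry.electrodes):
        area = geometry.areas[eid]
        mult = cfg.area_down_multipliers.get(area, 1.0)
        ch_cfg = replace(cfg, down_median=cfg.down_median * mult, area_down_multipliers={})
        rng = np.random.default_rng(child)
        trace, truth = generate_channel(ch_cfg, rng)
        signals[eid] = trace
        transitions[eid] = truth.transitions["0"]
        durations[eid] = truth.durations["0"]
        params[eid] = {"area": area, "down_median": ch_cfg.down_median, "config": ch_cfg}
    rec = Recording(session_id=session_id, fs=cfg.fs, signals=signals)
    return rec, GroundTruth(transitions=transitions, durations=durations, params=params)
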