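"""Up/Down state detection from the log(MUA) distribution.

The log(MUA) histogram of a channel expressing slow-wave activity is
bimodal: a dominant narrow peak at low values (Down states, where the
residual power reflects only the acquisition chain) and a broad tail at
high values (Up states).  Rather than a two-Gaussian mixture, the method
fits a single Gaussian to the Down peak and treats everything in excess of
it as a generic "tail": the tail mass, its skewness and its location drive
a battery of quality alerts, and the state threshold (UD threshold) is
placed at mu + k*sigma of the fitted peak (k = 2 by default, i.e. a fixed
one-sided false-positive rate of ~2.3% per channel).

Binarizing log(MUA) against the threshold yields the state sequence; each
transition time is then refined below the bin width by solving a local
cubic through the four MUA samples bracketing the threshold crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

UPWARD = "upward"      # Down -> Up
DOWNWARD = "downward"  # Up -> Down


@dataclass
class PeakFit:
    """Gaussian fit of the Down-state peak plus tail statistics."""

    mu: float
    sigma: float
    amp: float
    converged: bool
    tail_area: float            # fraction of total distribution mass
    tail_skewness: float        # third standardized moment of the tail
    tail_mean: float
    tail_median: float
    tail_mode: float
    # histogram bookkeeping (density-normalized), kept for alerts and audit
    bin_centers: np.ndarray | None = None
    density: np.ndarray | None = None
    data_q01: float = np.nan
    data_q99: float = np.nan
    peak_mode: float = np.nan
    n_samples: int = 0


@dataclass
class AlertSet:
    """Channel-quality alerts derived from the fit and the threshold.

    weak_bimodality: tail mass < 10% of the distribution.
    positive_skewness / negative_skewness: tail skewness beyond +-1.
    right_peak: the dominant peak sits on the right of the range with the
        tail on its left (no Down state identifiable).
    large_threshold: threshold beyond the mean of the tail.
    few_transitions: fewer than 3 transitions (cannot isolate one Up and
        one Down state).
    Blocking alerts (right_peak, few_transitions, failed fit) stop the
    channel; the others are recorded as notes.
    """

    weak_bimodality: bool = False
    positive_skewness: bool = False
    negative_skewness: bool = False
    right_peak: bool = False
    large_threshold: bool = False
    few_transitions: bool = False
    fit_failed: bool = False

    @property
    def blocking(self) -> bool:
        return self.few_transitions or self.right_peak or self.fit_failed

    def active(self) -> list[str]:
        return [k for k, v in self.__dict__.items() if v]


@dataclass
class ThresholdPolicy:
    """How the UD threshold is chosen: mu + k*sigma (default k=2) or fixed."""

    mode: str = "k_sigma"
    k: float = 2.0
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("k_sigma", "fixed"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "k_sigma" and self.k <= 0:
            raise ValueError("k must be positive in k_sigma mode")
        if self.mode == "fixed" and self.fixed_value is None:
            raise ValueError("fixed mode requires fixed_value")


@dataclass
class StateSequence:
    """Binary Up/Down labelling with sub-bin transition times."""

    binary: np.ndarray
    transitions: list[tuple[float, str]]     # (t0 seconds, direction)
    threshold: float
    complete_states_only: bool = True
    stitch_flags: list[bool] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def times(self, direction: str | None = None) -> np.ndarray:
        return np.array([t for t, d in self.transitions if direction is None or d == direction])


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def histogram_density(values: np.ndarray, min_bin_floor: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Freedman-Diaconis histogram with a bin-count floor, unit-area normalized."""
    values = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(values, [75, 25])
    span = values.max() - values.min()
    fd_width = 2.0 * (q75 - q25) / max(len(values), 1) ** (1 / 3)
    if fd_width <= 0 or span / fd_width < min_bin_floor:
        n_bins = min_bin_floor
    else:
        n_bins = int(np.ceil(span / fd_width))
    density, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def _robust_left_width(values: np.ndarray, mode: float) -> float:
    """Half-width of the peak from the left flank: 68% quantile of (mode - x)+.

    The right flank is contaminated by the Up-state tail, so the width
    estimate mirrors the left flank only.
    """
    d = mode - values[values <= mode]
    if d.size < 2:
        return np.nan
    w = float(np.quantile(d, 0.68))
    return w if w > 0 else np.nan


def fit_down_peak(log_mua: np.ndarray, min_bins: int = 20, min_bin_floor: int = 50) -> PeakFit:
    """Fit a Gaussian to the Down-state peak of the log(MUA) distribution.

    The fit is restricted to bins in [mode - 3*s, mode + 1*s] around the
    histogram mode (s = robust left-flank width), iterated twice with the
    region recentred on the fitted parameters; the asymmetric window keeps
    the tail-contaminated right flank out of the fit.  The tail is the
    positive excess of the histogram over the fitted Gaussian, renormalized
    into a distribution from which mass, skewness and location statistics
    are computed.
    """
    log_mua = np.asarray(log_mua, dtype=float)
    log_mua = log_mua[np.isfinite(log_mua)]
    if log_mua.size == 0:
        raise ValueError("empty log(MUA) input")
    centers, density = histogram_density(log_mua, min_bin_floor=min_bin_floor)
    if np.count_nonzero(density) < min_bins:
        raise ValueError(
            f"histogram has {np.count_nonzero(density)} non-empty bins; "
            f"need >= {min_bins}"
        )
    bw = centers[1] - centers[0]
    mode = float(centers[np.argmax(density)])
    q01, q99 = np.percentile(log_mua, [1, 99])

    s_hat = _robust_left_width(log_mua, mode)
    if not np.isfinite(s_hat):
        s_hat = float(np.std(log_mua)) or bw

    params = None
    mu_c, s_c = mode, s_hat
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        for _ in range(2):
            # fit only the peak core: the right flank is contaminated by the
            # Up tail, and a long left window biases sigma upward when the
            # Down distribution is mildly left-skewed (log of band-averaged
            # power), so the window is [-1.5, +1] robust widths off center
            sel = (centers >= mu_c - 1.5 * s_c) & (centers <= mu_c + 1 * s_c)
            if sel.sum() < 4:
                sel = np.abs(centers - mu_c) <= max(2 * s_c, 2 * bw)
            try:
                params, _ = curve_fit(
                    _gauss,
                    centers[sel],
                    density[sel],
                    p0=(density.max(), mu_c, s_c),
                    maxfev=10000,
                )
            except (RuntimeError, ValueError):
                params = None
                break
            amp, mu_c, s_c = params[0], params[1], abs(params[2])
            if s_c <= 0 or not np.isfinite(s_c):
                params = None
                break

    if params is None or abs(params[2]) <= 0:
        return PeakFit(
            mu=np.nan, sigma=np.nan, amp=np.nan, converged=False,
            tail_area=np.nan, tail_skewness=np.nan, tail_mean=np.nan,
            tail_median=np.nan, tail_mode=np.nan,
            bin_centers=centers, density=density,
            data_q01=q01, data_q99=q99, peak_mode=mode, n_samples=log_mua.size,
        )

    amp, mu, sigma = float(params[0]), float(params[1]), float(abs(params[2]))
    tail = np.clip(density - _gauss(centers, amp, mu, sigma), 0.0, None)
    tail_area = float(np.sum(tail) * bw)  # density integrates to 1
    if tail_area > 0:
        w = tail / tail.sum()
        t_mean = float(np.sum(w * centers))
        var = float(np.sum(w * (centers - t_mean) ** 2))
        if var > 0:
            skew = float(np.sum(w * (centers - t_mean) ** 3) / var ** 1.5)
        else:
            skew = 0.0
        cw = np.cumsum(w)
        t_median = float(centers[np.searchsorted(cw, 0.5)])
        t_mode = float(centers[np.argmax(tail)])
    else:
        t_mean = t_median = t_mode = np.nan
        skew = np.nan

    return PeakFit(
        mu=mu, sigma=sigma, amp=amp, converged=True,
        tail_area=min(tail_area, 1.0), tail_skewness=skew,
        tail_mean=t_mean, tail_median=t_median, tail_mode=t_mode,
        bin_centers=centers, density=density,
        data_q01=q01, data_q99=q99, peak_mode=mode, n_samples=log_mua.size,
    )


def evaluate_alerts(
    fit: PeakFit,
    threshold: float | None,
    n_transitions: int | None,
    weak_bimodality_area: float = 0.10,
    skewness_limit: float = 1.0,
    min_transitions: int = 3,
) -> AlertSet:
    """Evaluate the channel-quality alert battery.

    ``threshold`` / ``n_transitions`` may be None when a blocking fit
    failure prevented their computation; the corresponding alerts are then
    left unset and only distribution-shape flags are evaluated.
    """
    a = AlertSet()
    if not fit.converged:
        a.fit_failed = True
        return a
    if np.isfinite(fit.tail_area):
        a.weak_bimodality = fit.tail_area < weak_bimodality_area
    if np.isfinite(fit.tail_skewness):
        a.positive_skewness = fit.tail_skewness > skewness_limit
        a.negative_skewness = fit.tail_skewness < -skewness_limit
    # peak on the right of the occupied range, with the tail mass below it
    midpoint = 0.5 * (fit.data_q01 + fit.data_q99)
    a.right_peak = bool(
        fit.peak_mode > midpoint
        and np.isfinite(fit.tail_mean)
        and fit.tail_mean < fit.mu
    )
    if threshold is not None and np.isfinite(fit.tail_mean):
        a.large_threshold = threshold > fit.tail_mean
    if n_transitions is not None:
        a.few_transitions = n_transitions < min_transitions
    return a


def select_threshold(fit: PeakFit, policy: ThresholdPolicy | None = None) -> float:
    """UD threshold from the Down-peak fit: mu + k*sigma, or a fixed level."""
    policy = policy or ThresholdPolicy()
    if policy.mode == "fixed":
        return float(policy.fixed_value)
    if not fit.converged:
        raise ValueError("k_sigma threshold requires a converged Down-peak fit")
    return float(fit.mu + policy.k * fit.sigma)


def binarize_mua(log_mua: np.ndarray, threshold: float, min_state_bins: int = 0) -> np.ndarray:
    """Binary state sequence: 1 where log(MUA) > threshold, else 0.

    ``min_state_bins`` > 0 applies a debounce: runs shorter than the
    minimum are merged into the preceding state (forward pass).
    """
    binary = (np.asarray(log_mua) > threshold).astype(np.int8)
    if min_state_bins > 0 and binary.size:
        binary = _debounce(binary, min_state_bins)
    return binary


def _debounce(binary: np.ndarray, min_bins: int) -> np.ndarray:
    out = binary.copy()
    i = 0
    n = len(out)
    while i < n:
        j = i
        while j < n and out[j] == out[i]:
            j += 1
        if i > 0 and (j - i) < min_bins:
            out[i:j] = out[i - 1]
        i = j if j > i else i + 1
    return out


def _cubic_crossing(t4: np.ndarray, y4: np.ndarray, threshold: float, t_lo: float, t_hi: float) -> float | None:
    """Threshold crossing of the cubic through 4 points, inside [t_lo, t_hi]."""
    # center times for conditioning
    tc = t4 - t4[0]
    coeffs = np.polyfit(tc, y4 - threshold, 3)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real + t4[0]
    inside = real[(real >= t_lo - 1e-12) & (real <= t_hi + 1e-12)]
    if inside.size == 0:
        return None
    mid = 0.5 * (t_lo + t_hi)
    # nearest to the discrete crossing midpoint; tie -> earlier time
    order = np.lexsort((inside, np.abs(inside - mid)))
    return float(inside[order[0]])


def detect_transitions(
    log_mua: np.ndarray,
    times: np.ndarray,
    binary: np.ndarray,
    threshold: float,
    stitch_times: list[float] | None = None,
) -> StateSequence:
    """Locate state transitions with sub-bin (cubic-interpolated) times.

    For every 0<->1 boundary of the binary sequence a local cubic through
    the four log(MUA) samples bracketing the crossing is solved for the
    threshold level; boundaries too close to the edges fall back to linear
    interpolation.  Transitions alternate strictly by construction.
    """
    log_mua = np.asarray(log_mua, dtype=float)
    times = np.asarray(times, dtype=float)
    binary = np.asarray(binary)
    if len(log_mua) != len(times) or len(binary) != len(times):
        raise ValueError("log_mua, times and binary must have equal length")
    bounds = np.flatnonzero(np.diff(binary) != 0)
    transitions: list[tuple[float, str]] = []
    for i in bounds:
        direction = UPWARD if binary[i + 1] == 1 else DOWNWARD
        t_lo, t_hi = times[i], times[i + 1]
        t0 = None
        if 1 <= i <= len(times) - 3:
            t0 = _cubic_crossing(times[i - 1 : i + 3], log_mua[i - 1 : i + 3], threshold, t_lo, t_hi)
        if t0 is None:
            # linear interpolation between the two straddling samples
            y0, y1 = log_mua[i], log_mua[i + 1]
            frac = 0.5 if y1 == y0 else (threshold - y0) / (y1 - y0)
            t0 = float(t_lo + np.clip(frac, 0.0, 1.0) * (t_hi - t_lo))
        transitions.append((t0, direction))
    transitions.sort(key=lambda td: td[0])
    flags = []
    if stitch_times:
        st = np.asarray(stitch_times)
        for k, (t0, _) in enumerate(transitions):
            prev = transitions[k - 1][0] if k > 0 else -np.inf
            flags.append(bool(np.any((st > prev) & (st <= t0))))
    return StateSequence(
        binary=binary,
        transitions=transitions,
        threshold=float(threshold),
        stitch_flags=flags,
    )
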