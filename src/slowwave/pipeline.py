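"""End-to-end orchestration: single-session analysis and multi-session summary.

``run_single_session`` loops over the channels of one recording: excise
flat acquisition drop-outs, estimate the MUA, fit the Down peak, set the
threshold, evaluate the alert battery, binarize, locate transitions and
compute the per-channel observables.  Channels hitting a blocking alert
carry their reason and no features.

``run_summary`` combines sessions: pooled peak-width stability screen,
exclusion ledger, area aggregation, per-subject normalization, rank-sum/BH
matrices at the area and at the electrode level, core-node ranking and
map-ready tables.  Everything is deterministic given inputs and config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detection, features, maps, qc, stats
from .config import PipelineConfig
from .io import ArrayGeometry, Recording, excise_discontinuities, find_flat_runs, stitch_times
from .mua import MUATrace, mua_trace

#: observables summarized per channel; duration-like ones carry distributions
OBSERVABLES = ("d_down", "d_up", "d_ud", "s_up", "s_down", "p", "f")
DURATION_OBSERVABLES = ("d_down", "d_up", "d_ud")


@dataclass
class ChannelResult:
    channel: str
    fit: detection.PeakFit | None = None
    threshold: float | None = None
    alerts: detection.AlertSet | None = None
    seq: detection.StateSequence | None = None
    trace: MUATrace | None = None
    durations: features.DurationSet | None = None
    summary: features.ChannelSummary | None = None
    discontinuities: list[tuple[float, float]] = field(default_factory=list)
    blocked: bool = False
    block_reason: str | None = None


@dataclass
class SessionResult:
    session_id: str
    channels: dict[str, ChannelResult]
    config: PipelineConfig

    @property
    def usable_channels(self) -> list[str]:
        return [c for c, r in self.channels.items() if not r.blocked]

    def observable_table(self) -> pd.DataFrame:
        rows = []
        for ch, r in self.channels.items():
            if r.summary is None:
                continue
            s = r.summary
            rows.append(
                {
                    "channel": ch,
                    "median_d_down": s.median_d_down,
                    "median_d_up": s.median_d_up,
                    "median_d_ud": s.median_d_ud,
                    "s_up": s.s_up,
                    "s_down": s.s_down,
                    "p": s.p,
                    "f": s.f,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SummaryResult:
    stability: qc.StabilityReport
    ledger: qc.ExclusionLedger
    area_values: dict[str, dict[str, dict[str, float]]]     # obs -> subject -> area -> value
    normalized_area: dict[str, pd.DataFrame]
    area_pmatrix: dict[str, stats.PMatrix]
    channel_pmatrix: dict[str, stats.PMatrix]
    core_nodes: dict[str, stats.CoreNodeReport]
    normalized_channel: dict[str, pd.DataFrame]


def analyze_channel(
    signal: np.ndarray, fs: float, channel: str, cfg: PipelineConfig
) -> ChannelResult:
    """Full single-channel analysis; blocking alerts short-circuit features."""
    res = ChannelResult(channel=channel)
    runs = find_flat_runs(signal, fs, cfg.excise_min_flat_s, cfg.excise_flat_tol)
    st: list[float] | None = None
    if runs:
        rec = Recording(session_id="tmp", fs=fs, signals={channel: signal})
        rec, report = excise_discontinuities(
            rec, channel, cfg.excise_min_flat_s, cfg.excise_flat_tol
        )
        signal = rec.signals[channel]
        res.discontinuities = report.intervals
        st = stitch_times(report)

    res.trace = mua_trace(signal, fs, cfg.spectrogram())
    try:
        res.fit = detection.fit_down_peak(res.trace.log_mua)
    except ValueError:
        res.blocked, res.block_reason = True, "fit_failed"
        res.alerts = detection.AlertSet(fit_failed=True)
        return res
    if not res.fit.converged:
        res.blocked, res.block_reason = True, "fit_failed"
        res.alerts = detection.evaluate_alerts(res.fit, None, None)
        return res

    res.threshold = detection.select_threshold(res.fit, cfg.threshold_policy())
    binary = detection.binarize_mua(res.trace.log_mua, res.threshold, cfg.min_state_bins)
    res.seq = detection.detect_transitions(
        res.trace.log_mua, res.trace.t, binary, res.threshold, stitch_times=st
    )
    res.alerts = detection.evaluate_alerts(
        res.fit,
        res.threshold,
        res.seq.n_transitions,
        weak_bimodality_area=cfg.weak_bimodality_area,
        skewness_limit=cfg.skewness_limit,
        min_transitions=cfg.min_transitions,
    )
    if res.alerts.blocking:
        res.blocked = True
        res.block_reason = next(
            r for r in ("few_transitions", "right_peak", "fit_failed") if getattr(res.alerts, r)
        )
        return res

    res.durations = features.compute_durations(res.seq)
    wf_up = features.average_waveform(
        res.trace, res.seq, detection.UPWARD, cfg.waveform_window, signal="log"
    )
    wf_down = features.average_waveform(
        res.trace, res.seq, detection.DOWNWARD, cfg.waveform_window, signal="log"
    )
    wf_up_lin = features.average_waveform(
        res.trace, res.seq, detection.UPWARD, cfg.waveform_window, signal="linear"
    )
    front_up = features.fit_front_slope(wf_up)
    front_down = features.fit_front_slope(wf_down)
    peak, _truncated = features.compute_peak_mua(wf_up_lin, cfg.peak_span_s)
    res.summary = features.summarize_channel(channel, res.durations, front_up, front_down, peak)
    return res


def run_single_session(
    rec: Recording, geometry: ArrayGeometry, cfg: PipelineConfig | None = None
) -> SessionResult:
    """Analyze every channel of one recording."""
    cfg = cfg or PipelineConfig()
    out: dict[str, ChannelResult] = {}
    for ch in rec.channels:
        out[ch] = analyze_channel(rec.signals[ch], rec.fs, ch, cfg)
    if all(r.blocked for r in out.values()):
        reasons = {ch: r.block_reason for ch, r in out.items()}
        raise RuntimeError(f"all channels blocked: {reasons}")
    return SessionResult(session_id=rec.session_id, channels=out, config=cfg)


def _channel_observable(res: ChannelResult, obs: str):
    if res.durations is None or res.summary is None:
        return None
    if obs in DURATION_OBSERVABLES:
        return getattr(res.durations, obs)
    return getattr(res.summary, obs)


def run_summary(
    sessions: list[SessionResult],
    geometry: ArrayGeometry,
    cfg: PipelineConfig | None = None,
) -> SummaryResult:
    """Combine per-session results into inter-session summary statistics."""
    if len(sessions) < 2:
        raise ValueError("summary requires >= 2 sessions")
    cfg = cfg or sessions[0].config

    # pooled stability screen over all converged fits
    fits = [
        (s.session_id, ch, r.fit.sigma)
        for s in sessions
        for ch, r in s.channels.items()
        if r.fit is not None and r.fit.converged
    ]
    stability = qc.stability_study(fits)
    alerts = {s.session_id: {ch: r.alerts for ch, r in s.channels.items()} for s in sessions}
    ledger = qc.apply_exclusions(alerts, stability)

    area_values: dict[str, dict[str, dict[str, float]]] = {}
    normalized_area: dict[str, pd.DataFrame] = {}
    area_pm: dict[str, stats.PMatrix] = {}
    channel_pm: dict[str, stats.PMatrix] = {}
    core: dict[str, stats.CoreNodeReport] = {}
    normalized_channel: dict[str, pd.DataFrame] = {}

    for obs in OBSERVABLES:
        per_subject: dict[str, dict[str, float]] = {}
        per_subject_channels: dict[str, dict[str, float]] = {}
        for s in sessions:
            excluded = set(ledger.excluded.get(s.session_id, {}))
            values = {
                ch: v
                for ch, r in s.channels.items()
                if ch not in excluded and (v := _channel_observable(r, obs)) is not None
            }
            if values:
                per_subject[s.session_id] = stats.aggregate_by_area(values, geometry)
                per_subject_channels[s.session_id] = {
                    ch: float(np.median(v)) if not np.isscalar(v) else float(v)
                    for ch, v in values.items()
                }
        area_values[obs] = per_subject
        norm = stats.normalize_by_subject(per_subject)
        normalized_area[obs] = norm
        groups = {
            a: norm.loc[norm["group"] == a, "value"].to_numpy()
            for a in sorted(norm["group"].unique(), key=geometry.area_labels.index)
        }
        area_pm[obs] = stats.wilcoxon_matrix(groups, alpha=cfg.alpha)

        norm_ch = stats.normalize_by_subject(per_subject_channels)
        normalized_channel[obs] = norm_ch
        ch_order = [e for a in geometry.area_labels for e in geometry.area_channels(a)]
        ch_groups = {
            ch: norm_ch.loc[norm_ch["group"] == ch, "value"].to_numpy()
            for ch in ch_order
            if (norm_ch["group"] == ch).any()
        }
        channel_pm[obs] = stats.wilcoxon_matrix(
            ch_groups, alpha=cfg.alpha, min_n=cfg.min_subjects_per_pair
        )
        core[obs] = stats.rank_core_nodes(channel_pm[obs])

    return SummaryResult(
        stability=stability,
        ledger=ledger,
        area_values=area_values,
        normalized_area=normalized_area,
        area_pmatrix=area_pm,
        channel_pmatrix=channel_pm,
        core_nodes=core,
        normalized_channel=normalized_channel,
    )


def summary_map(
    summary: SummaryResult,
    geometry: ArrayGeometry,
    obs: str = "d_ud",
    cfg: PipelineConfig | None = None,
    method: str = "linear",
) -> maps.InterpolatedMap:
    """Across-subject mean normalized map of one observable with SD markers."""
    cfg = cfg or PipelineConfig()
    norm = summary.normalized_channel[obs]
    grouped = norm.groupby("group")["value"]
    values = grouped.mean().to_dict()
    sds = grouped.std(ddof=1).fillna(0.0).to_dict()
    grid = maps.build_grid(geometry, cfg.grid_nx, cfg.grid_ny)
    return maps.interpolate_map(values, geometry, grid, method=method, marker_sd=sds)
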