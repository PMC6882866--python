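"""Cross-session stability screening of the Down-peak width and exclusions.

Comparing channels (within and across subjects) assumes a comparable
log(MUA) noise floor: during Down states the residual MUA variability is
dominated by the acquisition chain, so the fitted Gaussian width sigma
should be stable across channels.  The stability study pools all fitted
sigmas, flags channels beyond the Tukey upper fence Q3 + 1.5*IQR as
outliers, and the exclusion ledger combines those with the blocking
alerts of the per-session loop (right peak, too few transitions, failed
fits).  Non-blocking observations (weak bimodality, discontinuities) are
recorded as notes but do not exclude a channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: exclusion reasons, in report order
REASONS = (
    "sd_outlier",
    "right_peak",
    "few_transitions",
    "negative_asymmetry",
    "daq_failure",
    "fit_failed",
)


@dataclass
class StabilityReport:
    """Pooled quartile screen of the Down-peak widths."""

    entries: list[tuple[str, str, float]]   # (session, channel, sigma)
    q1: float
    q3: float
    iqr: float
    fence: float
    outliers: list[tuple[str, str, float]]
    mean_before: float
    sd_before: float
    mean_after: float
    sd_after: float

    @property
    def n_outliers(self) -> int:
        return len(self.outliers)


@dataclass
class ExclusionLedger:
    """Excluded channels per session with reasons, plus non-blocking notes."""

    excluded: dict[str, dict[str, str]] = field(default_factory=dict)   # session -> channel -> reason
    notes: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def exclude(self, session: str, channel: str, reason: str) -> None:
        self.excluded.setdefault(session, {})
        # a channel is excluded once; first (alert-stage) reason wins
        self.excluded[session].setdefault(str(channel), reason)

    def note(self, session: str, channel: str, note: str) -> None:
        notes = self.notes.setdefault(session, {}).setdefault(str(channel), [])
        if note not in notes:
            notes.append(note)

    def is_excluded(self, session: str, channel: str) -> bool:
        return str(channel) in self.excluded.get(session, {})

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for v in self.excluded.values())


def stability_study(
    fits: list[tuple[str, str, float]],
    quartile_method: str = "linear",
    fence_factor: float = 1.5,
) -> StabilityReport:
    """Pool fitted sigmas and flag upper-fence outliers.

    Only the upper fence excludes (anomalously wide peaks mean a noisy
    channel); unusually narrow peaks are left in.  The quartile estimator
    (numpy interpolation method) is configurable because fence membership
    of borderline channels can depend on it.
    """
    if len(fits) < 4:
        raise ValueError(f"need >= 4 sigma entries, got {len(fits)}")
    sigmas = np.array([s for _, _, s in fits], dtype=float)
    q1, q3 = np.quantile(sigmas, [0.25, 0.75], method=quartile_method)
    iqr = q3 - q1
    fence = q3 + fence_factor * iqr
    outliers = [(s, c, v) for (s, c, v) in fits if v > fence]
    kept = sigmas[sigmas <= fence]
    return StabilityReport(
        entries=list(fits),
        q1=float(q1), q3=float(q3), iqr=float(iqr), fence=float(fence),
        outliers=outliers,
        mean_before=float(sigmas.mean()), sd_before=float(sigmas.std(ddof=1)),
        mean_after=float(kept.mean()), sd_after=float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
    )


def apply_exclusions(
    session_alerts: dict[str, dict[str, "object"]],
    stability: StabilityReport | None = None,
    session_notes: dict[str, dict[str, list[str]]] | None = None,
) -> ExclusionLedger:
    """Combine blocking alerts and stability outliers into one ledger.

    ``session_alerts`` maps session -> channel -> AlertSet (or any object
    with the same boolean attributes).  The operation is idempotent and
    order-independent: reasons are deterministic per channel.
    """
    ledger = ExclusionLedger()
    for session in sorted(session_alerts):
        for channel in sorted(session_alerts[session], key=str):
            a = session_alerts[session][channel]
            if getattr(a, "fit_failed", False):
                ledger.exclude(session, channel, "fit_failed")
            elif getattr(a, "right_peak", False):
                ledger.exclude(session, channel, "right_peak")
            elif getattr(a, "few_transitions", False):
                ledger.exclude(session, channel, "few_transitions")
            if getattr(a, "weak_bimodality", False):
                ledger.note(session, channel, "weak_bimodality")
            if getattr(a, "negative_skewness", False):
                ledger.note(session, channel, "negative_skewness")
    if stability is not None:
        for session, channel, _sigma in stability.outliers:
            if not ledger.is_excluded(session, channel):
                ledger.exclude(session, channel, "sd_outlier")
    if session_notes:
        for session, by_ch in session_notes.items():
            for channel, notes in by_ch.items():
                for n in notes:
                    ledger.note(session, channel, n)
    return ledger


# ---------------------------------------------------------------------------
# reference ledger fixture


def load_session_notes(path: str | Path | None = None) -> dict:
    """Load a session-notes ledger document (bundled reference one by default)."""
    if path is None:
        ref = resources.files("slowwave.data") / "reference_session_notes.json"
        return json.loads(ref.read_text())
    return json.loads(Path(path).read_text())


def ledger_from_notes(doc: dict) -> ExclusionLedger:
    """Build an ExclusionLedger from a session-notes document."""
    ledger = ExclusionLedger()
    for sess in doc["sessions"]:
        sid = str(sess["id"])
        ledger.excluded.setdefault(sid, {})
        for ch, reason in sess.get("excluded", {}).items():
            ledger.exclude(sid, ch, reason)
        for ch in sess.get("weak_bimodality", []):
            ledger.note(sid, ch, "weak_bimodality")
        for ch in sess.get("discontinuity", []):
            ledger.note(sid, ch, "discontinuity")
    return ledger


def combined_outlier_total(doc: dict) -> dict[str, int]:
    """Session-level exclusions plus stability-screen additions.

    Returns counts: channels excluded during the per-session loops, the
    extra channels removed by the pooled peak-width screen, and the
    combined total removed from the inter-session summary.
    """
    ledger = ledger_from_notes(doc)
    session_level = ledger.n_excluded
    screen = int(doc.get("stability_screen_additional", 0))
    return {
        "session_level": session_level,
        "stability_screen": screen,
        "total": session_level + screen,
    }
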