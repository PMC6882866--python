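"""Recording and electrode-geometry I/O in neutral container formats.

Recordings are raw multi-channel extracellular voltage traces ("unfiltered
field potential", microvolts) sampled at a common rate.  Two on-disk layouts
are supported: a single HDF5 file (one group per channel holding a float32
``signal`` dataset, sampling rate and session metadata as root attributes)
and a directory of per-channel CSV files next to a ``metadata.json``.

The module also removes acquisition discontinuities: flat runs of the trace
(amplifier drop-outs) are excised and the remaining segments are stitched,
with the original-clock intervals preserved in a report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np

VALID_AREAS = frozenset({"M", "S", "P", "R", "V"})


class FormatError(ValueError):
    """Raised when an on-disk container violates the expected layout."""


@dataclass
class Recording:
    """A multi-channel raw voltage recording.

    Parameters
    ----------
    session_id : str
        Identifier of the acquisition session.
    fs : float
        Sampling frequency in Hz (must be positive).
    signals : dict
        Mapping channel id -> 1-D float array of voltage samples (uV).
        All channels must have the same length.
    hemisphere : str, optional
        Recorded hemisphere label ("L"/"R"), if known.
    """

    session_id: str
    fs: float
    signals: dict[str, np.ndarray]
    hemisphere: str | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling frequency must be positive, got {self.fs}")
        if not self.signals:
            raise FormatError("recording has no channels")
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise FormatError(f"ragged channel lengths: {sorted(lengths)}")
        self.signals = {k: np.asarray(v, dtype=np.float64) for k, v in self.signals.items()}

    @property
    def channels(self) -> list[str]:
        return list(self.signals)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    @property
    def duration(self) -> float:
        """Session duration in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass
class ArrayGeometry:
    """Electrode positions (mm) and cortical-area labels of an array."""

    positions: dict[str, tuple[float, float]]
    areas: dict[str, str]
    array_step: float = 0.550

    def __post_init__(self) -> None:
        if self.array_step <= 0:
            raise FormatError("array_step must be positive")
        if set(self.positions) != set(self.areas):
            raise FormatError("positions and area labels must cover the same electrodes")
        seen: dict[tuple[float, float], str] = {}
        for eid, xy in self.positions.items():
            if xy in seen:
                raise FormatError(f"electrodes {seen[xy]} and {eid} share position {xy}")
            seen[xy] = eid

    @property
    def electrodes(self) -> list[str]:
        return list(self.positions)

    def area_channels(self, area: str) -> list[str]:
        return [e for e, a in self.areas.items() if a == area]

    @property
    def area_labels(self) -> list[str]:
        out: list[str] = []
        for a in self.areas.values():
            if a not in out:
                out.append(a)
        return out

    def coords(self, electrodes: list[str] | None = None) -> np.ndarray:
        ids = electrodes if electrodes is not None else self.electrodes
        return np.array([self.positions[e] for e in ids], dtype=float)


@dataclass
class DiscontinuityReport:
    """Excised flat intervals of one channel, on the original session clock."""

    channel: str
    intervals: list[tuple[float, float]] = field(default_factory=list)
    stitched: bool = False

    @property
    def total_excised_s(self) -> float:
        return float(sum(e - s for s, e in self.intervals))


# ---------------------------------------------------------------------------
# recordings


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as HDF5 (group per channel, float32 signals)."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = rec.fs
        f.attrs["session_id"] = rec.session_id
        if rec.hemisphere is not None:
            f.attrs["hemisphere"] = rec.hemisphere
        for ch, sig in rec.signals.items():
            g = f.create_group(str(ch))
            g.create_dataset("signal", data=np.asarray(sig, dtype=np.float32))


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a recording from HDF5 or a per-channel CSV directory.

    The container must declare the sampling frequency and the channel list;
    ragged channel lengths are rejected.
    """
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv-dir":
        return _load_csv_dir(path)
    raise FormatError(f"unknown recording format {format!r}")


def _load_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise FormatError(f"{path}: missing required attribute 'fs'")
        fs = float(f.attrs["fs"])
        session_id = str(f.attrs.get("session_id", path.stem))
        hemisphere = f.attrs.get("hemisphere")
        hemisphere = str(hemisphere) if hemisphere is not None else None
        signals = {}
        for ch in f:
            signals[str(ch)] = np.asarray(f[ch]["signal"], dtype=np.float64)
    if not signals:
        raise FormatError(f"{path}: no channel groups found")
    return Recording(session_id=session_id, fs=fs, signals=signals, hemisphere=hemisphere)


def _load_csv_dir(path: Path) -> Recording:
    meta_path = path / "metadata.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing metadata.json")
    meta = json.loads(meta_path.read_text())
    if "fs" not in meta:
        raise FormatError(f"{meta_path}: missing required key 'fs'")
    channels = meta.get("channels")
    if channels is None:
        channels = sorted(p.stem for p in path.glob("*.csv"))
    signals = {}
    for ch in channels:
        f = path / f"{ch}.csv"
        if not f.exists():
            raise FormatError(f"{path}: declared channel {ch!r} has no CSV file")
        signals[str(ch)] = np.loadtxt(f, dtype=np.float64, ndmin=1)
    return Recording(
        session_id=str(meta.get("session_id", path.name)),
        fs=float(meta["fs"]),
        signals=signals,
        hemisphere=meta.get("hemisphere"),
    )


def save_recording_csv(rec: Recording, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a recording as a directory of per-channel CSVs plus metadata."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "fs": rec.fs,
        "session_id": rec.session_id,
        "channels": rec.channels,
        "hemisphere": rec.hemisphere,
    }
    (path / "metadata.json").write_text(json.dumps(meta))
    for ch, sig in rec.signals.items():
        np.savetxt(path / f"{ch}.csv", sig, fmt=fmt)


# ---------------------------------------------------------------------------
# geometry


def load_geometry(path: str | Path, allow_unknown_areas: bool = False) -> ArrayGeometry:
    """Load an electrode-geometry descriptor (JSON).

    The descriptor lists, per electrode, an id, x/y position in mm and a
    cortical-area label; labels outside M/S/P/R/V are rejected unless
    ``allow_unknown_areas`` is set.
    """
    doc = json.loads(Path(path).read_text())
    return geometry_from_dict(doc, allow_unknown_areas=allow_unknown_areas)


def geometry_from_dict(doc: dict, allow_unknown_areas: bool = False) -> ArrayGeometry:
    positions: dict[str, tuple[float, float]] = {}
    areas: dict[str, str] = {}
    for e in doc["electrodes"]:
        eid = str(e["id"])
        if eid in positions:
            raise FormatError(f"duplicate electrode id {eid!r}")
        area = str(e["area"])
        if area not in VALID_AREAS and not allow_unknown_areas:
            raise FormatError(f"electrode {eid}: unknown area label {area!r}")
        positions[eid] = (float(e["x_mm"]), float(e["y_mm"]))
        areas[eid] = area
    return ArrayGeometry(
        positions=positions,
        areas=areas,
        array_step=float(doc.get("array_step_mm", 0.550)),
    )


def default_geometry() -> ArrayGeometry:
    """The bundled synthetic 32-electrode array layout (0.550 mm step)."""
    ref = resources.files("slowwave.data") / "geometry32_synthetic.json"
    return geometry_from_dict(json.loads(ref.read_text()))


# ---------------------------------------------------------------------------
# discontinuities


def find_flat_runs(signal: np.ndarray, fs: float, min_flat_s: float, flat_tol: float) -> list[tuple[int, int]]:
    """Sample-index intervals [start, end) where the trace is flat.

    A flat run is a maximal stretch of consecutive samples whose successive
    differences are all <= ``flat_tol`` in absolute value and whose span is
    at least ``min_flat_s`` seconds.
    """
    if min_flat_s <= 0:
        raise ValueError("min_flat_s must be positive")
    d = np.abs(np.diff(signal)) <= flat_tol
    if not d.any():
        return []
    # run-length encode the boolean diff sequence
    edges = np.flatnonzero(np.diff(d.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges, len(d) - 1]
    out = []
    for s, e in zip(starts, ends):
        if not d[s]:
            continue
        n_samples = e - s + 2  # m flat diffs span m+1 samples
        if n_samples / fs >= min_flat_s:
            out.append((int(s), int(e + 2)))
    return out


def excise_discontinuities(
    rec: Recording,
    channel: str,
    min_flat_s: float = 0.2,
    flat_tol: float = 0.0,
) -> tuple[Recording, DiscontinuityReport]:
    """Remove flat acquisition drop-outs from one channel.

    Returns a single-channel recording with the retained segments
    concatenated (stitched clock) and a report of the excised intervals on
    the original clock.  Retained samples are never modified; the duration
    shrinks by exactly the summed interval lengths.
    """
    if channel not in rec.signals:
        raise KeyError(f"channel {channel!r} not in recording")
    sig = rec.signals[channel]
    runs = find_flat_runs(sig, rec.fs, min_flat_s, flat_tol)
    report = DiscontinuityReport(
        channel=channel,
        intervals=[(s / rec.fs, e / rec.fs) for s, e in runs],
        stitched=bool(runs),
    )
    if runs:
        keep = np.ones(len(sig), dtype=bool)
        for s, e in runs:
            keep[s:e] = False
        sig = sig[keep]
    out = Recording(
        session_id=rec.session_id,
        fs=rec.fs,
        signals={channel: sig},
        hemisphere=rec.hemisphere,
    )
    return out, report


def stitch_times(report: DiscontinuityReport) -> list[float]:
    """Stitch points on the excised (new) clock, for flagging spanned states."""
    out = []
    removed = 0.0
    for s, e in report.intervals:
        out.append(s - removed)
        removed += e - s
    return out
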