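"""Pipeline configuration: one document holding every stage's settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .detection import ThresholdPolicy
from .mua import SpectrogramConfig


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis, with the standard defaults.

    spectrogram: 5 ms rectangular windows, 200-1500 Hz band.
    threshold: mu + 2*sigma of the Down peak (~2.3% false positives/bin).
    alerts: weak bimodality below 10% tail mass, |skewness| limit 1,
        minimum 3 transitions.
    fronts: 35 ms cubic-fit windows, peak MUA within 250 ms of the upward
        transition.
    maps: 50 x 90 mesh-grid steps.  alpha: 0.05 significance level.
    """

    window_s: float = 0.005
    band: tuple[float, float] = (200.0, 1500.0)
    taper: str = "rect"
    threshold_mode: str = "k_sigma"
    threshold_k: float = 2.0
    threshold_fixed: float | None = None
    weak_bimodality_area: float = 0.10
    skewness_limit: float = 1.0
    min_transitions: int = 3
    min_state_bins: int = 4
    waveform_window: tuple[float, float] = (0.25, 0.30)
    peak_span_s: float = 0.250
    excise_min_flat_s: float = 0.2
    excise_flat_tol: float = 0.0
    grid_nx: int = 50
    grid_ny: int = 90
    alpha: float = 0.05
    min_subjects_per_pair: int = 4
    seed: int = 0

    def spectrogram(self) -> SpectrogramConfig:
        return SpectrogramConfig(window_s=self.window_s, band=tuple(self.band), taper=self.taper)

    def threshold_policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            mode=self.threshold_mode, k=self.threshold_k, fixed_value=self.threshold_fixed
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["band"] = list(self.band)
        d["waveform_window"] = list(self.waveform_window)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def validate(self) -> None:
        self.spectrogram()          # raises on a bad band/window at use time
        self.threshold_policy()
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_transitions < 3:
            raise ValueError("min_transitions below 3 cannot isolate a state pair")
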