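"""Pipeline configuration: filter band, epoching, spectral grid, tests, CV."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis pipeline."""

    filter_low_hz: float = 0.5
    filter_high_hz: float = 15.0
    beats_per_epoch: int = 10
    freq_resolution_hz: float = 0.1
    band_hz: tuple[float, float] = (1.0, 10.0)
    p_max: int = 40
    alpha_pairwise: float = 0.1
    alpha_threeway: float = 0.05
    h1_reject_threshold: float = 0.3
    classifiers: tuple[str, ...] = (
        "nn",
        "linear",
        "diaglinear",
        "quadratic",
        "knn",
        "tree",
        "naive_bayes",
        "svm",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)  # type: ignore[assignment]
        self.classifiers = tuple(self.classifiers)  # type: ignore[assignment]
        numeric = (
            self.filter_low_hz,
            self.filter_high_hz,
            self.beats_per_epoch,
            self.freq_resolution_hz,
            self.p_max,
            self.alpha_pairwise,
            self.alpha_threeway,
            self.h1_reject_threshold,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all numeric configuration fields must be positive")
        if self.filter_low_hz >= self.filter_high_hz:
            raise ValueError("filter band must have low < high")
        if not self.band_hz[0] < self.band_hz[1]:
            raise ValueError("band_hz must be an increasing interval")

    def validate_for_fs(self, fs: float) -> None:
        """Checks that need the record sampling rate."""
        if self.filter_high_hz >= fs / 2:
            raise ValueError("filter_high_hz must be below the Nyquist frequency")
        if self.band_hz[1] > fs / 2:
            raise ValueError("band_hz must lie within the Nyquist range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["band_hz"] = list(self.band_hz)
        data["classifiers"] = list(self.classifiers)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
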