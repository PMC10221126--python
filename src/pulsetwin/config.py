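"""Run configuration: preprocessing, training and evaluation knobs."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline.

    Attributes
    ----------
    n_cycles : number of single cycles averaged into one template (N of the
        multicycle average), >= 1.
    window_size : moving-mean window in samples for detrending; default 75
        (1.5 s at 50 Hz, about two heart cycles — windows close to one
        cycle beat against the heart period and distort cycle shape).
    cycle_length : resampling target length of a single cycle; default 50.
    min_interval_s : shortest admissible foot-to-foot interval in seconds;
        candidate feet closer than this to the last accepted foot are
        rejected as noise. Default 0.33 s (a 180 bpm ceiling).
    sampling_rate_hz : sampling rate the pipeline assumes for record files.
    learning_rate, batch_size, epochs : Adam step size, minibatch size and
        training epochs; defaults 1e-4 / 32 / 500, no early stopping.
    decision_threshold : similarity threshold for accept/reject accuracy.
    random_seed : master seed; all substreams derive from it.
    """

    n_cycles: int = 5
    window_size: int = 75
    cycle_length: int = 50
    min_interval_s: float = 0.33
    sampling_rate_hz: float = 50.0
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 500
    decision_threshold: float = 0.5
    random_seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.cycle_length < 2:
            raise ValueError("cycle_length must be >= 2")
        if not self.min_interval_s > 0:
            raise ValueError("min_interval_s must be > 0")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size >= 1 and epochs >= 0 required")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")

    @property
    def min_interval_samples(self) -> int:
        return max(1, int(round(self.min_interval_s * self.sampling_rate_hz)))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config file must hold a mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "RunConfig":
        data = self.to_dict()
        data.update(kwargs)
        return RunConfig.from_dict(data)
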