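"""Study configuration and run manifests.

``StudyConfig`` bundles every analysis parameter of the pipeline with the
defaults of the study being emulated: spike threshold at 5 baseline noise SDs,
bursts of >=5 spikes with inter-spike intervals <=100 ms, synchrony on 100 ms
bins with electrodes excluded below 5 bursts per recording, calcium transients
at 2 noise SDs with a 1 s F0 window at 15.3 Hz, and alpha = 0.05 throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml


@dataclass
class StudyConfig:
    spike_threshold_multiple: float = 5.0
    spike_dead_time: float = 0.001  # s, refractory after each detection
    burst_n_min: int = 5
    burst_isi_max: float = 0.100  # s
    min_bursts_for_synchrony: int = 5
    synchrony_bin: float = 0.100  # s
    alpha: float = 0.05
    ca_frame_rate: float = 15.3  # Hz
    ca_noise_multiple: float = 2.0
    ca_f0_window: float = 1.0  # s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            "spike_threshold_multiple", "spike_dead_time", "burst_n_min",
            "burst_isi_max", "min_bursts_for_synchrony", "synchrony_bin",
            "ca_frame_rate", "ca_noise_multiple", "ca_f0_window",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if int(self.rng_seed) != self.rng_seed or self.rng_seed < 0:
            raise ValueError("rng_seed must be a non-negative integer")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader serves both)."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        return cls.from_dict(data)


@dataclass
class RunManifest:
    """Provenance record written next to every results directory."""

    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    software: str = "neuroquant"
    version: str = "0.1.0"
    created: str = ""

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
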