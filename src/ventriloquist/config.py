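"""Run configuration: one structured object driving the whole pipeline.

Every stochastic stage takes its seed from the config, so a rerun with the
same config reproduces every number.  The config round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .design import DEFAULT_GRID, DEFAULT_NULL_FRACTION, NOMINAL_DELTA
from .exceptions import InvalidDesignError


@dataclass
class RunConfig:
    # design
    grid: tuple = DEFAULT_GRID
    nominal_delta: float = NOMINAL_DELTA
    null_fraction: float = DEFAULT_NULL_FRACTION
    n_av_sessions_per_report: int = 10
    n_auditory_sessions: int = 3
    n_visual_sessions: int = 3

    # behavioral observers
    n_subjects: int = 5
    sigma_a: float = 12.0
    sigma_v_high: float = 2.5
    sigma_v_low: float = 10.0
    lapse: float = 0.03
    attention_gain: float = 1.0
    observer_mode: str = "fusion"
    subject_jitter: float = 0.15  # SD of log-normal between-subject scatter on the σs

    # neural encoding
    w_v_neural: float = 0.7
    neural_noise_sd: float = 20.0
    reliability_noise_scale: dict = field(default_factory=lambda: {"high": 1.0, "low": 1.5})
    report_gain: dict = field(default_factory=lambda: {"auditory": 1.0, "visual": 1.0})
    n_voxels: int = 40
    voxel_gain_spread: float = 0.5
    znorm_scope: str = "region"

    # fitting and inference
    schemes: tuple = ("model_I", "model_II", "model_III", "model_IV", "congruent21")
    n_starts: int = 20
    n_boot_ci: int = 1000
    n_boot_test: int = 5000
    bonferroni_m: int = 3

    # orchestration
    mode: str = "both"  # "behavior", "neural" or "both"
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if self.mode not in ("behavior", "neural", "both"):
            raise InvalidDesignError(f"unknown mode {self.mode!r}")
        self.grid = tuple(float(g) for g in self.grid)
        self.schemes = tuple(self.schemes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        d["schemes"] = list(self.schemes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
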