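"""Reproducible run configuration for the pipeline CLI.

Defaults encode the study parameters: solver tolerance 1e-6 with six
multigrid levels, nine electrodes, 100 test dipoles, SNR grid
{0, 10, 20, 30, inf} dB, 1000 noise patterns for error bars, and a
ventricular conduction velocity of 1.9 m/s.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import yaml

from .localization import SNR_GRID_DB
from .kalman import V_VENTRICULAR_MPS

__all__ = ["SolverBlock", "StudyBlock", "TrackBlock", "RunConfig"]


@dataclass
class SolverBlock:
    tol: float = 1e-6
    max_iter: int = 500
    levels: int = 6
    omega: float = 1.5
    method: str = "multigrid"


@dataclass
class StudyBlock:
    n_dipoles: int = 100
    snr_db: list = field(default_factory=lambda: list(SNR_GRID_DB))
    n_noise: int = 1000
    seed: int = 0


@dataclass
class TrackBlock:
    v_mps: float = V_VENTRICULAR_MPS
    dt_s: float = 1e-3
    q_mm2: float | None = None   # None: estimate from a dipole study
    r_mm2: float | None = None   # None: estimate from LFM sub-dictionaries
    x0_mm: list = field(default_factory=lambda: [0.0, 0.0, 0.0])


@dataclass
class RunConfig:
    model: str | None = None          # model path; None: generate the phantom
    phantom_spec: str | None = None   # YAML phantom spec path
    electrodes: str | None = None     # electrode CSV; None: phantom defaults
    lfm: str | None = None
    spacing_mm: float = 6.0
    n_electrodes: int = 9
    solver: SolverBlock = field(default_factory=SolverBlock)
    study: StudyBlock = field(default_factory=StudyBlock)
    track: TrackBlock = field(default_factory=TrackBlock)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        cfg = cls()
        for key, sub in (("solver", SolverBlock), ("study", StudyBlock),
                         ("track", TrackBlock)):
            if key in data:
                setattr(cfg, key, sub(**data.pop(key)))
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["study"]["snr_db"] = [("inf" if math.isinf(s) else s)
                                for s in d["study"]["snr_db"]]
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
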