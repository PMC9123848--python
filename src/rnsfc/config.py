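"""Pipeline configuration.

Defaults reproduce the analysis's stated choices: 15 s epochs, the first
6 clean epochs (90 s segment), the five canonical bands, the >= 50%
responder rule and 1000 bootstrap replicates.  Every run embeds the fully
resolved configuration (and its hash) in its reports so that every
estimator and modeling choice is auditable per run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import CohortDesign


@dataclass
class PipelineConfig:
    # spectral analysis
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 14.0),
            "beta": (14.0, 30.0), "gamma": (30.0, 58.0),
        }
    )
    epoch_len: float = 15.0
    n_epochs: int = 6
    welch_window: float = 1.0
    welch_overlap: float = 0.5
    imcoh_mode: str = "abs_per_bin"  # or "abs_of_mean"
    per_epoch: bool = False
    # features
    hemispheric_mode: str = "both_endpoint"  # or "any_endpoint"
    # outcome / classification
    responder_threshold: float = 50.0
    bootstrap_reps: int = 1000
    # stats
    random_slope_lobe: bool = False
    # cohort
    n_rois: int = 218
    n_modules: int = 44
    design: CohortDesign = field(default_factory=CohortDesign)
    # orchestration
    seed: int = 0
    data_dir: str | None = None  # read a written cohort instead of simulating
    out_dir: str = "results"
    write_timeseries: bool = False
    timeseries_format: str = "hdf5"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bands"] = {k: list(v) for k, v in self.bands.items()}
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        d = self.to_dict()
        for key in ("out_dir", "data_dir"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = CohortDesign(**d["design"])
        if "bands" in d:
            d["bands"] = {k: tuple(v) for k, v in d["bands"].items()}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})
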