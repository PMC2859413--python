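"""Pipeline configuration shared by the CLI and scripted runs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .segmentation import DEFAULT_TISSUE_NAMES


@dataclass
class PipelineConfig:
    """All knobs of the fit -> segment -> maps pipeline.

    ``n_sources`` defaults to five, the decomposition depth at which one
    slice separates into artery, gray matter, white matter, venous
    structures and choroid plexus.  Unknown keys in a config file are
    rejected rather than ignored.
    """

    n_sources: int = 5
    n_gauss: int = 2
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 3
    seed: int = 0
    baseline_frames: int = 5
    svd_threshold_fraction: float = 0.2
    first_pass: tuple[int, int] | None = None
    tissue_names: tuple[str, ...] = DEFAULT_TISSUE_NAMES
    te: float | None = None
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.n_gauss < 1:
            raise ValueError("n_gauss must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")
        if not 0 < self.svd_threshold_fraction < 1:
            raise ValueError("svd_threshold_fraction must be in (0, 1)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.te is not None and self.te <= 0:
            raise ValueError("te must be positive")
        if self.first_pass is not None:
            self.first_pass = (int(self.first_pass[0]), int(self.first_pass[1]))
        self.tissue_names = tuple(self.tissue_names)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML or JSON; keyword overrides win over file values."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tissue_names"] = list(self.tissue_names)
        if self.first_pass is not None:
            d["first_pass"] = list(self.first_pass)
        return d
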