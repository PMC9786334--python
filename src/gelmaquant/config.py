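"""Run configuration: one flat-key YAML file plus keyword overrides.

Precedence is overrides > file > defaults.  Derived defaults follow the
expected nucleus radius: the minimum object area is 25% of the smallest
expected nucleus area (debris removal) and the watershed seed separation is
the expected radius itself (over-segmentation guard).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    channel_map: dict[str, int] | None = None
    # segmentation
    threshold_override: dict[str, float] = field(default_factory=dict)  # role -> intensity
    expected_radius: float = 10.0  # px, sets derived segmentation defaults
    min_object_area: int | None = None  # px; default derived from expected_radius
    min_seed_distance: float | None = None  # px; default = expected_radius
    h_maxima: float = 0.0  # optional h-maxima prominence pre-filter, distance units
    connectivity: int = 2  # 1 = 4-neighborhood, 2 = 8-neighborhood
    exclude_border: bool = False
    # classification
    overlap_threshold: float = 0.5
    classify_mode: str = "overlap"  # or "centroid"
    # statistics
    alpha: float = 0.05
    pooling: str = "pooled"  # or "frame"
    # bookkeeping
    outdir: str = "out"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def effective_min_object_area(self) -> int:
        if self.min_object_area is not None:
            return int(self.min_object_area)
        return int(round(0.25 * math.pi * self.expected_radius**2))

    @property
    def effective_min_seed_distance(self) -> float:
        return self.expected_radius if self.min_seed_distance is None else self.min_seed_distance

    def validate(self, check_paths: bool = False) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must lie in (0, 1]")
        if self.expected_radius <= 0:
            raise ValueError("expected_radius must be positive")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")
        if self.classify_mode not in ("overlap", "centroid"):
            raise ValueError("classify_mode must be 'overlap' or 'centroid'")
        if self.pooling not in ("pooled", "frame"):
            raise ValueError("pooling must be 'pooled' or 'frame'")
        if check_paths:
            missing = [p for p in self.inputs if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input path(s) do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Build a config from a flat-key YAML file, then apply overrides."""
        data: dict = {}
        if path is not None:
            with open(path, "r", encoding="utf-8") as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: configuration must be a mapping of flat keys")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effective_min_object_area"] = self.effective_min_object_area
        d["effective_min_seed_distance"] = self.effective_min_seed_distance
        return d
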