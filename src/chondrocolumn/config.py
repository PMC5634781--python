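"""Run configuration: the thresholds and scales every stage shares.

Centralizes the classification constants (the 12° SD threshold for both
the stacked/arbitrary and single/multi rules, the 70–100° complete-pivot
band, the contact dip threshold) plus geometric scales, so one config
object reproduces a full analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    phi_sd_threshold_deg: float = 12.0
    theta_sd_threshold_deg: float = 12.0
    complete_pivot_range_deg: tuple[float, float] = (70.0, 100.0)
    partial_pivot_range_deg: tuple[float, float] = (30.0, 70.0)
    dip_threshold: float = 0.5
    interior_fraction: float = 0.5
    cell_radius_um: float = 5.0
    pixel_size_um: float = 0.5
    seed: int = 0
    output_dir: str = "chondrocolumn_out"

    def __post_init__(self):
        for name in ("phi_sd_threshold_deg", "theta_sd_threshold_deg",
                     "dip_threshold", "interior_fraction",
                     "cell_radius_um", "pixel_size_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["complete_pivot_range_deg"] = list(self.complete_pivot_range_deg)
        d["partial_pivot_range_deg"] = list(self.partial_pivot_range_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("complete_pivot_range_deg", "partial_pivot_range_deg"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
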