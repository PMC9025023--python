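"""Run configuration shared by the library pipeline and the CLI.

Defaults follow the published operating point of the method: 2-pixel angle
step, 60 degree candidate threshold, area-ratio threshold 1.50, and a
20 px/mm imaging scale (mm_per_px = 0.05).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # preprocessing
    sigma: float = 1.0                 # Gaussian smoothing, px
    element_length: int = 3            # linear structuring element, px, odd
    dark_objects: bool = True          # backlit: objects darker than field
    # region analysis
    k_threshold: float = 1.50          # area-ratio contact threshold, strict >
    min_area: int = 50                 # speckle floor, px
    reference_area: float | None = None  # substitute S_min when no single exists
    # concavity
    step: int = 2                      # angle-model step, px along contour
    max_step: int = 8                  # adaptive step-escalation cap
    angle_threshold_deg: float = 60.0  # candidate pit threshold
    max_angle_deg: float = 90.0        # adaptive relaxation cap
    angle_increment_deg: float = 5.0   # relaxation increment
    depth_gate_frac: float = 0.5       # cut depth cap vs max inscribed radius
    max_split_rounds: int = 12
    # shape grading
    mm_per_px: float = 1.0 / 20.0
    d_mean_mode: str = "contour"       # "contour" = mean(d_i); "extremes" = (dmax+dmin)/2
    smooth_window: int = 5             # circular mean over ordered diameters
    # determinism
    seed: int = 0

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
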