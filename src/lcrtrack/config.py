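"""Run configuration: every tunable of the pipeline in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    The segmentation defaults (50 bins, 4-connected clusters, 8-connected
    peak neighbourhood) and calibration defaults (5 ms frames, 100 nm
    voxels) match the submembrane-simulation conventions this tool was
    written for; the −50 mV threshold is the L-type channel activation
    level that ends the diastolic analysis window.
    """

    n_bins: int = 50
    cluster_connectivity: int = 4
    peak_neighborhood: int = 8
    dt_ms: float = 5.0
    voxel_edge_nm: float = 100.0
    periodic_x: bool = False
    threshold_mV: float = -50.0
    exclude_frame0_births: bool = True
    birth_time_bin_ms: float = 25.0
    complex_collision_rule: str = "survivor"

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            n_bins=self.n_bins,
            cluster_connectivity=self.cluster_connectivity,
            peak_neighborhood=self.peak_neighborhood,
            periodic_x=self.periodic_x,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
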