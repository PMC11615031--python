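"""Run configuration: one serializable object holding every stage's
parameters, with defaults for all of them (a config file only overrides)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition import ScanPlan
from .features import FeatureConfig
from .optics import ProbeIntrinsics


@dataclass
class RunConfig:
    """Parameters of a full simulate -> process -> stitch -> features run."""

    seed: int = 0
    phantom_kind: str = "normal"          # 'normal' | 'polyp'
    phantom: dict = field(default_factory=dict)   # kwargs of the phantom maker
    intrinsics: ProbeIntrinsics = field(default_factory=ProbeIntrinsics)
    plan: ScanPlan = field(default_factory=ScanPlan)
    speckle: bool = True
    noise_snr_db: float = None
    scatterer_density: float = 10.0
    window: str = "hann"                  # apodization
    pixel_size: float = 0.005             # mm, scan conversion
    tune_params: tuple = ()               # e.g. ("fov_angle", "mounting_angle")
    percentile_window: tuple = (1.0, 99.0)
    gamma: float = 0.7
    features: FeatureConfig = field(default_factory=FeatureConfig)
    verbosity: int = 1

    def to_dict(self) -> dict:
        def listify(obj):
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            return obj
        return listify(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("intrinsics"), dict):
            d["intrinsics"] = ProbeIntrinsics(**d["intrinsics"])
        if isinstance(d.get("plan"), dict):
            d["plan"] = ScanPlan(**d["plan"])
        if isinstance(d.get("features"), dict):
            f = dict(d["features"])
            if isinstance(f.get("band_search_mm"), list):
                f["band_search_mm"] = tuple(f["band_search_mm"])
            d["features"] = FeatureConfig(**f)
        for key in ("tune_params", "percentile_window"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
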