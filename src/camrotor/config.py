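"""Run configuration and deterministic seed fan-out.

A :class:`RunConfig` bundles the sections consumed by the pipelines
(mechanism, hopping generator, scene/optics/camera, tracking, analysis)
plus a single global seed and output directory.  Every stochastic stage
derives its own stream deterministically from the global seed and the
stage name, so a full run is reproducible from the config alone.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .mechanics import MechanicalParams, MechanismGeometry, SteeredProtocol
from .movie import CameraModel, HopModel, OpticsModel
from .tracking import DetectionParams, TrackingParams

__all__ = ["RunConfig", "substream_seed", "substream_rng"]


def substream_seed(seed: int, name: str) -> int:
    """Deterministic child seed (< 2^31) for the named stage."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def substream_rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "camrotor_out"

    # mechanism section
    variant: int = 3
    variants: tuple = (1, 2, 3, 4, 5, 6)
    geometry: MechanismGeometry = field(default_factory=MechanismGeometry)
    params: MechanicalParams = field(default_factory=MechanicalParams)
    protocol: SteeredProtocol = field(default_factory=SteeredProtocol)
    sim_duration: float = 30.0        # s, equilibrium runs driving the movies
    mobility_duration: float = 30.0   # s, per-variant mobility runs

    # movie section
    trace_source: str = "hopping"     # 'hopping' | 'mechanism'
    hop_model: HopModel = field(default_factory=HopModel)
    n_particles: int = 12
    n_stationary: int = 0
    movie_duration: float = 30.0      # s per particle
    optics: OpticsModel = field(default_factory=OpticsModel)
    camera: CameraModel = field(default_factory=CameraModel)
    crop_size: int = 32               # px, per-particle field
    save_movies: bool = False

    # tracking / analysis section
    detection: DetectionParams = field(default_factory=DetectionParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    n_states: int = 3
    span_threshold: float = 200.0     # deg, rotary/stationary classifier
    min_transitions: int = 2

    def to_dict(self) -> dict:
        return _to_native(asdict(self))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = {}
        section_types = {"geometry": MechanismGeometry,
                         "params": MechanicalParams,
                         "protocol": SteeredProtocol,
                         "hop_model": HopModel,
                         "optics": OpticsModel,
                         "camera": CameraModel,
                         "detection": DetectionParams,
                         "tracking": TrackingParams}
        valid = {f.name for f in fields(cls)}
        for key, value in data.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            if key in section_types and isinstance(value, dict):
                value = _build_section(section_types[key], value)
            kwargs[key] = value
        return cls(**kwargs)

    def override(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def _to_native(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _to_native(obj.tolist())
    return obj


def _build_section(typ, data: dict):
    valid = {f.name for f in fields(typ)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {typ.__name__} keys: {sorted(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return typ(**coerced)
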