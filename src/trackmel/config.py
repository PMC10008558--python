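"""Run configuration: one serializable object reproduces a run with a seed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .localization import PriorConfig, SearchConfig
from .psf_pattern import BeamGeometry, PatternConfig


@dataclass
class SimulationConfig:
    """Emitter and photon-budget settings.

    ``mode`` is "stage" (deterministic circle + axial sinusoid, the bead
    protocol) or "cell" (state-switching diffusion in a spherocylinder).
    """

    mode: str = "stage"
    rate_hz: float = 60e3
    background_per_slot: float = 0.0
    # stage mode
    circle_radius_nm: float = 750.0
    z_peak_to_peak_nm: float = 500.0
    duration_s: float = 1.0
    # cell mode
    n_trajectories: int = 100
    min_duration_s: float = 0.05
    max_duration_s: float = 0.8
    cylinder_length_nm: float = 2000.0
    cell_radius_nm: float = 400.0
    diffusion_um2s: tuple = (0.1, 1.4, 6.0)


@dataclass
class EstimatorConfig:
    """Diffusion-estimator settings: ECVE lag, window, HMM states."""

    lag: int = 8
    window: int = 16
    hmm_states: int = 3
    hmm_restarts: int = 20
    bootstrap: int = 200


@dataclass
class RunConfig:
    geometry: BeamGeometry = field(default_factory=BeamGeometry)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    estimators: EstimatorConfig = field(default_factory=EstimatorConfig)
    psf_voxel_nm: float = 10.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pattern"].pop("layout_xy", None)  # array; regenerate from span
        return _plainify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        out = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                out[f.name] = getattr(cfg, f.name)
            elif dataclasses.is_dataclass(f.type) or f.name in (
                "geometry", "pattern", "priors", "search", "simulation", "estimators"
            ):
                sub_cls = type(getattr(cfg, f.name))
                sub = {
                    k: _tuplify(v) for k, v in d[f.name].items()
                    if k in {sf.name for sf in dataclasses.fields(sub_cls)}
                }
                out[f.name] = sub_cls(**sub)
            else:
                out[f.name] = d[f.name]
        return cls(**out)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, overrides: dict[str, str]) -> "RunConfig":
        """Apply dotted-key string overrides, e.g. {"priors.r_tail": "0.5"}."""
        d = self.to_dict()
        for key, raw in overrides.items():
            parts = key.split(".")
            node = d
            for p in parts[:-1]:
                node = node[p]
            if parts[-1] not in node:
                raise KeyError(f"unknown config key {key!r}")
            node[parts[-1]] = yaml.safe_load(raw)
        return self.from_dict(d)


def _plainify(x):
    if isinstance(x, dict):
        return {k: _plainify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_plainify(v) for v in x]
    if hasattr(x, "item"):
        return x.item()
    return x


def _tuplify(v):
    if isinstance(v, list):
        return tuple(v)
    return v
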