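"""Run configuration: schema, defaults, presets, YAML (de)serialization.

A run is fully described by one nested configuration; all defaults are
echoed into the output manifest so every number in the outputs is traceable
to an explicit parameter value.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import yaml

from .circulation import CirculationParams
from .fibers import SSFiberParams, TransitionParams
from .geometry import GeometryParams
from .materials import ActiveParams, PassiveParams
from .reorientation import AdaptationConfig
from .solver import SolverConfig


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class FiberConfig:
    kind: str = "ss"                                  # 'ss' | 'sit'
    ss: SSFiberParams = SSFiberParams()
    transition: TransitionParams = TransitionParams()

    def validate(self) -> None:
        if self.kind not in ("ss", "sit"):
            raise ConfigError(f"fiber kind must be 'ss' or 'sit', got {self.kind!r}")
        if self.kind == "sit":
            self.transition.validate()


@dataclasses.dataclass(frozen=True)
class PostprocessConfig:
    n_sections: int = 4
    slice_margin: float = 0.25  # axial inset of outer slices, fraction of extent

    def validate(self) -> None:
        if self.n_sections < 1 or not (0.0 < self.slice_margin < 0.5):
            raise ConfigError("invalid postprocess configuration")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    name: str = "run"
    geometry: GeometryParams = GeometryParams()
    subdivisions: tuple[int, int, int] = (6, 1, 10)
    passive: PassiveParams = PassiveParams()
    active: ActiveParams = ActiveParams()
    circulation: CirculationParams = CirculationParams()
    fiber: FiberConfig = FiberConfig()
    adaptation: AdaptationConfig = AdaptationConfig()
    solver: SolverConfig = SolverConfig()
    postprocess: PostprocessConfig = PostprocessConfig()
    n_hemodynamic_cycles: int = 10
    seed: int = 0
    write_fields: bool = False

    def validate(self) -> None:
        self.geometry.validate()
        self.passive.validate()
        self.active.validate()
        self.circulation.validate()
        self.fiber.validate()
        self.adaptation.validate()
        self.solver.validate()
        self.postprocess.validate()
        if self.n_hemodynamic_cycles < 0:
            raise ConfigError("n_hemodynamic_cycles must be >= 0")


def to_dict(cfg: Any) -> Any:
    import numpy as np

    if dataclasses.is_dataclass(cfg):
        return {f.name: to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return [to_dict(x) for x in cfg]
    if isinstance(cfg, np.generic):
        return cfg.item()
    return cfg


_NESTED = {
    "geometry": GeometryParams, "passive": PassiveParams, "active": ActiveParams,
    "circulation": CirculationParams, "adaptation": AdaptationConfig,
    "solver": SolverConfig, "postprocess": PostprocessConfig,
}


def from_dict(d: dict) -> RunConfig:
    kw: dict[str, Any] = {}
    for key, val in d.items():
        if key == "fiber":
            fkw = dict(val)
            if "ss" in fkw:
                fkw["ss"] = SSFiberParams(**fkw["ss"])
            if "transition" in fkw:
                fkw["transition"] = TransitionParams(**fkw["transition"])
            kw[key] = FiberConfig(**fkw)
        elif key in _NESTED:
            kw[key] = _NESTED[key](**val)
        elif key == "subdivisions":
            kw[key] = tuple(val)
        else:
            kw[key] = val
    cfg = RunConfig(**kw)
    cfg.validate()
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def _with(cfg: RunConfig, **kw) -> RunConfig:
    return dataclasses.replace(cfg, **kw)


def preset(name: str) -> RunConfig:
    """Named study configurations.

    Headline runs: 'ss' and the three SIT transition-location variants
    'base' (u_t = +0.4), 'mid' (u_t = 0), 'apex' (u_t = -0.4); slope and
    height are shared.  Slope/height variants of 'mid': 'mid-s90' (steepest
    admissible tilt), 'mid-s0' (no tilt), 'mid-h0' (sharp transition),
    'mid-hlarge' (tall blend).  Each has a '<name>-reduced' counterpart
    (3x1x5 mesh, dt 4 ms, 5 adaptation cycles) exercising the whole pipeline
    in minutes.
    """
    reduced = name.endswith("-reduced")
    base_name = name[: -len("-reduced")] if reduced else name

    sit_variants = {
        "base": TransitionParams(u_t=+0.4),
        "mid": TransitionParams(u_t=0.0),
        "apex": TransitionParams(u_t=-0.4),
        "mid-s90": TransitionParams(u_t=0.0, slope=0.7, height=0.3),
        "mid-s0": TransitionParams(u_t=0.0, slope=0.0),
        "mid-h0": TransitionParams(u_t=0.0, height=0.0),
        "mid-hlarge": TransitionParams(u_t=0.0, height=0.8, slope=0.1),
    }
    if base_name == "ss":
        cfg = RunConfig(name=name, fiber=FiberConfig(kind="ss"))
    elif base_name in sit_variants:
        cfg = RunConfig(name=name,
                        fiber=FiberConfig(kind="sit", transition=sit_variants[base_name]))
    else:
        raise ConfigError(f"unknown preset {name!r}")
    if reduced:
        cfg = _with(cfg, subdivisions=(3, 1, 5),
                    solver=SolverConfig(dt=4.0),
                    adaptation=AdaptationConfig(n_cycles=5),
                    n_hemodynamic_cycles=4)
    cfg.validate()
    return cfg


PRESET_NAMES = ["ss", "base", "mid", "apex",
                "mid-s90", "mid-s0", "mid-h0", "mid-hlarge"]
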