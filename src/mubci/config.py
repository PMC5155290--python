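"""Structured run configuration: nested sections mirroring the component
parameter dataclasses, loadable from and dumpable to YAML, strict about
unknown keys so typos fail loudly instead of silently using defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .decoder import DecoderConfig
from .erd import ERDParams
from .synthetic import SimulationParams
from .task import TaskConfig


def _build(cls, mapping: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(names)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, val in mapping.items():
        f = names[key]
        default = f.default if f.default is not dataclasses.MISSING else None
        if isinstance(val, list) and not isinstance(default, list):
            # YAML has no tuples; restore them (recursively for nested lists)
            val = _tuplify(val)
        kwargs[key] = val
    return cls(**kwargs)


def _tuplify(v):
    return tuple(_tuplify(x) for x in v) if isinstance(v, list) else v


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if hasattr(obj, "item") and callable(obj.item):  # numpy scalar
        return obj.item()
    return obj


@dataclass
class RunConfig:
    simulation: SimulationParams = field(default_factory=SimulationParams)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    erd: ERDParams = field(default_factory=ERDParams)
    seed: int = 0
    out_dir: str = "."

    _SECTIONS = {"simulation": SimulationParams, "decoder": DecoderConfig,
                 "task": TaskConfig, "erd": ERDParams}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - set(cls._SECTIONS) - {"seed", "out_dir"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in d:
                kwargs[name] = _build(section_cls, d[name] or {})
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        if "out_dir" in d:
            kwargs["out_dir"] = str(d["out_dir"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {"simulation": _plain(self.simulation),
                "decoder": _plain(self.decoder),
                "task": _plain(self.task),
                "erd": _plain(self.erd),
                "seed": self.seed,
                "out_dir": self.out_dir}

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
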