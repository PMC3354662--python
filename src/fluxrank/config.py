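"""Pipeline configuration: one flat, sectioned mapping holding every tunable.

Loadable from YAML, overridable per-key; validated before any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .edge_flux import DEFAULT_GAMMA, DEFAULT_MAX_ITER, DEFAULT_PSEUDO, DEFAULT_TOL
from .expression import DEFAULT_EPSILON_FLOOR
from .paths import DEFAULT_CAP_PER_PAIR, DEFAULT_LENGTH_FLOOR

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # inputs / outputs
    network_path: str | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    seeds_path: str | None = None
    output_path: str | None = None

    # expression
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR

    # edge flux
    gamma: float = DEFAULT_GAMMA
    tail_fractions: tuple[float, ...] = (0.025, 0.05, 0.10)
    pseudo: float = DEFAULT_PSEUDO
    tol: float = DEFAULT_TOL
    max_iter: int = DEFAULT_MAX_ITER
    restart_mode: str = "seeds"  # {"seeds", "uniform"}

    # scoring
    cap_per_pair: int = DEFAULT_CAP_PER_PAIR
    length_floor: float = DEFAULT_LENGTH_FLOOR

    # output
    exclude_seeds: bool = False

    # fixture generation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.tail_fractions = tuple(float(t) for t in self.tail_fractions)
        if not self.tail_fractions:
            raise ValueError("tail_fractions must be non-empty")
        for t in self.tail_fractions:
            if not (0.0 < t < 0.5):
                raise ValueError(f"tail fraction {t} outside (0, 0.5)")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")
        if self.pseudo <= 0 or self.tol <= 0 or self.epsilon_floor <= 0 or self.length_floor <= 0:
            raise ValueError("pseudo, tol, epsilon_floor and length_floor must be > 0")
        if self.max_iter < 1 or self.cap_per_pair < 1:
            raise ValueError("max_iter and cap_per_pair must be >= 1")
        if self.restart_mode not in ("seeds", "uniform"):
            raise ValueError(f"unknown restart_mode {self.restart_mode!r}")

    # flat-section round trip -----------------------------------------
    _SECTIONS = {
        "io": ("network_path", "expression_path", "groups_path", "seeds_path", "output_path"),
        "expression": ("epsilon_floor",),
        "edge_flux": ("gamma", "tail_fractions", "pseudo", "tol", "max_iter", "restart_mode"),
        "scoring": ("cap_per_pair", "length_floor"),
        "output": ("exclude_seeds",),
        "fixture": ("rng_seed",),
    }

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for section, keys in cls._SECTIONS.items():
            block = raw.get(section, {}) or {}
            for k in keys:
                if k in block:
                    kwargs[k] = block[k]
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["tail_fractions"] = list(d["tail_fractions"])
        out = {sec: {k: d[k] for k in keys} for sec, keys in self._SECTIONS.items()}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(out, fh, sort_keys=False)
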