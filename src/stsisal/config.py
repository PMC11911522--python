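"""Run configuration: one flat record of every tunable knob.

Serializes losslessly to JSON; unknown keys are rejected so a stale or
misspelled config fails loudly instead of silently using defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    seed: int = 0
    k: int | str = "auto"        # integer or "auto"
    k_min: int = 2
    k_max: int = 8
    reps: int = 1
    n_init: int = 1000
    per_type: int = 100
    g_markers: int = 50
    tau: float = 1.0
    tol_a: float | None = None
    rmse_tol: float = 1e-4
    max_outer: int = 20
    min_frac: float = 0.05
    max_frac: float = 1.0
    threshold: float = 0.3
    use_lognorm: bool = False
    sisal_max_iter: int = 100
    deconf_max_iter: int = 1000
    input: str | None = None
    output: str | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def updated(self, **overrides) -> "RunConfig":
        d = asdict(self)
        for k, v in overrides.items():
            if v is not None:
                if k not in d:
                    raise ValueError(f"unknown config key: {k}")
                d[k] = v
        return RunConfig.from_dict(d)
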