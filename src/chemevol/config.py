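"""Run configuration: YAML round-trip, validation, and ModelParams assembly.

Config keys mirror the model's standard parameter names (N, theta, nh,
g, p, L, m, da, dc, b0, ahalf, s, c, u) plus run controls (T,
replicates, seed, init_mode, record_every, scenario, effect_distribution,
dominance_mode).  Unspecified fields take the standard defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model_core import BenefitParams, DominanceParams, ModelParams
from .scenarios import HERBIVORY_PRESETS, preset_params

__all__ = ["RunConfig", "load_config", "save_config"]

DOMINANCE_MODES = ("scalar", "grid", "uniform-random")


@dataclass
class RunConfig:
    # model parameters
    N: int = 500
    theta: float = 1.0
    nh: int = 1
    g: int = 5
    p: float = 0.2
    L: int = 10
    m: float = 1.0
    da: float = 0.5
    dc: float = 0.5
    b0: float = 0.0
    ahalf: float = 0.0
    s: float = 1.0
    c: float = 0.02
    u: float = 1e-4
    # run controls
    T: int = 5000
    replicates: int = 5
    seed: int = 1
    init_mode: str = "all-absent"
    record_every: int = 5
    scenario: str | None = None
    effect_distribution: str | None = None
    dominance_mode: str = "scalar"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        checks = [
            ("N", self.N >= 1, "must be a positive integer"),
            ("theta", 0 < self.theta <= 1, "must be in (0, 1] (turnover requires theta > 0)"),
            ("nh", self.nh >= 1, "must be >= 1"),
            ("g", self.g >= 1, "must be >= 1"),
            ("p", 0 <= self.p <= 1, "must be in [0, 1]"),
            ("L", self.L >= 1, "must be >= 1"),
            ("da", 0 <= self.da <= 1, "must be in [0, 1]"),
            ("dc", 0 <= self.dc <= 1, "must be in [0, 1]"),
            ("s", self.s > 0, "must be > 0"),
            ("c", self.c >= 0, "must be >= 0"),
            ("u", 0 <= self.u < 1, "must be in [0, 1)"),
            ("T", self.T >= 0, "must be >= 0"),
            ("replicates", self.replicates >= 1, "must be >= 1"),
            ("record_every", self.record_every >= 1, "must be >= 1"),
            ("init_mode", self.init_mode in ("all-absent", "random-0.5", "fixed-frequency"),
             "unknown initialization mode"),
            ("dominance_mode", self.dominance_mode in DOMINANCE_MODES,
             f"must be one of {DOMINANCE_MODES}"),
            ("scenario", self.scenario is None or self.scenario in HERBIVORY_PRESETS,
             f"must be one of {sorted(HERBIVORY_PRESETS)}"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValueError(f"config field {name!r} {msg} (got {getattr(self, name)!r})")

    def to_model_params(self, M: np.ndarray | None = None,
                        dom: DominanceParams | None = None) -> ModelParams:
        """Assemble ModelParams; effect matrix / dominance may be supplied externally."""
        if dom is None:
            dom = DominanceParams.broadcast(self.da, self.dc, self.L)
        params = ModelParams(
            N=self.N, theta=self.theta, nh=self.nh, g=self.g, p=self.p,
            L=self.L, M=self.m if M is None else M, dom=dom,
            benefit=BenefitParams(b0=self.b0, ahalf=self.ahalf, s=self.s),
            c=self.c, u=self.u,
        )
        if self.scenario is not None:
            params = preset_params(self.scenario, params)
        return params

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
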