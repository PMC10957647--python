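"""YAML run configuration: declarative model specs mapped onto the library.

A config names the structural model (baseline family and offset, frailty and
modifier laws, copula dependence, randomization probability), the experiment
grid (Kendall-tau and baseline-offset lists), and run parameters (n, seed,
Riemann step, time horizon, output directory).  Unknown keys are rejected so
typos fail loudly; the assembled model re-runs the hazard positivity check
at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .distributions import (
    BHNModifier,
    CopulaSpec,
    DegenerateFrailty,
    DegenerateModifier,
    GammaFrailty,
    ShiftedGammaModifier,
)
from .scm import AdditiveHazardSCM

__all__ = ["RunConfig", "load_config", "scm_from_dict", "modifier_from_dict", "frailty_from_dict"]

_MODIFIERS = {
    "bhn": (BHNModifier, {"p1", "mu1", "p2", "mu2"}),
    "shifted_gamma": (ShiftedGammaModifier, {"shape", "scale", "shift"}),
    "degenerate": (DegenerateModifier, {"value"}),
}
_FRAILTIES = {
    "gamma": (GammaFrailty, {"shape", "scale"}),
    "degenerate": (DegenerateFrailty, {"value"}),
}


def _build(kind: str, table: dict, spec: dict):
    spec = dict(spec)
    typ = spec.pop("type", None)
    if typ not in table:
        raise ValueError(f"{kind} type must be one of {sorted(table)}, got {typ!r}")
    cls, allowed = table[typ]
    unknown = set(spec) - allowed
    if unknown:
        raise ValueError(f"unknown {kind} keys {sorted(unknown)}")
    return cls(**spec)


def modifier_from_dict(spec: dict):
    """e.g. ``{type: bhn, p1: 0.5, mu1: -0.1, p2: 0.5, mu2: 0.4}``."""
    return _build("modifier", _MODIFIERS, spec)


def frailty_from_dict(spec: dict):
    return _build("frailty", _FRAILTIES, spec)


def scm_from_dict(spec: dict) -> AdditiveHazardSCM:
    spec = dict(spec)
    allowed = {"baseline_family", "ell", "frailty", "modifier", "kendall_tau", "exposure_prob"}
    unknown = set(spec) - allowed
    if unknown:
        raise ValueError(f"unknown scm keys {sorted(unknown)}")
    if "modifier" not in spec:
        raise ValueError("scm config requires a modifier")
    return AdditiveHazardSCM(
        frailty=frailty_from_dict(spec.get("frailty", {"type": "gamma", "shape": 1.0, "scale": 1.0})),
        modifier=modifier_from_dict(spec["modifier"]),
        baseline_family=spec.get("baseline_family", "quadratic"),
        ell=float(spec.get("ell", 0.0)),
        copula=CopulaSpec(kendall_tau=float(spec.get("kendall_tau", 0.0))),
        exposure_prob=float(spec.get("exposure_prob", 0.5)),
    )


@dataclass
class RunConfig:
    """Validated run configuration; defaults follow the study settings
    (n = 10,000, Riemann step 0.1, tau grid {-1,-0.5,0,0.5,1}, ell grid {0,0.5,1})."""

    scm: dict
    n: int = 10_000
    seed: int = 1
    step: float = 0.1
    t_max: float = 3.0
    tau_grid: list[float] = field(default_factory=lambda: [-1.0, -0.5, 0.0, 0.5, 1.0])
    ell_grid: list[float] = field(default_factory=lambda: [0.0, 0.5, 1.0])
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if self.n < 1 or self.step <= 0 or self.t_max <= 0:
            raise ValueError("need n >= 1, step > 0, t_max > 0")
        self.build_scm()  # runs positivity validation early

    def build_scm(self, **overrides) -> AdditiveHazardSCM:
        spec = dict(self.scm)
        spec.update(overrides)
        return scm_from_dict(spec)

    def to_dict(self) -> dict:
        return {
            "scm": self.scm,
            "n": self.n,
            "seed": self.seed,
            "step": self.step,
            "t_max": self.t_max,
            "tau_grid": self.tau_grid,
            "ell_grid": self.ell_grid,
            "out_dir": self.out_dir,
        }


def load_config(path, **overrides) -> RunConfig:
    """Read a YAML config, apply CLI overrides, reject unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    allowed = {"scm", "n", "seed", "step", "t_max", "tau_grid", "ell_grid", "out_dir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if "scm" not in raw:
        raise ValueError("config requires an 'scm' block")
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
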