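"""Scenario configuration, fixtures, and deterministic output writers.

A scenario is a flat YAML mapping: model kind, UPD level(s), initial
condition, time horizon, tolerances, and parameter overrides.  The named
fixtures bundle the canonical in-silico experiments of the switch (motile /
stationary time courses, the miRNA GO/SLOW/STOP series, STAT knockdown, the
APT initial-condition sweep, and the separatrix-shift conditions) so that
analyses and tests never hard-code their settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .params import PARAM_NAMES, ParameterSet, default_parameters

__all__ = ["ScenarioConfig", "load_config", "scenario_fixtures",
           "write_table", "read_table", "write_json"]

_SCALAR_KEYS = {
    "model": str, "U": float, "t_end": float, "rtol": float, "atol": float,
    "deadline": float, "grid_n": int, "rel_tol": float, "rel_band": float,
}
_LIST_KEYS = {"U_list", "initial", "deltaAsigma_values", "A0_values"}
_MODEL_KINDS = {"full15", "reduced2", "reduced3"}


@dataclass(frozen=True)
class ScenarioConfig:
    """Validated settings for one simulation or experiment."""

    model: str = "reduced3"
    U: float = 4.0
    U_list: tuple[float, ...] = ()
    initial: tuple[float, ...] = (12.0, 56.0, 1.5)
    t_end: float = 1000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    deadline: float = 500.0
    rel_tol: float = 0.05
    rel_band: float = 0.05
    grid_n: int = 21
    overrides: dict = field(default_factory=dict)
    deltaAsigma_values: tuple[float, ...] = ()
    A0_values: tuple[float, ...] = ()

    def parameters(self, base: ParameterSet | None = None) -> ParameterSet:
        return (base or default_parameters()).with_overrides(**self.overrides)

    def to_dict(self) -> dict:
        d = {"model": self.model, "U": self.U, "initial": list(self.initial),
             "t_end": self.t_end, "rtol": self.rtol, "atol": self.atol,
             "deadline": self.deadline, "rel_tol": self.rel_tol,
             "rel_band": self.rel_band, "grid_n": self.grid_n,
             "overrides": dict(self.overrides)}
        if self.U_list:
            d["U_list"] = list(self.U_list)
        if self.deltaAsigma_values:
            d["deltaAsigma_values"] = list(self.deltaAsigma_values)
        if self.A0_values:
            d["A0_values"] = list(self.A0_values)
        return d


def _validate(raw: dict, source: str) -> ScenarioConfig:
    known = set(_SCALAR_KEYS) | _LIST_KEYS | {"overrides"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{source}: unknown key(s) {sorted(unknown)}")
    kwargs: dict = {}
    for key, typ in _SCALAR_KEYS.items():
        if key in raw:
            try:
                kwargs[key] = typ(raw[key])
            except (TypeError, ValueError):
                raise ValueError(f"{source}: key {key!r} must be "
                                 f"{typ.__name__}, got {raw[key]!r}")
    for key in _LIST_KEYS:
        if key in raw:
            try:
                kwargs[key] = tuple(float(v) for v in raw[key])
            except (TypeError, ValueError):
                raise ValueError(f"{source}: key {key!r} must be a list of "
                                 f"numbers, got {raw[key]!r}")
    ov = raw.get("overrides", {})
    if not isinstance(ov, dict):
        raise ValueError(f"{source}: 'overrides' must be a mapping")
    bad = set(ov) - set(PARAM_NAMES)
    if bad:
        raise ValueError(f"{source}: unknown parameter(s) in overrides: "
                         f"{sorted(bad)}")
    kwargs["overrides"] = {k: float(v) for k, v in ov.items()}
    cfg = ScenarioConfig(**kwargs)
    if cfg.model not in _MODEL_KINDS:
        raise ValueError(f"{source}: model must be one of "
                         f"{sorted(_MODEL_KINDS)}, got {cfg.model!r}")
    for key in ("t_end", "rtol", "atol", "deadline"):
        if getattr(cfg, key) <= 0:
            raise ValueError(f"{source}: key {key!r} must be positive")
    if any(v < 0 for v in cfg.initial) or cfg.U < 0:
        raise ValueError(f"{source}: initial condition and U must be >= 0")
    # validated overrides by constructing the parameter set once
    cfg.parameters()
    return cfg


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario file (flat YAML); defaults applied."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario file must be a flat mapping")
    return _validate(raw, str(path))


def scenario_fixtures() -> dict[str, ScenarioConfig]:
    """The canonical experiment configurations of the switch."""
    return {
        # the two reference time courses from IC (S,A,B)=(12,56,1.5)
        "motile_timecourse": ScenarioConfig(U=4.0),
        "stationary_timecourse": ScenarioConfig(U=1.0),
        # miRNA strength series: prompt, delayed, failed STAT activation
        "mirna_go": ScenarioConfig(U=4.0, overrides={"deltaAsigma": 0.05}),
        "mirna_slow": ScenarioConfig(U=4.0,
                                     overrides={"deltaAsigma": 0.17382}),
        "mirna_stop": ScenarioConfig(U=4.0, overrides={"deltaAsigma": 0.18}),
        "mirna_series": ScenarioConfig(
            U=4.0, deltaAsigma_values=(0.05, 0.17382, 0.18), t_end=1000.0),
        # STAT knockdown from the stationary state
        "stat_knockdown": ScenarioConfig(U=1.0, t_end=2000.0),
        # final STAT vs initial APT at a low bistable UPD
        "apt_sweep": ScenarioConfig(
            U=0.1, t_end=2000.0, A0_values=(0, 20, 40, 60, 80, 100)),
        # separatrix position across the bistable UPD range
        "manifold_shift": ScenarioConfig(U_list=(0.0133, 0.133, 4.0)),
    }


def _provenance(meta: dict | None) -> list[str]:
    from . import __version__
    lines = [f"# statswitch {__version__}"]
    if meta:
        digest = hashlib.sha256(
            json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()
        for k, v in meta.items():
            lines.append(f"# {k}: {v}")
        lines.append(f"# config_hash: {digest[:16]}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> None:
    """Deterministic CSV with '#'-prefixed provenance header.

    Column order is preserved; floats are rendered at 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    body = df.to_csv(index=False, float_format="%.12g")
    path.write_text("\n".join(_provenance(meta)) + "\n" + body)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if meta:
        payload["_meta"] = meta

    def default(o):
        import numpy as np
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=default) + "\n")
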