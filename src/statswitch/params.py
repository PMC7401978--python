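"""Kinetic parameterization of the JAK/STAT border-cell switch.

The model couples the JAK/STAT signalling cascade to the APT–SLBO
cross-repression circuit that decides whether a *Drosophila* follicle cell
becomes a motile border cell or stays stationary.  All 33 rate constants and
levels live in :class:`ParameterSet`; concentrations are in nM and time in
minutes throughout the package.

The baseline values come from the published literature-derived calibration of
this pathway (translation/transcription rates from gene lengths, degradation
rates, STAT-DNA binding kinetics, miRNA-mediated mRNA degradation).  They are
the reference conditions for every analysis module.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import yaml

logger = logging.getLogger("statswitch")

#: Canonical ASCII parameter names, in calibration-table order.
PARAM_NAMES: tuple[str, ...] = (
    "kUJf", "kUJb", "kc1f", "kc1b", "kc1", "kS2star",
    "kS", "deltaS", "kmsigma", "deltamsigma", "msigma0", "deltaAsigma",
    "ksigmaf", "ksigmab", "JT", "kA", "kmalpha", "malpha0",
    "deltaA", "deltamalpha", "deltaAbeta", "kalphaf", "kalphab",
    "kB", "kmbeta", "mbeta0", "deltaB", "deltambeta", "deltaBalpha",
    "kbetaf", "kbetab", "kbetaRf", "kbetaRb",
)

# Degradation/turnover rates that must be strictly positive so that every
# steady state is finite.
_STRICTLY_POSITIVE = ("JT", "deltaS", "deltaA", "deltaB",
                      "deltamalpha", "deltambeta", "deltamsigma")

_DEFAULTS: dict[str, float] = {
    "kUJf": 0.0133,       # UPD-JAK binding (min^-1 per nM UPD)
    "kUJb": 0.1,          # UPD-JAK dissociation
    "kc1f": 1.0,          # J* + 2S -> c1 binding
    "kc1b": 0.1,          # c1 dissociation
    "kc1": 100.0,         # S2* release from c1 (catalytic rate)
    "kS2star": 0.1,       # S2* dedimerization
    "kS": 3.0,            # STAT translation
    "deltaS": 0.1,        # STAT degradation
    "kmsigma": 1.0,       # stat transcription
    "deltamsigma": 0.2,   # stat mRNA degradation
    "msigma0": 0.5,       # basal stat mRNA production
    "deltaAsigma": 0.05,  # APT-induced miRNA degradation of stat mRNA
    "ksigmaf": 1.0,       # S2* binding to stat gene
    "ksigmab": 2.0,       # S2* dissociation from stat gene
    "JT": 0.15,           # total JAK
    "kA": 0.298,          # APT translation
    "kmalpha": 0.54,      # apt transcription
    "malpha0": 0.52,      # STAT-independent apt mRNA production (e.g. via EYA)
    "deltaA": 0.04,       # APT degradation
    "deltamalpha": 0.086,  # apt mRNA degradation
    "deltaAbeta": 0.1,    # APT-induced miRNA degradation of slbo mRNA
    "kalphaf": 100.0,     # S2* binding to apt gene
    "kalphab": 0.66,      # S2* dissociation from apt gene
    "kB": 0.312,          # SLBO translation
    "kmbeta": 0.538,      # slbo transcription
    "mbeta0": 0.03,       # STAT-independent slbo mRNA production
    "deltaB": 0.04,       # SLBO degradation
    "deltambeta": 0.086,  # slbo mRNA degradation
    "deltaBalpha": 0.5,   # SLBO-induced (cooperative, B^2) apt mRNA degradation
    "kbetaf": 100.0,      # S2* binding to slbo gene
    "kbetab": 0.66,       # S2* dissociation from slbo gene
    "kbetaRf": 100.0,     # APT-driven slbo repression (into repressed state)
    "kbetaRb": 0.522,     # exit from the slbo repressed state
}

assert tuple(_DEFAULTS) == PARAM_NAMES


@dataclass(frozen=True)
class ParameterSet:
    """The 33 rate constants and levels of the switch, immutable.

    Overriding always goes through :meth:`with_overrides`, which returns a
    modified copy, so scan modules can never corrupt a shared baseline.
    """

    kUJf: float
    kUJb: float
    kc1f: float
    kc1b: float
    kc1: float
    kS2star: float
    kS: float
    deltaS: float
    kmsigma: float
    deltamsigma: float
    msigma0: float
    deltaAsigma: float
    ksigmaf: float
    ksigmab: float
    JT: float
    kA: float
    kmalpha: float
    malpha0: float
    deltaA: float
    deltamalpha: float
    deltaAbeta: float
    kalphaf: float
    kalphab: float
    kB: float
    kmbeta: float
    mbeta0: float
    deltaB: float
    deltambeta: float
    deltaBalpha: float
    kbetaf: float
    kbetab: float
    kbetaRf: float
    kbetaRb: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {name!r} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {name!r} must be >= 0, got {v!r}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be > 0")

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced."""
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())

    @classmethod
    def from_dict(cls, values: Mapping[str, float],
                  strict: bool = True) -> "ParameterSet":
        """Build from a flat name→value mapping.

        Unknown keys raise ``KeyError``.  With ``strict=False`` missing keys
        fall back to the baseline values (a notice is logged once per key).
        """
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        merged = {}
        for name in PARAM_NAMES:
            if name in values:
                merged[name] = float(values[name])
            elif strict:
                raise KeyError(f"missing parameter {name!r}")
            else:
                merged[name] = _DEFAULTS[name]
                logger.info("parameter %s not in config, using default %r",
                            name, _DEFAULTS[name])
        return cls(**merged)


def default_parameters() -> ParameterSet:
    """The literature-calibrated baseline parameter set (immutable)."""
    return ParameterSet(**_DEFAULTS)


def save_params(p: ParameterSet, path: str | Path) -> None:
    """Write a flat ``name: value`` YAML file.

    Values are rendered with :func:`repr`, which round-trips any Python float
    bit-exactly through its decimal string.
    """
    lines = [f"{name}: {value!r}" for name, value in p]
    Path(path).write_text("\n".join(lines) + "\n")


def load_params(path: str | Path) -> ParameterSet:
    """Read a flat YAML parameter file.

    Missing keys fall back to the baseline; unknown keys are an error.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"parameter file {path} must be a flat mapping")
    return ParameterSet.from_dict(raw, strict=False)
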