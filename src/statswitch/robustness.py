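"""Per-parameter robustness of bistability.

For each of the 33 rate constants the scan asks: over what one-at-a-time
range of this parameter does the switch remain bistable?  The operational
criterion is configurable because it is genuinely underdetermined:

* ``"interval"`` (default): some UPD level in a search window admits two
  stable fates (a nonempty bistable UPD interval);
* ``"fixedU"``: two stable fates coexist at a fixed reference UPD.

Range endpoints are found by outward geometric march from the baseline
followed by bisection; a parameter whose bistability survives to the search
floor (or cap) reports the clipped bound.  Results are summarised both as
absolute ranges and as log10 percent change, the scale on which relative
parameter sensitivity is compared (the smaller the maximal percent change,
the more sensitive the parameter).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibria import bistable_interval, find_steady_states
from .params import PARAM_NAMES, ParameterSet

logger = logging.getLogger("statswitch")

__all__ = ["BistableRange", "is_bistable", "param_bistable_range", "scan_all"]

#: Upper search cap for scanned parameter values.
SEARCH_CAP = 1100.0


@dataclass(frozen=True)
class Criterion:
    """Operational bistability criterion."""

    kind: str = "interval"          # "interval" | "fixedU"
    u_search: tuple[float, float] = (0.0, 50.0)
    u_ref: float = 4.0
    n_scan: int = 14                # UPD samples for the interval criterion
    n_grid: int = 5                 # multistart lattice size per UPD
    separation: float = 1e-2        # min relative distance of the two fates


@dataclass(frozen=True)
class BistableRange:
    """One-at-a-time bistable range of a single parameter."""

    name: str
    baseline: float
    bistable_start: float
    bistable_end: float
    criterion: str

    @property
    def pct_change_neg(self) -> float:
        return abs(self.bistable_start - self.baseline) / self.baseline * 100.0

    @property
    def pct_change_pos(self) -> float:
        return abs(self.bistable_end - self.baseline) / self.baseline * 100.0

    @property
    def log10_pct_neg(self) -> float:
        return math.log10(self.pct_change_neg) if self.pct_change_neg > 0 \
            else -math.inf

    @property
    def log10_pct_pos(self) -> float:
        return math.log10(self.pct_change_pos) if self.pct_change_pos > 0 \
            else -math.inf

    @property
    def max_pct_change(self) -> float:
        return max(self.pct_change_neg, self.pct_change_pos)


def _two_separated_stables(U: float, p: ParameterSet, crit: Criterion,
                           seeds=None) -> bool:
    try:
        ss = find_steady_states(U, p, n_grid=crit.n_grid, extra_seeds=seeds)
    except RuntimeError:
        return False
    stab = [s for s in ss if s.is_stable]
    if len(stab) < 2:
        return False
    a, b = stab[0].state, stab[-1].state
    scale = max(np.linalg.norm(a), np.linalg.norm(b), 1e-12)
    return float(np.linalg.norm(a - b)) / scale > crit.separation


def is_bistable(p: ParameterSet, criterion: Criterion | None = None) -> bool:
    """Whether the parameter set supports two coexisting stable fates."""
    crit = criterion or Criterion()
    if crit.kind == "fixedU":
        return _two_separated_stables(crit.u_ref, p, crit)
    if crit.kind != "interval":
        raise ValueError(f"unknown criterion kind {crit.kind!r}")
    lo, hi = crit.u_search
    lo_pos = max(lo, 1e-3)
    us = np.unique(np.concatenate([
        np.logspace(np.log10(lo_pos), np.log10(max(hi, 10 * lo_pos)),
                    crit.n_scan // 2),
        np.linspace(lo_pos, hi, crit.n_scan - crit.n_scan // 2)]))
    seeds = None
    for u in us:
        try:
            ss = find_steady_states(u, p, n_grid=crit.n_grid,
                                    extra_seeds=seeds)
        except RuntimeError:
            continue
        seeds = [s.state for s in ss]
        stab = [s for s in ss if s.is_stable]
        if len(stab) >= 2:
            a, b = stab[0].state, stab[-1].state
            scale = max(np.linalg.norm(a), np.linalg.norm(b), 1e-12)
            if float(np.linalg.norm(a - b)) / scale > crit.separation:
                return True
    return False


def _march_and_bisect(p: ParameterSet, name: str, direction: int,
                      crit: Criterion, tol_rel: float = 1e-2) -> float:
    """Boundary of bistability along one direction of one parameter axis.

    Geometric march (factor 2) away from the baseline until bistability is
    lost or the floor/cap is hit, then bisection to relative tolerance.
    """
    base = getattr(p, name)
    floor = base / 1e4
    cap = min(base * 1e4, SEARCH_CAP)

    inside = base
    x = base
    for _ in range(60):
        x = x * 2.0 if direction > 0 else x / 2.0
        if direction > 0 and x >= cap:
            if is_bistable(p.with_overrides(**{name: cap}), crit):
                return cap
            x = cap
            break
        if direction < 0 and x <= floor:
            if is_bistable(p.with_overrides(**{name: floor}), crit):
                # bistable all the way down; test a hard zero
                if is_bistable(p.with_overrides(**{name: 0.0}), crit):
                    return 0.0
                x = floor
                inside = floor
                # boundary between 0 and floor is numerically indistinct
                return floor
            break
        if is_bistable(p.with_overrides(**{name: x}), crit):
            inside = x
        else:
            break
    outside = x
    lo, hi = (inside, outside) if direction > 0 else (outside, inside)
    tol = max(tol_rel * base, 1e-12)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if is_bistable(p.with_overrides(**{name: mid}), crit):
            if direction > 0:
                lo = mid
            else:
                hi = mid
        else:
            if direction > 0:
                hi = mid
            else:
                lo = mid
    return lo if direction > 0 else hi


def param_bistable_range(name: str, p: ParameterSet,
                         criterion: Criterion | None = None,
                         tol_rel: float = 1e-2) -> BistableRange:
    """One-at-a-time bistable range of a single named parameter."""
    if name not in PARAM_NAMES:
        raise KeyError(f"unknown parameter {name!r}")
    crit = criterion or Criterion()
    if not is_bistable(p, crit):
        raise RuntimeError("baseline parameters are not bistable under this "
                           "criterion; review the criterion configuration")
    lo = _march_and_bisect(p, name, -1, crit, tol_rel)
    hi = _march_and_bisect(p, name, +1, crit, tol_rel)
    return BistableRange(name=name, baseline=getattr(p, name),
                         bistable_start=lo, bistable_end=hi,
                         criterion=crit.kind)


def scan_all(p: ParameterSet, names=None,
             criterion: Criterion | None = None,
             cache: dict[str, BistableRange] | None = None) -> pd.DataFrame:
    """Bistable ranges for all (or selected) parameters.

    Returns a table with absolute endpoints and log10 percent changes.
    A pre-populated ``cache`` dict (name → BistableRange) makes the scan
    resumable; per-parameter failures are recorded and the scan continues.
    """
    crit = criterion or Criterion()
    names = list(names) if names is not None else list(PARAM_NAMES)
    rows = []
    for name in names:
        if cache is not None and name in cache:
            r = cache[name]
        else:
            try:
                r = param_bistable_range(name, p, crit)
            except Exception as exc:
                logger.warning("scan of %s failed: %s", name, exc)
                rows.append((name, getattr(p, name), np.nan, np.nan,
                             np.nan, np.nan, np.nan, crit.kind, str(exc)))
                continue
            if cache is not None:
                cache[name] = r
        rows.append((r.name, r.baseline, r.bistable_start, r.bistable_end,
                     r.log10_pct_neg, r.log10_pct_pos, r.max_pct_change,
                     r.criterion, ""))
    return pd.DataFrame(rows, columns=[
        "parameter", "baseline", "bistable_start", "bistable_end",
        "log10_pct_neg", "log10_pct_pos", "max_pct_change", "criterion",
        "error"])
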