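"""Basins of attraction and the separatrix surface of the minimal model.

In the bistable regime the saddle's two-dimensional stable manifold divides
(STAT, APT, SLBO) space into the motile and stationary basins.  The surface
is mapped empirically: a 3-d grid of initial conditions is integrated and
each point labelled by the attractor it reaches within a deadline; points
that fail to resolve lie near the manifold.  Because a coarse grid can leave
that set tiny, midpoints of grid edges whose endpoints reach opposite fates
are added by default (switchable off).  An implicit surface — plane or full
quadric — is then fitted by total least squares, and its quality is scored
by how many resolved grid points it sides correctly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import FateLabel, fate_of_initial
from .equilibria import SteadyState, find_steady_states
from .params import ParameterSet

logger = logging.getLogger("statswitch")

__all__ = ["GridSpec", "BasinGrid", "ManifoldFit", "classify_grid",
           "near_manifold_points", "fit_manifold", "manifold_shift_report"]


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice of initial conditions in (S, A, B)."""

    s_max: float = 250.0
    a_max: float = 120.0
    b_max: float = 60.0
    n: int = 21
    s_min: float = 0.0
    a_min: float = 0.0
    b_min: float = 0.0

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.linspace(self.s_min, self.s_max, self.n),
                np.linspace(self.a_min, self.a_max, self.n),
                np.linspace(self.b_min, self.b_max, self.n))

    def points(self) -> np.ndarray:
        g = np.meshgrid(*self.axes(), indexing="ij")
        return np.stack([v.ravel() for v in g], axis=1)

    def cell_diagonal(self) -> float:
        s, a, b = self.axes()
        return float(np.linalg.norm([s[1] - s[0], a[1] - a[0], b[1] - b[0]]))


@dataclass
class BasinGrid:
    """Fate-labelled grid of initial conditions at one condition."""

    spec: GridSpec
    U: float
    points: np.ndarray               # (n^3, 3)
    fates: np.ndarray                # (n^3,) of {"motile","stationary","unresolved"}
    t_converge: np.ndarray           # (n^3,), nan where unresolved
    deadline: float
    equilibria: list[SteadyState] = field(default_factory=list)

    def fraction(self, tag: str) -> float:
        return float(np.mean(self.fates == tag))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "S0": self.points[:, 0], "A0": self.points[:, 1],
            "B0": self.points[:, 2], "fate": self.fates,
            "t_converge": self.t_converge,
        })


@dataclass(frozen=True)
class ManifoldFit:
    """Implicit separatrix surface g(S,A,B)=0 with quality scores."""

    form: str                        # "plane" | "quadratic"
    coefficients: np.ndarray
    rms_residual: float              # geometric RMS distance of fit points
    sided_accuracy: float            # fraction of resolved grid points on the
                                     # correct side (nan if no grid attached)

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        """Signed value of g at points (n, 3); positive = motile side by
        construction of the fit."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return _design(pts, self.form) @ self.coefficients

    def plane_normal(self) -> np.ndarray:
        if self.form != "plane":
            raise ValueError("normal defined for plane fits only")
        n = self.coefficients[:3]
        return n / np.linalg.norm(n)


def classify_grid(U: float, p: ParameterSet, spec: GridSpec | None = None,
                  deadline: float = 500.0, rel_tol: float = 0.05,
                  rtol: float = 1e-6, atol: float = 1e-9) -> BasinGrid:
    """Integrate every grid point and label its fate.

    Points not within tolerance of either attractor by the deadline are
    labelled unresolved (near-manifold).  Per-point solver failures are also
    labelled unresolved, with a logged warning.
    """
    spec = spec or GridSpec()
    eq = find_steady_states(U, p)
    stables = [s for s in eq if s.is_stable]
    if len(stables) < 2:
        raise ValueError(f"U={U} is not in the bistable regime")
    pts = spec.points()
    fates = np.empty(len(pts), dtype=object)
    tconv = np.full(len(pts), np.nan)
    for i, x0 in enumerate(pts):
        try:
            lab: FateLabel = fate_of_initial(x0, U, p, eq, rel_tol=rel_tol,
                                             deadline=deadline, rtol=rtol,
                                             atol=atol)
        except Exception as exc:       # solver breakdown on a single point
            logger.warning("point %s failed: %s", x0, exc)
            lab = FateLabel("unresolved", None, None)
        fates[i] = lab.tag
        if lab.t_converge is not None:
            tconv[i] = lab.t_converge
    return BasinGrid(spec=spec, U=U, points=pts, fates=fates.astype(str),
                     t_converge=tconv, deadline=deadline, equilibria=eq)


def near_manifold_points(grid: BasinGrid,
                         include_edge_midpoints: bool = True) -> np.ndarray:
    """Points lying near the basin boundary.

    Unresolved grid points, plus (by default) midpoints of every lattice
    edge whose endpoints reached opposite fates.  Empty with a warning if
    the condition is monostable over the grid.
    """
    n = grid.spec.n
    fates = grid.fates.reshape(n, n, n)
    pts = grid.points.reshape(n, n, n, 3)
    out = [grid.points[grid.fates == "unresolved"]]
    if include_edge_midpoints:
        mids = []
        for axis in range(3):
            a = [slice(None)] * 3
            b = [slice(None)] * 3
            a[axis] = slice(None, -1)
            b[axis] = slice(1, None)
            fa, fb = fates[tuple(a)], fates[tuple(b)]
            opposite = ((fa == "motile") & (fb == "stationary")) | \
                       ((fa == "stationary") & (fb == "motile"))
            if opposite.any():
                mids.append(0.5 * (pts[tuple(a)][opposite]
                                   + pts[tuple(b)][opposite]))
        if mids:
            out.append(np.vstack(mids))
    result = np.vstack([o for o in out if len(o)]) if any(
        len(o) for o in out) else np.empty((0, 3))
    if len(result) == 0:
        logger.warning("no basin boundary found on the grid "
                       "(monostable condition?)")
    return result


def _design(pts: np.ndarray, form: str) -> np.ndarray:
    S, A, B = pts[:, 0], pts[:, 1], pts[:, 2]
    if form == "plane":
        return np.stack([S, A, B, np.ones_like(S)], axis=1)
    if form == "quadratic":
        return np.stack([S * S, A * A, B * B, S * A, S * B, A * B,
                         S, A, B, np.ones_like(S)], axis=1)
    raise ValueError(f"unknown surface form {form!r}")


def fit_manifold(points: np.ndarray, form: str = "plane",
                 grid: BasinGrid | None = None) -> ManifoldFit:
    """Total-least-squares implicit surface through near-manifold points.

    Plane: smallest singular direction of the centered point cloud.
    Quadratic: unit-norm least-squares fit over degree-≤2 monomials.
    When a source grid is supplied, the fit's sided-classification accuracy
    is computed against the grid's resolved fate labels and the sign is
    oriented so the motile side is positive.
    """
    pts = np.asarray(points, dtype=float)
    need = 10 if form == "plane" else 30
    if len(pts) < need:
        raise ValueError(f"{form} fit needs >= {need} points, got {len(pts)}")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("degenerate point cloud (rank < 2)")

    if form == "plane":
        c = pts.mean(axis=0)
        _, sv, Vt = np.linalg.svd(pts - c)
        normal = Vt[-1]
        coef = np.append(normal, -normal @ c)
        rms = float(np.sqrt(np.mean(((pts - c) @ normal) ** 2)))
    else:
        X = _design(pts, form)
        # column scaling for conditioning; refold scale into coefficients
        s = np.linalg.norm(X, axis=0)
        s[s == 0] = 1.0
        _, sv, Vt = np.linalg.svd(X / s)
        coef = Vt[-1] / s
        grad = _numeric_gradient(pts, coef, form)
        val = X @ coef
        rms = float(np.sqrt(np.mean((val / np.maximum(
            np.linalg.norm(grad, axis=1), 1e-12)) ** 2)))

    acc = float("nan")
    if grid is not None:
        resolved = grid.fates != "unresolved"
        val = _design(grid.points[resolved], form) @ coef
        motile = grid.fates[resolved] == "motile"
        acc_pos = np.mean((val > 0) == motile)
        acc_neg = np.mean((val < 0) == motile)
        if acc_neg > acc_pos:
            coef = -coef
            acc = float(acc_neg)
        else:
            acc = float(acc_pos)
    return ManifoldFit(form=form, coefficients=coef, rms_residual=rms,
                       sided_accuracy=acc)


def _numeric_gradient(pts: np.ndarray, coef: np.ndarray,
                      form: str) -> np.ndarray:
    h = 1e-6 * max(1.0, float(np.abs(pts).max()))
    grad = np.empty_like(pts)
    for j in range(3):
        e = np.zeros(3)
        e[j] = h
        grad[:, j] = ((_design(pts + e, form) @ coef)
                      - (_design(pts - e, form) @ coef)) / (2 * h)
    return grad


def manifold_shift_report(p: ParameterSet, U_values=None,
                          deltaAsigma_values=None, U_fixed: float = 4.0,
                          spec: GridSpec | None = None,
                          probe=(12.0, 56.0, 1.5), deadline: float = 500.0,
                          form: str = "plane") -> pd.DataFrame:
    """Separatrix fits across conditions, with the probe point's side.

    Conditions are either UPD levels (``U_values``) or miRNA strengths
    (``deltaAsigma_values`` at ``U_fixed``).  For each bistable condition the
    basin grid is classified, the surface fitted (``probe_value`` is the
    signed surface value at the probe, positive on the motile side), and the
    probe initial condition labelled by the basin it actually belongs to
    (``probe_side``, determined by integration — exact even when the probe
    sits closer to the separatrix than the fit error).  Monostable
    conditions are skipped with a note.
    """
    if (U_values is None) == (deltaAsigma_values is None):
        raise ValueError("give exactly one of U_values, deltaAsigma_values")
    conditions = ([("U", u, p, u) for u in U_values] if U_values is not None
                  else [("deltaAsigma", d, p.with_overrides(deltaAsigma=d),
                         U_fixed) for d in deltaAsigma_values])
    rows = []
    probe = np.asarray(probe, dtype=float)
    for name, value, pc, u in conditions:
        try:
            grid = classify_grid(u, pc, spec=spec, deadline=deadline)
        except ValueError as exc:
            logger.warning("condition %s=%s skipped: %s", name, value, exc)
            rows.append((name, value, u, "monostable", np.nan, np.nan,
                         np.nan, None))
            continue
        pts = near_manifold_points(grid)
        fit = fit_manifold(pts, form=form, grid=grid)
        motile_frac = grid.fraction("motile")
        side_val = float(fit.evaluate(probe)[0])
        # the probe's true side of the separatrix is its fate — the plane
        # value is only a geometric diagnostic and can mis-side a probe
        # sitting closer to the boundary than the fit error
        lab = fate_of_initial(probe, u, pc, grid.equilibria,
                              deadline=10.0 * deadline)
        rows.append((name, value, u, "bistable", motile_frac,
                     fit.sided_accuracy, side_val, lab.tag))
    return pd.DataFrame(rows, columns=[
        "parameter", "value", "U", "regime", "motile_fraction",
        "sided_accuracy", "probe_value", "probe_side"])
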