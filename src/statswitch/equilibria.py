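"""Steady states, stability, and fold bifurcations of the minimal model.

The (STAT, APT, SLBO) switch is dissipative: every production term is a
bounded rational function, so trajectories enter a box whose edges are the
closed-form ultimate bounds (production maximum over degradation rate).
Steady states are found by damped multistart Newton on a log-spaced lattice,
deduplicated and classified by the eigenvalues of the finite-difference
Jacobian.  One-parameter continuation in the UPD input uses pseudo-arclength
steps so the branch can be followed around fold (limit) points, where the
stationary and intermediate saddle branches meet and annihilate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet
from .reduction import _rhs3_core, jacobian_three_var, three_var_rhs

logger = logging.getLogger("statswitch")

__all__ = [
    "SteadyState", "BifurcationBranch", "ultimate_bounds",
    "find_steady_states", "continue_branch", "bistable_interval",
    "bifurcation_table",
]

_RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class SteadyState:
    """An equilibrium of the three-variable model at a given UPD level."""

    state: np.ndarray          # (S, A, B)
    U: float
    stability: str             # "stable" | "unstable"
    eigenvalues: np.ndarray    # 3 complex eigenvalues
    residual: float            # ||rhs(state)||_2

    @property
    def S(self) -> float:
        return float(self.state[0])

    @property
    def A(self) -> float:
        return float(self.state[1])

    @property
    def B(self) -> float:
        return float(self.state[2])

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BifurcationBranch:
    """A continuation path with detected fold points.

    ``label`` records the seed's identity (stationary/motile/middle); the
    path itself may run through folds onto other segments — per-state
    stability is authoritative.
    """

    states: list[SteadyState]
    folds: list[SteadyState] = field(default_factory=list)
    label: str = ""
    truncated: bool = False

    @property
    def fold_U(self) -> list[float]:
        return [s.U for s in self.folds]


def ultimate_bounds(p: ParameterSet) -> np.ndarray:
    """Closed-form ultimate bounds (S_max, A_max, B_max) of the flow.

    Each production term is maximal with full gene activity and no
    repressor, e.g. ``S <= kS (kmsigma + msigma0)/(deltamsigma deltaS)``.
    """
    s = p.kS * (p.kmsigma + p.msigma0) / (p.deltamsigma * p.deltaS)
    a = p.kA * (p.kmalpha + p.malpha0) / (p.deltamalpha * p.deltaA)
    b = p.kB * (p.kmbeta + p.mbeta0) / (p.deltambeta * p.deltaB)
    return np.array([s, a, b])


def _classify(x: np.ndarray, U: float, p: ParameterSet, **kw) -> SteadyState:
    J = jacobian_three_var(x, U, p, **kw)
    ev = np.linalg.eigvals(J)
    res = float(np.linalg.norm(three_var_rhs(x, U, p, **kw)))
    stability = "stable" if np.all(ev.real < 0) else "unstable"
    return SteadyState(state=np.array(x, dtype=float), U=float(U),
                       stability=stability, eigenvalues=ev, residual=res)


def _newton_polish(x0: np.ndarray, U: float, p: ParameterSet,
                   tol: float = 1e-12, maxiter: int = 60, **kw):
    """Damped Newton on a single starting point; None on failure."""
    x = np.array(x0, dtype=float)
    for _ in range(maxiter):
        f = three_var_rhs(x, U, p, **kw)
        nf = np.linalg.norm(f)
        if nf < tol:
            return x
        J = jacobian_three_var(x, U, p, **kw)
        try:
            step = np.linalg.solve(J, f)
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(30):
            xn = x - lam * step
            if np.all(xn > -1e-12):
                fn = three_var_rhs(np.clip(xn, 0.0, None), U, p, **kw)
                if np.linalg.norm(fn) < nf:
                    x = np.clip(xn, 0.0, None)
                    break
            lam *= 0.5
        else:
            return None
    f = three_var_rhs(x, U, p, **kw)
    return x if np.linalg.norm(f) < tol else None


def _multistart_newton(starts: np.ndarray, U: float, p: ParameterSet,
                       printed_k: bool = False, km_squared: bool = False,
                       iters: int = 60) -> np.ndarray:
    """Vectorized Newton on many starts at once; returns converged points."""
    X = np.array(starts, dtype=float)          # (n, 3)
    lo, hi = 1e-12, 10.0 * ultimate_bounds(p).max()

    def F(X):
        dS, dA, dB = _rhs3_core(X[:, 0], X[:, 1], X[:, 2], U, p,
                                printed_k, km_squared)
        return np.stack([dS, dA, dB], axis=1)

    for _ in range(iters):
        f = F(X)
        J = np.empty((X.shape[0], 3, 3))
        h = np.maximum(1e-7 * np.abs(X), 1e-9)
        for j in range(3):
            Xp = X.copy()
            Xp[:, j] += h[:, j]
            J[:, :, j] = (F(Xp) - f) / h[:, j][:, None]
        try:
            step = np.linalg.solve(J, f[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.array([np.linalg.lstsq(J[i], f[i], rcond=None)[0]
                             for i in range(X.shape[0])])
        X = np.clip(X - step, lo, hi)
    f = F(X)
    ok = np.linalg.norm(f, axis=1) < 1e-8
    return X[ok]


def _default_lattice(n: int = 8) -> np.ndarray:
    S = np.logspace(-3, np.log10(500.0), n)
    A = np.logspace(-3, np.log10(200.0), n)
    B = np.logspace(-3, np.log10(200.0), n)
    g = np.meshgrid(S, A, B, indexing="ij")
    return np.stack([v.ravel() for v in g], axis=1)


def find_steady_states(U: float, p: ParameterSet, n_grid: int = 8,
                       extra_seeds=None, printed_k: bool = False,
                       km_squared: bool = False,
                       dedup_rtol: float = 1e-4) -> list[SteadyState]:
    """All equilibria at UPD level ``U``, sorted by APT descending.

    Multistart Newton from a log-spaced ``n_grid³`` lattice (plus optional
    seeds, e.g. solutions at a nearby UPD), deduplicated at relative distance
    ``dedup_rtol``, polished to residual < 1e-12 and classified by Jacobian
    eigenvalues.
    """
    kw = dict(printed_k=printed_k, km_squared=km_squared)
    starts = _default_lattice(n_grid)
    if extra_seeds is not None and len(extra_seeds):
        starts = np.vstack([np.atleast_2d(np.asarray(extra_seeds, float)),
                            starts])
    cand = _multistart_newton(starts, U, p, **kw)
    roots: list[np.ndarray] = []
    for x in cand:
        x = _newton_polish(x, U, p, **kw)
        if x is None:
            continue
        scale = max(1.0, float(np.linalg.norm(x)))
        if not any(np.linalg.norm(x - r) / max(scale, np.linalg.norm(r))
                   < dedup_rtol for r in roots):
            roots.append(x)
    if not roots:
        raise RuntimeError(f"no steady state found at U={U!r} "
                           "(unexpected for a dissipative system)")
    out = [_classify(x, U, p, **kw) for x in roots]
    out.sort(key=lambda s: -s.A)
    return out


def stable_states(U: float, p: ParameterSet, **kw) -> list[SteadyState]:
    """Convenience: only the stable equilibria at ``U``."""
    return [s for s in find_steady_states(U, p, **kw) if s.is_stable]


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

def _ext_jacobian(x: np.ndarray, U: float, p: ParameterSet, **kw):
    """[F_x | F_U] — 3x4 Jacobian of the RHS in (state, U)."""
    Jx = jacobian_three_var(x, U, p, **kw)
    hU = max(1e-6 * abs(U), 1e-9)
    fU = (three_var_rhs(x, U + hU, p, **kw)
          - three_var_rhs(x, max(U - hU, 0.0), p, **kw)) / (hU + min(hU, U))
    return np.hstack([Jx, fU[:, None]])


def _tangent(x, U, p, prev=None, scale=None, **kw):
    """Unit tangent (in scaled coordinates) of the solution curve."""
    A = _ext_jacobian(x, U, p, **kw) * scale[None, :]
    _, _, Vt = np.linalg.svd(A)
    t = Vt[-1]
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t / np.linalg.norm(t)


def _corrector(y_pred, t, ds, y_prev, p, scale, maxiter=12, **kw):
    """Newton on [F(x,U); t·(y_scaled - y_prev_scaled) - ds] = 0."""
    y = y_pred.copy()
    for _ in range(maxiter):
        x, U = y[:3], max(y[3], 0.0)
        f = three_var_rhs(np.clip(x, 0.0, None), U, p, **kw)
        g = np.dot(t, (y - y_prev) * scale) - ds
        r = np.append(f, g)
        if np.linalg.norm(r) < 1e-11:
            y[:3] = np.clip(y[:3], 0.0, None)
            y[3] = max(y[3], 0.0)
            return y
        Jext = _ext_jacobian(np.clip(x, 0.0, None), U, p, **kw)
        M = np.vstack([Jext, (t * scale)[None, :]])
        try:
            step = np.linalg.solve(M, r)
        except np.linalg.LinAlgError:
            return None
        y = y - step
        if not np.all(np.isfinite(y)):
            return None
    return None


def continue_branch(p: ParameterSet, u_range: tuple[float, float],
                    seed: SteadyState, ds0: float = 0.05,
                    max_ds: float = 0.5, min_ds: float = 1e-6,
                    max_steps: int = 2000, fold_tol: float = 1e-3,
                    printed_k: bool = False,
                    km_squared: bool = False) -> BifurcationBranch:
    """Pseudo-arclength continuation of a steady-state branch in UPD.

    Starts from ``seed`` (a converged steady state at ``u_range[0]`` or
    within the range) and follows the solution curve until UPD leaves
    ``u_range``.  Steps adapt: halve on corrector failure, grow (×1.3, capped
    at ``max_ds``) on fast convergence.  A fold is flagged where the tangent's
    U-component changes sign; its location is refined by step bisection until
    the bracketing states differ by less than ``fold_tol`` in U.

    Arclength is measured in scaled coordinates (states by the dissipative
    ultimate bounds, U by the range width) so that all components contribute
    comparably.
    """
    kw = dict(printed_k=printed_k, km_squared=km_squared)
    u_lo, u_hi = u_range
    bounds = ultimate_bounds(p)
    scale = 1.0 / np.append(bounds, max(u_hi - u_lo, 1.0))

    y = np.append(seed.state, seed.U)
    t = _tangent(y[:3], y[3], p, prev=None, scale=scale, **kw)
    if t[3] < 0:   # start off toward increasing U
        t = -t
    states = [_classify(y[:3], y[3], p, **kw)]
    folds: list[SteadyState] = []
    truncated = False
    ds = ds0

    def refine_fold(y0, t0, ds_bracket):
        """Arclength bisection on the tangent's U-component sign.

        Near a fold dU/ds ~ 0, so |dU| across a step says nothing about how
        close the extremum is; bisecting on the sign of dU/ds does.
        """
        yr, tr = y0.copy(), t0.copy()
        h = ds_bracket
        for _ in range(40):
            if h < min(1e-4, fold_tol):
                break
            y_try = _corrector(yr + h * tr / scale, tr, h, yr, p, scale, **kw)
            if y_try is None:
                h *= 0.5
                continue
            t_try = _tangent(y_try[:3], y_try[3], p, prev=tr, scale=scale,
                             **kw)
            if tr[3] * t_try[3] < 0:
                h *= 0.5          # fold inside (yr, y_try): shrink
            else:
                yr, tr = y_try, t_try   # advance toward the fold
        return yr

    for _ in range(max_steps):
        y_pred = y + ds * t / scale
        y_new = _corrector(y_pred, t, ds, y, p, scale, **kw)
        if y_new is None:
            ds *= 0.5
            if ds < min_ds:
                truncated = True
                logger.warning("continuation stalled at U=%.6g", y[3])
                break
            continue
        t_new = _tangent(y_new[:3], y_new[3], p, prev=t, scale=scale, **kw)
        if t[3] * t_new[3] < 0:          # crossed a fold: pin it down
            y_fold = refine_fold(y, t, ds)
            folds.append(_classify(y_fold[:3], y_fold[3], p, **kw))
        y, t = y_new, t_new
        states.append(_classify(y[:3], y[3], p, **kw))
        ds = min(ds * 1.3, max_ds)
        if y[3] > u_hi + 1e-9 or y[3] < u_lo - 1e-9:
            break
    else:
        truncated = True

    return BifurcationBranch(states=states, folds=folds, label="",
                             truncated=truncated)


def label_branch_states(branch: BifurcationBranch) -> list[str]:
    """Per-state labels: stable APT-dominated = stationary, stable
    SLBO-dominated = motile, unstable = middle."""
    out = []
    for s in branch.states:
        if not s.is_stable:
            out.append("middle")
        else:
            out.append("motile" if s.B > s.A else "stationary")
    return out


def bistable_interval(p: ParameterSet, u_search: tuple[float, float] = (0.0, 50.0),
                      n_scan: int = 40, refine_tol: float = 1e-3,
                      n_grid: int = 6, printed_k: bool = False,
                      km_squared: bool = False) -> tuple[float, float] | None:
    """The UPD interval over which two stable fates coexist.

    Scans a log/linear grid of UPD values counting stable equilibria, then
    bisects the edges of the widest bistable run to ``refine_tol``.  Returns
    ``None`` if the system is monostable throughout the search range.
    """
    kw = dict(printed_k=printed_k, km_squared=km_squared, n_grid=n_grid)
    u_lo, u_hi = u_search
    lo_pos = max(u_lo, 1e-4)
    us = np.unique(np.concatenate([
        [u_lo],
        np.logspace(np.log10(lo_pos), np.log10(max(u_hi, lo_pos * 10)),
                    n_scan // 2),
        np.linspace(u_lo, u_hi, n_scan - n_scan // 2),
    ]))
    us = us[(us >= u_lo) & (us <= u_hi)]

    seeds = None
    flags = []
    for u in us:
        ss = find_steady_states(u, p, extra_seeds=seeds, **kw)
        seeds = [s.state for s in ss]
        flags.append(sum(s.is_stable for s in ss) >= 2)
    flags = np.asarray(flags)
    if not flags.any():
        return None

    # widest contiguous bistable run
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        if not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    i0, i1 = max(runs, key=lambda r: us[r[1]] - us[r[0]])

    def is_bi(u):
        return sum(s.is_stable for s in find_steady_states(u, p, **kw)) >= 2

    lo = us[i0]
    if i0 > 0:
        a, b = us[i0 - 1], us[i0]
        while b - a > refine_tol:
            m = 0.5 * (a + b)
            if is_bi(m):
                b = m
            else:
                a = m
        lo = b
    hi = us[i1]
    if i1 < len(us) - 1:
        a, b = us[i1], us[i1 + 1]
        while b - a > refine_tol:
            m = 0.5 * (a + b)
            if is_bi(m):
                a = m
            else:
                b = m
        hi = a
    return float(lo), float(hi)


def bifurcation_table(branches: list[BifurcationBranch]) -> pd.DataFrame:
    """Long-format table of continuation branches for re-plotting.

    Columns: ``branch, U, S, A, B, stability``.
    """
    if not branches:
        raise ValueError("need at least one branch")
    rows = []
    for br in branches:
        labels = label_branch_states(br)
        for s, lab in zip(br.states, labels):
            rows.append((br.label or lab, s.U, s.S, s.A, s.B, s.stability))
    return pd.DataFrame(rows,
                        columns=["branch", "U", "S", "A", "B", "stability"])
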