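"""Time integration, fate classification, and scripted experiments.

A cell's fate is read off its trajectory: convergence to the high-SLBO
attractor is the motile fate, convergence to the high-APT attractor the
stationary fate.  Initial conditions that fail to resolve within the
experimental deadline (default 500 min, a realistic specification window
for border cells) lie near the separatrix between the basins.

Scripted experiments:

* :func:`mirna_delay_experiment` — varying the APT-driven miRNA degradation
  of stat mRNA (``deltaAsigma``) produces GO (prompt STAT activation), SLOW
  (delayed activation, the separatrix grazes the initial condition) and STOP
  (no activation: the separatrix has moved past the initial condition).
* :func:`stat_knockdown_experiment` — silencing STAT translation (``kS=0``)
  from the stationary steady state roughly halves APT, because apt
  transcription loses its STAT-dependent component.
* :func:`apt_sweep_experiment` — raising the initial APT level pushes the
  final STAT level down onto the low branch (APT inhibits STAT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .fullmodel import FULL_VARS, FullState, default_initial_full_state, full_rhs
from .params import ParameterSet
from .equilibria import SteadyState, find_steady_states
from .reduction import stat_dimer_qss, three_var_rhs, two_var_rhs

ModelKind = Literal["full15", "reduced2", "reduced3"]

_DIMS: dict[str, int] = {"full15": 15, "reduced2": 2, "reduced3": 3}
_VAR_NAMES: dict[str, tuple[str, ...]] = {
    "full15": FULL_VARS,
    "reduced2": ("A", "B"),
    "reduced3": ("S", "A", "B"),
}

__all__ = [
    "ModelKind", "Trajectory", "FateLabel", "integrate", "classify_fate",
    "convergence_time", "fate_of_initial", "mirna_delay_experiment",
    "stat_knockdown_experiment", "apt_sweep_experiment",
    "full_model_attractor",
]


@dataclass
class Trajectory:
    """An integrated time course with its provenance."""

    times: np.ndarray           # (n,), minutes, times[0] == 0
    states: np.ndarray          # (n, dim)
    model: str
    U: float                    # UPD (for reduced2: the frozen S2* level)
    overrides: dict = field(default_factory=dict)
    rtol: float = 1e-8
    atol: float = 1e-10

    @property
    def var_names(self) -> tuple[str, ...]:
        return _VAR_NAMES[self.model]

    def component(self, name: str) -> np.ndarray:
        return self.states[:, self.var_names.index(name)]

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.var_names))
        df.insert(0, "t", self.times)
        return df

    def write_csv(self, path: str | Path) -> None:
        from .config import write_table
        meta = {"model": self.model, "U": self.U,
                "rtol": self.rtol, "atol": self.atol}
        meta.update({f"override:{k}": v for k, v in self.overrides.items()})
        write_table(self.to_frame(), path, meta)


@dataclass(frozen=True)
class FateLabel:
    """Outcome of a fate-classified trajectory."""

    tag: str                         # "motile" | "stationary" | "unresolved"
    reference: SteadyState | None    # the matched attractor, if resolved
    t_converge: float | None         # minutes; None iff unresolved

    def __post_init__(self) -> None:
        if (self.tag == "unresolved") != (self.t_converge is None):
            raise ValueError("unresolved iff convergence time is None")


def integrate(model: ModelKind, initial: Sequence[float], U: float,
              p: ParameterSet, t_end: float, rtol: float = 1e-8,
              atol: float = 1e-10, n_out: int = 1001,
              overrides: dict | None = None, printed_k: bool = False,
              km_squared: bool = False, method: str = "LSODA") -> Trajectory:
    """Integrate the selected model with a stiff solver on a dense grid.

    ``initial`` must match the model dimension (15, 2 or 3).  For the
    fixed-dimer two-variable model, ``U`` is interpreted as the frozen S2*
    level.  Output is on a uniform grid of ``n_out`` points (>= 200 for
    stable downstream metrics).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    y0 = np.asarray(initial, dtype=float)
    if y0.shape != (_DIMS[model],):
        raise ValueError(f"model {model!r} needs a state of length "
                         f"{_DIMS[model]}, got {y0.shape}")
    n_out = max(int(n_out), 200)

    if model == "full15":
        fun = lambda t, y: full_rhs(y, U, p)
    elif model == "reduced3":
        fun = lambda t, y: three_var_rhs(y, U, p, printed_k, km_squared)
    else:
        fun = lambda t, y: np.asarray(
            two_var_rhs(y[0], y[1], U, p, printed_k))

    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(fun, (0.0, t_end), y0, method=method, rtol=rtol,
                    atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(
            f"stiff integration failed at t={sol.t[-1] if len(sol.t) else 0}:"
            f" {sol.message}")
    return Trajectory(times=sol.t, states=sol.y.T, model=model, U=U,
                      overrides=dict(overrides or {}), rtol=rtol, atol=atol)


def _reduced_point(traj_state: np.ndarray, model: str) -> np.ndarray:
    """Project a state onto (S, A, B) for fate comparison."""
    if model == "full15":
        idx = [FULL_VARS.index(n) for n in ("S", "A", "B")]
        return traj_state[idx]
    if model == "reduced3":
        return traj_state
    raise ValueError("fate classification needs S, A, B components")


def classify_fate(traj: Trajectory, equilibria: Sequence[SteadyState],
                  rel_tol: float = 0.05,
                  deadline: float = 500.0) -> FateLabel:
    """Label a trajectory motile/stationary/unresolved.

    The trajectory endpoint at the deadline is compared with the two stable
    attractors; within relative euclidean distance ``rel_tol`` (scaled by the
    attractor's norm) of the high-SLBO state it is motile, of the high-APT
    state stationary, otherwise unresolved.  The convergence time is the
    first time after which the trajectory stays inside the tolerance ball.
    """
    stables = sorted((s for s in equilibria if s.is_stable),
                     key=lambda s: s.B)
    if len(stables) < 2:
        raise ValueError("need both stable fates among the equilibria")
    stationary, motile = stables[0], stables[-1]

    pts = np.stack([_reduced_point(s, traj.model) for s in traj.states])
    mask = traj.times <= deadline + 1e-9
    i_end = int(np.max(np.nonzero(mask)))
    end = pts[i_end]

    for ref, tag in ((motile, "motile"), (stationary, "stationary")):
        scale = max(float(np.linalg.norm(ref.state)), 1e-12)
        if np.linalg.norm(end - ref.state) / scale <= rel_tol:
            d = np.linalg.norm(pts[: i_end + 1] - ref.state, axis=1) / scale
            outside = np.nonzero(d > rel_tol)[0]
            t_conv = 0.0 if len(outside) == 0 else float(
                traj.times[outside[-1] + 1])
            return FateLabel(tag=tag, reference=ref, t_converge=t_conv)
    return FateLabel(tag="unresolved", reference=None, t_converge=None)


def fate_of_initial(initial: Sequence[float], U: float, p: ParameterSet,
                    equilibria: Sequence[SteadyState], rel_tol: float = 0.05,
                    deadline: float = 500.0, rtol: float = 1e-6,
                    atol: float = 1e-9, printed_k: bool = False,
                    km_squared: bool = False) -> FateLabel:
    """Fast event-based fate classification of one initial condition.

    Integration terminates as soon as the trajectory enters the tolerance
    ball of either attractor — much cheaper than a dense trajectory when
    classifying thousands of grid points.
    """
    stables = sorted((s for s in equilibria if s.is_stable),
                     key=lambda s: s.B)
    if len(stables) < 2:
        raise ValueError("need both stable fates among the equilibria")
    stationary, motile = stables[0], stables[-1]

    fun = lambda t, y: three_var_rhs(y, U, p, printed_k, km_squared)

    def mk_event(ref):
        scale = max(float(np.linalg.norm(ref.state)), 1e-12)

        def ev(t, y):
            return np.linalg.norm(y - ref.state) / scale - rel_tol
        ev.terminal = True
        ev.direction = -1
        return ev

    ev_m, ev_s = mk_event(motile), mk_event(stationary)
    y0 = np.asarray(initial, dtype=float)
    if ev_m(0.0, y0) <= 0:
        return FateLabel("motile", motile, 0.0)
    if ev_s(0.0, y0) <= 0:
        return FateLabel("stationary", stationary, 0.0)
    sol = solve_ivp(fun, (0.0, deadline), y0, method="LSODA", rtol=rtol,
                    atol=atol, events=[ev_m, ev_s], dense_output=False)
    if sol.status == 1:      # a terminal event fired
        if len(sol.t_events[0]):
            return FateLabel("motile", motile, float(sol.t_events[0][0]))
        return FateLabel("stationary", stationary, float(sol.t_events[1][0]))
    return FateLabel("unresolved", None, None)


def convergence_time(traj: Trajectory, component: str,
                     rel_band: float = 0.05,
                     abs_floor: float = 1e-6) -> float | None:
    """First time after which ``component`` stays within ``rel_band`` of its
    final value; ``None`` if it never settles.

    The band has an absolute floor so that components converging to zero
    (e.g. STAT under knockdown) are handled sensibly.
    """
    y = traj.component(component)
    final = float(y[-1])
    band = max(rel_band * abs(final), abs_floor)
    outside = np.nonzero(np.abs(y - final) > band)[0]
    if len(outside) == 0:
        return 0.0
    i = outside[-1] + 1
    if i >= len(y):
        return None
    return float(traj.times[i])


def _saddle_S(U: float, p: ParameterSet, **kw) -> float | None:
    """STAT level of the unstable saddle at (U, p); None if monostable."""
    sad = [s for s in find_steady_states(U, p, **kw) if not s.is_stable]
    return sad[0].S if sad else None


def mirna_delay_experiment(p: ParameterSet, deltaAsigma_values: Sequence[float],
                           U: float = 4.0,
                           initial: Sequence[float] = (12.0, 56.0, 1.5),
                           t_end: float = 1000.0,
                           rel_band: float = 0.05) -> pd.DataFrame:
    """STAT-activation delay as the APT-driven miRNA strength increases.

    For each ``deltaAsigma`` the minimal model is integrated from ``initial``
    and the STAT equilibration time (entry into the ``rel_band`` band around
    its final value) is measured.  The first value is the baseline.  Fates:
    GO — converges with elevated STAT (above the saddle's STAT level);
    SLOW — converges elevated but delayed more than twice the baseline time;
    STOP — STAT never elevates within ``t_end``.
    """
    rows = []
    t_base = None
    for i, das in enumerate(deltaAsigma_values):
        pi = p.with_overrides(deltaAsigma=das)
        traj = integrate("reduced3", initial, U, pi, t_end,
                         overrides={"deltaAsigma": das},
                         n_out=max(1001, int(2 * t_end)))
        t_conv = convergence_time(traj, "S", rel_band)
        s_sad = _saddle_S(U, pi)
        elevated = (s_sad is not None and traj.endpoint[0] > s_sad) or \
                   (s_sad is None and True)
        if i == 0:
            if t_conv is None or not elevated:
                raise RuntimeError("baseline condition failed to converge "
                                   "to the elevated state")
            t_base = t_conv
        if not elevated or t_conv is None:
            fate, delay = "STOP", None
        else:
            delay = t_conv - t_base
            fate = "SLOW" if t_conv > 2.0 * t_base else "GO"
        rows.append((das, fate, t_conv, delay, traj.endpoint[0]))
    return pd.DataFrame(rows, columns=["deltaAsigma", "fate", "t_converge",
                                       "delay", "final_S"])


def stat_knockdown_experiment(p: ParameterSet, U: float = 1.0,
                              initial: Sequence[float] = (12.0, 56.0, 1.5),
                              t_end: float = 2000.0) -> tuple[float, float, float]:
    """APT response to STAT knockdown (translation silenced, ``kS=0``).

    Runs the minimal model from ``initial`` to its steady state, then
    silences STAT translation and integrates onward from that state.
    Returns ``(A_before, A_after, ratio)``.
    """
    traj1 = integrate("reduced3", initial, U, p, t_end)
    dv = three_var_rhs(traj1.endpoint, U, p)
    if np.max(np.abs(dv)) > 1e-6:
        raise RuntimeError("system did not reach steady state before "
                           "knockdown; increase t_end")
    A_before = float(traj1.endpoint[1])
    p_kd = p.with_overrides(kS=0.0)
    traj2 = integrate("reduced3", traj1.endpoint, U, p_kd, t_end,
                      overrides={"kS": 0.0})
    A_after = float(traj2.endpoint[1])
    return A_before, A_after, A_after / A_before


def apt_sweep_experiment(p: ParameterSet, U: float = 0.1,
                         A0_values: Sequence[float] = (0, 20, 40, 60, 80, 100),
                         S0: float = 12.0, B0: float = 1.5,
                         t_end: float = 2000.0) -> pd.DataFrame:
    """Final STAT level versus the initial APT load at a bistable UPD.

    High initial APT suppresses STAT signalling enough to capture the cell
    on the low-STAT (stationary) branch; low initial APT lets STAT rise to
    the elevated branch.
    """
    rows = []
    for a0 in A0_values:
        traj = integrate("reduced3", (S0, float(a0), B0), U, p, t_end)
        rows.append((float(a0), float(traj.endpoint[0])))
    return pd.DataFrame(rows, columns=["A0", "final_S"])


def full_model_attractor(U: float, p: ParameterSet, near: SteadyState,
                         t_end: float = 4000.0) -> np.ndarray:
    """The 15-variable attractor reached from a reduced-model stable state.

    Seeds the full model at the reduced attractor (fast variables at their
    conditioned QSS) and relaxes it; used to compare steady-state structure
    across model resolutions.
    """
    y0 = default_initial_full_state(p, near.S, near.A, near.B).as_array()
    traj = integrate("full15", y0, U, p, t_end)
    return traj.endpoint
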