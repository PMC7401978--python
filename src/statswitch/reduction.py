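"""Quasi-steady-state reduction of the JAK/STAT switch.

Timescale separation is pronounced: STAT-DNA binding (``kalphaf`` etc.,
~100/min) is orders of magnitude faster than translation and degradation
(~0.04-0.3/min), and mRNA turnover is at least twice as fast as protein
turnover.  Setting the fast derivatives to zero collapses the 15-variable
mechanistic model in stages:

1. gene states ``alpha, beta, betaR, sigma`` → algebraic occupancy formulas
   (:func:`gene_qss`), governed by equilibrium constants K = k_forward/k_backward;
2. mRNAs → :func:`mrna_qss`, giving the fixed-dimer two-variable APT/SLBO
   cross-repression model (:func:`two_var_rhs`);
3. JAK activation and STAT dimerization → :func:`jak_qss` and
   :func:`stat_dimer_qss` (a Michaelis–Menten step with conserved activated
   JAK), giving the minimal three-variable model in (STAT, APT, SLBO)
   (:func:`three_var_rhs`).

Two documented interpretation switches exist for cross-checks:

* ``printed_k`` flips every gene-state equilibrium constant to its reciprocal
  (backward/forward).  The default forward/backward orientation is the one
  under which the occupancy formulas are the exact QSS solutions of the
  gene-state ODEs.
* ``km_squared``: the dimer-activation Michaelis constant
  ``Km = (kc1b + kc1)/kc1f`` arises from binding of *two* STAT monomers and
  carries units of nM², entering as ``S²/(S² + Km)`` (default).  The variant
  treats the same number as a half-saturation in nM and squares it.

All algebra here is vectorized over numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "EquilibriumConstants", "GeneQss", "StatActivation",
    "equilibrium_constants", "gene_qss", "jak_qss", "stat_dimer_qss",
    "dimer_km2", "mrna_qss", "two_var_rhs", "three_var_rhs",
    "jacobian_three_var",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Gene-state and JAK-activation equilibrium constants.

    ``Kalpha``, ``Kbeta``, ``KbetaR``, ``Ksigma`` are forward/backward ratios
    (units 1/nM); ``KUJ = kUJb/kUJf`` is the UPD half-saturation of JAK
    activation (nM).
    """

    Kalpha: float
    Kbeta: float
    KbetaR: float
    Ksigma: float
    KUJ: float


@dataclass(frozen=True)
class GeneQss:
    """Quasi-steady-state gene occupancies.

    ``alphaStar``/``betaStar`` are the *transcribing* apt/slbo fractions;
    ``sigma`` is the inactive stat fraction.  The identity
    ``beta + betaR + betaStar = 1`` is exact.
    """

    alphaStar: np.ndarray | float
    beta: np.ndarray | float
    betaR: np.ndarray | float
    betaStar: np.ndarray | float
    sigma: np.ndarray | float


@dataclass(frozen=True)
class StatActivation:
    """Quasi-steady-state JAK/STAT activation state."""

    Jstar: float
    vmax: float
    km: float
    S2star: np.ndarray | float


def equilibrium_constants(p: ParameterSet,
                          printed_k: bool = False) -> EquilibriumConstants:
    """Forward/backward equilibrium-constant ratios for the fast subsystems."""
    for name in ("kalphab", "kbetab", "kbetaRb", "ksigmab", "kUJf"):
        if getattr(p, name) == 0:
            raise ZeroDivisionError(f"backward rate {name!r} is zero")
    if printed_k:
        return EquilibriumConstants(
            Kalpha=p.kalphab / p.kalphaf, Kbeta=p.kbetab / p.kbetaf,
            KbetaR=p.kbetaRb / p.kbetaRf, Ksigma=p.ksigmab / p.ksigmaf,
            KUJ=p.kUJb / p.kUJf)
    return EquilibriumConstants(
        Kalpha=p.kalphaf / p.kalphab, Kbeta=p.kbetaf / p.kbetab,
        KbetaR=p.kbetaRf / p.kbetaRb, Ksigma=p.ksigmaf / p.ksigmab,
        KUJ=p.kUJb / p.kUJf)


def gene_qss(S2star, A, p: ParameterSet, printed_k: bool = False) -> GeneQss:
    """Gene occupancies at equilibrium with the dimer and APT levels frozen.

    Solves the gene-state ODE subsystem at rest:
    ``alphaStar = K_a S2*/(K_a S2* + 1)``,
    ``beta = 1/(K_b S2* + 1 + K_bR A)``, ``betaR = K_bR A beta``,
    ``betaStar = K_b S2* beta``, ``sigma = 1/(K_s S2* + 1)``.
    """
    S2star = np.asarray(S2star, dtype=float)
    A = np.asarray(A, dtype=float)
    if np.any(S2star < 0) or np.any(A < 0):
        raise ValueError("S2star and A must be >= 0")
    k = equilibrium_constants(p, printed_k)
    alphaStar = k.Kalpha * S2star / (k.Kalpha * S2star + 1.0)
    beta = 1.0 / (k.Kbeta * S2star + 1.0 + k.KbetaR * A)
    betaR = k.KbetaR * A * beta
    betaStar = k.Kbeta * S2star * beta
    sigma = 1.0 / (k.Ksigma * S2star + 1.0)
    if S2star.ndim == 0:
        return GeneQss(float(alphaStar), float(beta), float(betaR),
                       float(betaStar), float(sigma))
    return GeneQss(alphaStar, beta, betaR, betaStar, sigma)


def jak_qss(U, p: ParameterSet):
    """Activated JAK at equilibrium with the UPD input.

    ``J* = kUJf U JT / (kUJb + kUJf U)``: monotone in U, saturating at the
    total JAK pool ``JT``, half-saturated at ``U = KUJ``.
    """
    U = np.asarray(U, dtype=float)
    out = p.kUJf * U * p.JT / (p.kUJb + p.kUJf * U)
    return float(out) if U.ndim == 0 else out


def dimer_km2(p: ParameterSet, km_squared: bool = False) -> float:
    """Effective Michaelis constant (in nM²) of STAT-dimer activation.

    The activated-JAK enzyme binds two STAT monomers, so the Michaelis
    constant ``Km = (kc1b + kc1)/kc1f`` carries units of nM² and the
    saturation term is ``S²/(S² + Km)``.  With ``km_squared=True`` the same
    number is read as a half-saturation concentration in nM and squared.
    """
    km = (p.kc1b + p.kc1) / p.kc1f
    return km * km if km_squared else km


def stat_dimer_qss(S, U, p: ParameterSet,
                   km_squared: bool = False) -> StatActivation:
    """Active STAT dimer at quasi-steady state for given monomer and UPD.

    A Michaelis–Menten treatment of ``J* + 2S -> c1 -> J* + S2*`` with the
    activated-JAK pool conserved gives production ``vmax S²/(S² + Km)`` with
    ``vmax = kc1 J*``; balancing against dedimerization ``kS2star S2*`` yields
    ``S2* = vmax S² / (kS2star (S² + Km))``.  Monotone increasing in both
    ``S`` and ``U`` and bounded by ``vmax/kS2star``.
    """
    if p.kS2star == 0:
        raise ZeroDivisionError("kS2star must be > 0 for the dimer QSS")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0) or np.any(np.asarray(U) < 0):
        raise ValueError("S and U must be >= 0")
    Jstar = jak_qss(U, p)
    vmax = p.kc1 * Jstar
    km = (p.kc1b + p.kc1) / p.kc1f
    km2 = dimer_km2(p, km_squared)
    S2star = vmax / p.kS2star * S * S / (S * S + km2)
    if S.ndim == 0 and np.ndim(S2star) == 0:
        return StatActivation(float(Jstar), float(vmax), km, float(S2star))
    return StatActivation(Jstar, vmax, km, S2star)


def mrna_qss(alphaStar, betaStar, A, B, p: ParameterSet):
    """apt and slbo mRNA at quasi-steady state.

    ``malpha = (kmalpha alphaStar + malpha0)/(deltamalpha + deltaBalpha B²)``
    — SLBO represses apt translation cooperatively (the B² term);
    ``mbeta = (kmbeta betaStar + mbeta0)/(deltambeta + deltaAbeta A)``
    — APT enhances slbo mRNA degradation linearly.
    """
    alphaStar = np.asarray(alphaStar, dtype=float)
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    malpha = ((p.kmalpha * alphaStar + p.malpha0)
              / (p.deltamalpha + p.deltaBalpha * B * B))
    mbeta = ((p.kmbeta * np.asarray(betaStar, dtype=float) + p.mbeta0)
             / (p.deltambeta + p.deltaAbeta * A))
    if alphaStar.ndim == 0 and A.ndim == 0:
        return float(malpha), float(mbeta)
    return malpha, mbeta


def two_var_rhs(A, B, S2star, p: ParameterSet, printed_k: bool = False):
    """APT/SLBO cross-repression dynamics with the STAT dimer held fixed.

    The fixed-dimer core of the switch: gene states and mRNAs at QSS, only
    the two proteins dynamic.
    """
    g = gene_qss(S2star, A, p, printed_k)
    malpha, mbeta = mrna_qss(g.alphaStar, g.betaStar, A, B, p)
    dA = p.kA * malpha - p.deltaA * np.asarray(A, dtype=float)
    dB = p.kB * mbeta - p.deltaB * np.asarray(B, dtype=float)
    if np.ndim(dA) == 0:
        return float(dA), float(dB)
    return dA, dB


def _rhs3_core(S, A, B, U, p: ParameterSet, printed_k: bool,
               km_squared: bool):
    """Vectorized right-hand side of the minimal model; no input checks."""
    k = equilibrium_constants(p, printed_k)
    Jstar = p.kUJf * U * p.JT / (p.kUJb + p.kUJf * U)
    vmax = p.kc1 * Jstar
    km2 = dimer_km2(p, km_squared)
    S2 = vmax / p.kS2star * S * S / (S * S + km2)
    alphaStar = k.Kalpha * S2 / (k.Kalpha * S2 + 1.0)
    beta = 1.0 / (k.Kbeta * S2 + 1.0 + k.KbetaR * A)
    betaStar = k.Kbeta * S2 * beta
    sigmaAct = k.Ksigma * S2 / (k.Ksigma * S2 + 1.0)   # transcribing stat fraction
    dS = (p.kS * (p.kmsigma * sigmaAct + p.msigma0)
          / (p.deltamsigma + p.deltaAsigma * A) - p.deltaS * S)
    dA = (p.kA * (p.kmalpha * alphaStar + p.malpha0)
          / (p.deltamalpha + p.deltaBalpha * B * B) - p.deltaA * A)
    dB = (p.kB * (p.kmbeta * betaStar + p.mbeta0)
          / (p.deltambeta + p.deltaAbeta * A) - p.deltaB * B)
    return dS, dA, dB


def three_var_rhs(state, U: float, p: ParameterSet, printed_k: bool = False,
                  km_squared: bool = False) -> np.ndarray:
    """Right-hand side of the minimal (STAT, APT, SLBO) model.

    Composes the JAK and dimer QSS, the gene occupancies and the mRNA QSS
    into three rational production terms minus linear degradation.  ``state``
    is ``(S, A, B)``; arrays of shape ``(3, n)`` are evaluated pointwise.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)) or not np.isfinite(U):
        raise ValueError("non-finite state or input")
    dS, dA, dB = _rhs3_core(y[0], y[1], y[2], U, p, printed_k, km_squared)
    return np.array([dS, dA, dB])


def jacobian_three_var(state, U: float, p: ParameterSet,
                       printed_k: bool = False,
                       km_squared: bool = False) -> np.ndarray:
    """Central finite-difference Jacobian of :func:`three_var_rhs`.

    Relative step 1e-6 with an absolute floor of 1e-9 per component.
    """
    y = np.asarray(state, dtype=float).copy()
    h = np.maximum(1e-6 * np.abs(y), 1e-9)
    J = np.empty((3, 3))
    for j in range(3):
        yp, ym = y.copy(), y.copy()
        yp[j] += h[j]
        ym[j] -= h[j]
        fp = three_var_rhs(yp, U, p, printed_k, km_squared)
        fm = three_var_rhs(ym, U, p, printed_k, km_squared)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise FloatingPointError("non-finite RHS while differencing")
        J[:, j] = (fp - fm) / (2.0 * h[j])
    return J
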