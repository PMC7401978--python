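"""The full 15-variable mechanistic model of the JAK/STAT switch.

State variables (all concentrations in nM, gene states dimensionless):

========  =====================================================
``Jstar``  activated JAK
``J``      inactive JAK
``S``      STAT monomer
``c1``     J*–STAT complex (two monomers bound to activated JAK)
``c2``     S2*–APT complex (APT sequestering the active dimer)
``S2star`` activated STAT dimer
``A``      APT protein
``B``      SLBO protein
``malpha`` apt mRNA
``mbeta``  slbo mRNA
``msigma`` stat mRNA
``alpha``  proportion of inactive apt genes
``beta``   proportion of inactive slbo genes
``betaR``  proportion of repressed slbo genes (APT-bound)
``sigma``  proportion of inactive stat genes
========  =====================================================

Gene-state convention: ``alpha``/``beta``/``sigma`` are the *inactive*
(non-transcribing) fractions, so transcription terms read ``kmalpha*(1-alpha)``
etc. and the resting initial state is ``alpha = beta = sigma = 1``.

The UPD ligand concentration ``U`` is an external input, not a state.

The APT–S2* sequestration complex ``c2`` forms with rates that are not part
of the 33-parameter calibration (the three-variable parameter table omits
them).  ``full_rhs`` takes them as optional arguments; the defaults
(``kS2starAf=0.1`` per nM per min, ``kS2starAb=1`` per min) sit at the same
scale as the other protein complex kinetics in the calibration and give a
fast, weakly bound buffer.  Sequestration cancels identically at any
equilibrium, so it shapes transients (and hence basin membership) without
moving steady states; setting both rates to zero decouples ``c2``, which is
how that invariance is verified numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

#: State-vector component names, in canonical order.
FULL_VARS: tuple[str, ...] = (
    "Jstar", "J", "S", "c1", "c2", "S2star", "A", "B",
    "malpha", "mbeta", "msigma", "alpha", "beta", "betaR", "sigma",
)

N_FULL = len(FULL_VARS)


@dataclass(frozen=True)
class FullState:
    """A point in the 15-dimensional state space."""

    Jstar: float
    J: float
    S: float
    c1: float
    c2: float
    S2star: float
    A: float
    B: float
    malpha: float
    mbeta: float
    msigma: float
    alpha: float
    beta: float
    betaR: float
    sigma: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite component in FullState")
        if np.any(arr[:11] < 0):
            bad = [FULL_VARS[i] for i in range(11) if arr[i] < 0]
            raise ValueError(f"negative concentration(s): {bad}")
        if not (0 <= self.alpha <= 1 and 0 <= self.sigma <= 1):
            raise ValueError("alpha and sigma must lie in [0, 1]")
        if self.beta < 0 or self.betaR < 0 or self.beta + self.betaR > 1 + 1e-12:
            raise ValueError("need beta, betaR >= 0 and beta + betaR <= 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FULL_VARS], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "FullState":
        return cls(**dict(zip(FULL_VARS, map(float, y))))


def full_rhs(y: np.ndarray, U: float, p: ParameterSet,
             kS2starAf: float = 0.1, kS2starAb: float = 1.0) -> np.ndarray:
    """Time derivatives of the 15-variable model.

    Purely algebraic; ``y`` is in :data:`FULL_VARS` order.  The identity
    ``dJ/dt + dJ*/dt + dc1/dt = 0`` holds exactly (conservation of total JAK
    material), and the gene-state subsystem preserves the simplex
    ``alpha, sigma in [0,1]``, ``beta + betaR <= 1``.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_FULL,):
        raise ValueError(f"expected state of length {N_FULL}, got {y.shape}")
    if not np.all(np.isfinite(y)) or not np.isfinite(U):
        raise ValueError("non-finite state or input")

    (Jstar, J, S, c1, c2, S2star, A, B,
     malpha, mbeta, msigma, alpha, beta, betaR, sigma) = y

    bind = p.kc1f * Jstar * S * S        # J* + 2S -> c1
    unbind = p.kc1b * c1                 # c1 -> J* + 2S
    release = p.kc1 * c1                 # c1 -> J* + S2*
    seq_f = kS2starAf * S2star * A       # S2* + A -> c2
    seq_b = kS2starAb * c2

    dJstar = p.kUJf * U * J - p.kUJb * Jstar - bind + unbind + release
    dJ = -p.kUJf * U * J + p.kUJb * Jstar
    dS = (-2.0 * bind + 2.0 * unbind + 2.0 * p.kS2star * S2star
          + p.kS * msigma - p.deltaS * S)
    dc1 = bind - unbind - release
    dc2 = seq_f - seq_b
    dS2star = release - p.kS2star * S2star - seq_f + seq_b
    dA = p.kA * malpha - p.deltaA * A - seq_f + seq_b
    dB = p.kB * mbeta - p.deltaB * B
    dmalpha = (p.kmalpha * (1.0 - alpha) - p.deltamalpha * malpha
               + p.malpha0 - p.deltaBalpha * B * B * malpha)
    dmbeta = (p.kmbeta * (1.0 - beta - betaR) - p.deltambeta * mbeta
              + p.mbeta0 - p.deltaAbeta * A * mbeta)
    dmsigma = (p.kmsigma * (1.0 - sigma) - p.deltamsigma * msigma
               + p.msigma0 - p.deltaAsigma * A * msigma)
    dalpha = -p.kalphaf * S2star * alpha + p.kalphab * (1.0 - alpha)
    # the slbo gene shuttles between free (beta), transcribing (1-beta-betaR)
    # and APT-repressed (betaR) states; the repression exchange must appear
    # in both dbeta and dbetaR or the occupancy simplex is not preserved
    dbeta = (-p.kbetaf * S2star * beta + p.kbetab * (1.0 - beta - betaR)
             - p.kbetaRf * A * beta + p.kbetaRb * betaR)
    dbetaR = p.kbetaRf * A * beta - p.kbetaRb * betaR
    dsigma = -p.ksigmaf * S2star * sigma + p.ksigmab * (1.0 - sigma)

    return np.array([dJstar, dJ, dS, dc1, dc2, dS2star, dA, dB,
                     dmalpha, dmbeta, dmsigma, dalpha, dbeta, dbetaR, dsigma])


def full_state_at_qss(S: float, A: float, B: float, U: float,
                      p: ParameterSet) -> FullState:
    """Full state with every fast variable at its quasi-steady state.

    Uses exact JAK conservation (``J + J* + c1 = JT``) rather than the
    Michaelis–Menten shortcut, so the slow projection of :func:`full_rhs`
    at this state isolates the reduction error of the minimal model.
    """
    if min(S, A, B, U) < 0:
        raise ValueError("S, A, B, U must be >= 0")
    u = p.kUJf * U / p.kUJb
    Km = (p.kc1b + p.kc1) / p.kc1f
    J = p.JT / (1.0 + u + u * S * S / Km)
    Jstar = u * J
    c1 = u * J * S * S / Km
    S2star = p.kc1 * c1 / p.kS2star
    # gene occupancies and mRNAs conditioned on (S2*, A, B)
    from .reduction import gene_qss, mrna_qss
    g = gene_qss(S2star, A, p)
    malpha, mbeta = mrna_qss(g.alphaStar, g.betaStar, A, B, p)
    msigma = ((p.kmsigma * (1.0 - g.sigma) + p.msigma0)
              / (p.deltamsigma + p.deltaAsigma * A))
    return FullState(
        Jstar=Jstar, J=J, S=S, c1=c1, c2=0.0, S2star=S2star, A=A, B=B,
        malpha=malpha, mbeta=mbeta, msigma=msigma,
        alpha=1.0 - g.alphaStar, beta=g.beta, betaR=g.betaR, sigma=g.sigma,
    )


def default_initial_full_state(p: ParameterSet, S0: float, A0: float,
                               B0: float) -> FullState:
    """Resting initial condition given initial protein concentrations.

    JAK starts as an unbound pool (``J = JT``), all complexes and the active
    dimer at zero, all genes fully inactive (``alpha = beta = sigma = 1``,
    ``betaR = 0``), and the mRNAs at their quasi-steady state conditioned on
    the initial proteins (with inactive genes the only production is basal).
    """
    if min(S0, A0, B0) < 0:
        raise ValueError("initial protein concentrations must be >= 0")
    malpha = p.malpha0 / (p.deltamalpha + p.deltaBalpha * B0 * B0)
    mbeta = p.mbeta0 / (p.deltambeta + p.deltaAbeta * A0)
    msigma = p.msigma0 / (p.deltamsigma + p.deltaAsigma * A0)
    return FullState(
        Jstar=0.0, J=p.JT, S=S0, c1=0.0, c2=0.0, S2star=0.0,
        A=A0, B=B0, malpha=malpha, mbeta=mbeta, msigma=msigma,
        alpha=1.0, beta=1.0, betaR=0.0, sigma=1.0,
    )
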