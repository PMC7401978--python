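# Methods

## The biological switch

During *Drosophila* oogenesis, anterior polar cells secrete the cytokine
Unpaired (UPD), which activates JAK/STAT signalling in neighbouring
follicle cells. Activated STAT dimers turn on two antagonistic
transcription factors: SLBO, which drives border-cell motility, and APT,
which keeps cells stationary and feeds back on STAT itself (via an
APT-activated miRNA that degrades *stat* mRNA). APT and SLBO
cross-repress: APT silences the *slbo* gene and degrades its mRNA, while
SLBO cooperatively destabilizes *apt* mRNA (a B² term, presumed
miRNA-mediated). The cross-repression makes cell fate a bistable switch:
the same UPD level can produce a motile (high-SLBO/high-STAT) or a
stationary (high-APT) cell depending on initial protein levels.

## Models

**15-variable mechanistic model** (`fullmodel`). Mass-action kinetics for
JAK activation by UPD, JAK–STAT complex formation, STAT dimerization,
APT sequestration of the active dimer (the `c2` complex), protein
translation/degradation, mRNA production/degradation (with the
miRNA-dependent degradation terms), and three gene-state subsystems
(inactive/transcribing occupancy for *apt* and *stat*;
inactive/transcribing/repressed for *slbo*). Concentrations are nM, time
is minutes. Two deliberate modelling choices:

* *Gene-occupancy conservation.* The *slbo* gene shuttles among free,
  transcribing and APT-repressed states. The repression exchange
  (`kbetaRf·A·beta − kbetaRb·betaR`) appears in **both** the `beta` and
  `betaR` equations. Writing it only in `betaR` (a formulation that has
  the same quasi-steady state and so is indistinguishable at equilibrium)
  destroys the occupancy simplex dynamically: from a resting gene state
  with tens of nM APT, `betaR` transiently overshoots to values around
  −3…+10, which also corrupts *slbo* transcription through the
  `(1 − beta − betaR)` factor. The conservative form keeps
  `alpha, sigma ∈ [0,1]` and `beta + betaR ≤ 1` invariant (verified along
  trajectories) without changing any steady state.
* *Dimer sequestration rates.* The APT–dimer binding rates are not part
  of the 33-parameter calibration. They cancel identically at any
  equilibrium (the forward and backward fluxes balance), so they affect
  transients and basin membership only. The defaults
  (`kS2starAf = 0.1 /nM/min`, `kS2starAb = 1 /min`) sit at the same scale
  as the other protein-complex kinetics in the calibration and give a
  fast, weakly bound buffer; with them the mechanistic model reproduces
  the documented fate dichotomy of the reference cell (motile at UPD = 4,
  stationary at UPD = 1). Setting both to zero decouples the complex,
  which is how the steady-state invariance is tested.

**Quasi-steady-state reduction** (`reduction`). STAT–DNA binding
(~100/min) and mRNA turnover are much faster than protein turnover
(~0.04–0.3/min). Setting the fast derivatives to zero gives, in stages:
algebraic gene occupancies (equilibrium constants K = k_f/k_b), mRNA
levels, a two-variable APT/SLBO model at fixed dimer level, and — after
collapsing JAK activation (saturating in UPD with half-saturation
`KUJ = kUJb/kUJf ≈ 7.52 nM`) and dimerization — the minimal three-variable
model in (STAT, APT, SLBO).

Two interpretation switches are exposed because the source material for
this pathway admits both readings:

* `printed_k` uses reciprocal (backward/forward) equilibrium constants.
  Under that orientation the occupancy formulas are not the QSS solutions
  of the gene ODEs, APT barely responds to STAT (knockdown ratio ≈ 1
  instead of ≈ 0.5), and the switch degenerates; it exists for comparison
  only.
* `km_squared` controls the dimer-activation saturation. The default
  treats `Km = (kc1b + kc1)/kc1f = 100.1` as the Michaelis constant of
  the two-monomer binding step, which carries units of nM² (half
  saturation at S = √Km ≈ 10 nM): production is `vmax·S²/(S² + Km)` with
  `vmax = kc1·J*`. The variant squares the same number (half saturation
  at 100.1 nM). Under the variant the reference initial condition
  (S, A, B) = (12, 56, 1.5) at UPD = 4 falls into the stationary basin and
  STAT never activates — inconsistent with every dynamical property this
  package reproduces — so the Michaelis reading is the default.

## Analyses

**Steady states and continuation** (`equilibria`). Equilibria are found
by damped multistart Newton from a log-spaced lattice (8³ by default,
vectorized), deduplicated, polished to residual < 1e-12 and classified by
the eigenvalues of a central finite-difference Jacobian (relative step
1e-6, floor 1e-9). Branches are continued in UPD by pseudo-arclength
predictor–corrector steps (initial 0.05, adaptive halving on corrector
failure, cap 0.5, coordinates scaled by the closed-form dissipative
bounds). A fold is detected where the tangent's UPD-component changes
sign; because dU/ds vanishes at the fold itself, the location is refined
by bisection in arclength on that sign rather than on |ΔU|. The bistable
interval is the UPD range with two coexisting stable states, with edges
bisected to 1e-3 nM; it agrees with the continuation folds to ~1e-3.

With the baseline calibration the model is bistable for
UPD ∈ (0.0016, 7.873) nM: the motile branch is born just above zero UPD
and the stationary branch terminates at the upper fold, beyond which every
cell is motile. At UPD = 0 the single (stationary) state has
APT ≈ 44.36 nM, rising steeply along the branch to ≈ 90 nM by UPD ≈ 1.

**Fate classification and experiments** (`dynamics`). Stiff integration
(LSODA, rtol 1e-8/atol 1e-10, ≥ 200 output samples). A trajectory is
motile/stationary when its endpoint lies within 5% relative distance of
the corresponding attractor by the deadline (500 min for basin work — an
experimentally reasonable specification window — 1000 min or more for the
miRNA experiment); otherwise unresolved, i.e. near the separatrix.
"Equilibrated" is operationalized as entry into a 5% band around the
final value; "elevated" STAT means above the saddle's STAT level. The
miRNA experiment reports GO (converges elevated), SLOW (converges but
more than twice the baseline time) and STOP (no elevation by the
horizon); with the shipped model the GO→STOP boundary from the reference
initial condition at UPD = 4 lies at `deltaAsigma ≈ 0.2018`, and delays
grow without bound as that boundary is approached (e.g. ≈ 245 min extra
at 0.2016). STAT knockdown (kS = 0) from the stationary state at UPD = 1
drops APT from ≈ 90 to ≈ 44 nM (ratio 0.49); at UPD = 0.1 the stationary
STAT level is ≈ 3.9 nM and the final STAT level is non-increasing in the
initial APT load.

**Robustness scan** (`robustness`). One-at-a-time bistable ranges by
outward geometric march plus bisection (relative tolerance 1e-2, floor
baseline/10⁴, cap 1100). Because "maintains bistability" is genuinely
underdetermined, two criteria are implemented: a nonempty bistable UPD
interval on [0, 50] (default), and bistability at a fixed reference
UPD = 4. Both are reported; they disagree for parameters whose effect is
to *translate* the bistable window in UPD rather than destroy it — under
the interval criterion such parameters (including `deltaAsigma`) have
ranges hitting the search caps, because some shifted window always
survives. Sensitivity orderings therefore depend strongly on the
criterion, and neither criterion singles out `deltaAsigma` as the most
constrained parameter in this implementation.

**Basins and separatrix** (`basins`). A deterministic lattice of initial
conditions over S ∈ [0, 250], A ∈ [0, 120], B ∈ [0, 60] (21³ by default;
the test suite uses 7³–17³ to stay fast) is classified by event-terminated
integration (solver stops on entry into either attractor's tolerance
ball). Near-separatrix points are the unresolved points plus midpoints of
opposite-fate lattice edges (switchable off, since the strict
non-converged set can be tiny on coarse grids). The implicit surface is
fitted by total least squares — plane via the smallest singular direction
of the centred cloud, quadric via the unit-norm null vector of the
monomial design — and scored by the fraction of resolved grid points it
sides correctly ("near-planar" operationalized as ≥ 90%; measured ≈ 98%
at UPD = 4). The motile basin volume fraction grows monotonically with
UPD (≈ 0.17 → 0.78 → 0.91 across 0.0133, 0.133, 4 on a 9³ grid), and the
plane's normal lies within 25° of the normal of the saddle's stable
eigenplane. The shift report's probe side is decided by integrating the
probe (its true basin), not by the plane sign, because the interesting
probes sit closer to the separatrix than the fit error.

## Numerical choices and degenerate inputs

Parameters are validated as nonnegative with strictly positive
degradation rates and JAK pool (so steady states are finite). Newton
iterates are clipped to a positive box bounded by ten times the
dissipative bounds. Root deduplication uses 1e-4 relative distance.
Components converging to zero get an absolute floor (1e-6 nM) on the
convergence band. Monostable conditions make `classify_grid` raise and
are skipped with a note in the shift report; a missing basin boundary
yields an empty near-manifold set with a warning. All analyses are
deterministic — there is no random number generation anywhere in the
pipeline — so repeated runs are byte-identical.

## What the suite does and does not show

All inputs are model-generated; no experimental data enters. Passing
tests show the implemented equations have the stated dynamical structure
(bistability, folds, separatrix geometry, delay-near-threshold), not that
real border cells obey them. Known limitations: the mechanistic model's
bistable window is narrower than the reduced model's (its exact dimer
kinetics are stronger than the Michaelis form at high STAT, so its upper
fold sits below UPD = 4 and the stationary state there is only
metastable); UPD is a constant input with no spatial gradient or
dynamics; no stochastic version is provided; and the APT–dimer
sequestration rates are order-of-magnitude choices, constrained only by
the qualitative transient behaviour they must reproduce.
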