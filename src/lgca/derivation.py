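"""Deriving reorientation probabilities from potentials and from data.

Two routes produce LGCA reorientation rules:

1. **Biophysical route.** Overdamped self-propelled-particle models describe
   a cell's orientation θ by a Langevin equation with an interaction
   potential U and rotational noise.  Assuming fast relaxation, the
   orientation distribution is the stationary Fokker–Planck solution
   ``P(θ) ∝ exp(−β U(θ))`` with sensitivity ``β = γ/D_θ``.  Discretising
   orientations onto the lattice directions and assuming independent channel
   occupations yields outcome weights ``exp(−β Σ_j U(c_j) s_j^O)`` over
   mass-conserving node configurations.  For cosine potentials
   ``U = −C cos^n(θ − φ)`` the energy takes the director-field form
   ``β J(s^O)·G`` (n = 1, polar) or ``β N(s^O)·G`` (n = 2, nematic) with
   ``‖G‖ = C`` and ``arg G = φ``.

2. **Data-driven route (maximum caliber).** Given a dynamic observable
   ``Ũ(s_i | s_N)`` per channel and its experimentally measured values
   ``E_j`` per time step, the maximum-path-entropy distribution is
   ``P ∝ exp(β(j) Ũ)`` with the Lagrange multiplier β(j) fixed by the
   constraint ``⟨Ũ⟩ = E_j``.  Time-independent observables give a constant
   multiplier.  When ``Ũ(s_i|s_N) = s_i c_i·G(s_N)`` the two routes coincide.

The Langevin/Fokker–Planck dynamics themselves are not simulated; only the
stationary solution enters.  Independence of channel occupations is an
approximation inherited when factorising multi-cell outcomes.  All weights
are handled in log-space, so large multipliers do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import log_softmax, softmax

from .errors import DomainError, NumericalError, StructuralError
from .lattice import LatticeGeometry
from .operators import ReorientationDistribution, _log_softmax_rows, _outcome_table
from .rules import DirectorFieldRule

__all__ = [
    "PotentialSpec",
    "MaxCalProblem",
    "cosine_potential",
    "stationary_orientation_distribution",
    "reorientation_from_potential",
    "director_field_form",
    "maxcal_expectation",
    "maxcal_multipliers",
    "maxcal_reorientation_distribution",
    "persistence_rule_from_autocorrelation",
    "sample_channel_choices",
    "fit_multiplier_from_samples",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Cosine-family interaction potential ``U(θ) = −C cos^n(θ − φ)``.

    ``C`` is the interaction strength, ``φ`` the optimal orientation and
    ``n ∈ {1, 2}`` the order (polar vs nematic); the sensitivity is
    ``β = γ/D_θ`` (relaxation constant over rotational diffusion).
    """

    C: float
    phi: float = 0.0
    order: int = 1
    beta: float = 1.0

    def __post_init__(self):
        if self.C < 0:
            raise DomainError("interaction strength C must be >= 0")
        if self.order not in (1, 2):
            from .errors import CapabilityError

            raise CapabilityError("cosine potential order must be 1 or 2")
        if self.beta <= 0:
            raise DomainError("sensitivity beta = gamma/D_theta must be > 0")

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return -self.C * np.cos(np.asarray(theta, dtype=float) - self.phi) ** self.order


def cosine_potential(C: float, phi: float = 0.0, order: int = 1) -> Callable:
    """Potential ``U(θ) = −C cos^n(θ − φ)`` as a plain callable."""
    return PotentialSpec(C=C, phi=phi, order=order)


def stationary_orientation_distribution(
    potential: Callable[[np.ndarray], np.ndarray],
    beta: float,
    n_grid: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary orientation density ``P(θ) ∝ exp(−β U(θ))`` on a θ grid.

    Returns ``(theta, pdf)`` with ``sum(pdf) * Δθ = 1``.
    """
    if beta <= 0:
        raise DomainError("beta must be > 0")
    if n_grid < 8:
        raise DomainError("grid resolution must be >= 8")
    theta = np.linspace(0.0, 2 * np.pi, n_grid, endpoint=False)
    U = np.asarray(potential(theta), dtype=float)
    if not np.all(np.isfinite(U)):
        raise NumericalError("potential evaluated to non-finite values")
    log_w = -beta * U
    pdf = softmax(log_w)
    dtheta = 2 * np.pi / n_grid
    return theta, pdf / dtheta


def reorientation_from_potential(
    U: Sequence[float],
    beta: float,
    geometry: LatticeGeometry,
    n: int,
) -> ReorientationDistribution:
    """Transition distribution with outcome weights ``exp(−β Σ_j U(c_j) s_j^O)``.

    ``U`` gives the potential per velocity channel (length ``b``); rest
    channels receive zero potential unless a full length-``K`` vector is
    supplied.  Outcomes range over all configurations with ``n`` cells.
    """
    U = np.asarray(U, dtype=float).ravel()
    if U.size == geometry.b:
        U = np.concatenate([U, np.zeros(geometry.a)])
    if U.size != geometry.K:
        raise StructuralError(
            f"potential length {U.size} != b = {geometry.b} or K = {geometry.K}"
        )
    if not np.all(np.isfinite(U)):
        raise NumericalError("non-finite potential values")
    table = _outcome_table(geometry.K, (int(n),))
    energies = (-beta * (table.astype(float) @ U))[None, :]
    probs, log_Z = _log_softmax_rows(energies)
    return ReorientationDistribution(
        outcomes=table, probabilities=probs[0], log_Z=float(log_Z[0])
    )


def director_field_form(
    C: float, phi: float, order: int, beta: float = 1.0
) -> DirectorFieldRule:
    """Rule energy induced by the cosine potential family.

    Order 1 gives the polar form ``β J(s^O)·G``, order 2 the nematic form
    ``β N(s^O)·G``, with director ``G = C (cos φ, sin φ)``.
    """
    if order not in (1, 2):
        from .errors import CapabilityError

        raise CapabilityError("only cosine orders n = 1 (polar), 2 (nematic)")
    G = C * np.array([np.cos(phi), np.sin(phi)])
    return DirectorFieldRule(G=G, beta=beta, nematic=(order == 2))


# -- maximum caliber --------------------------------------------------------

@dataclass
class MaxCalProblem:
    """Max-caliber constraint problem for one observable.

    ``observable`` holds the per-channel observable values Ũ(s_i | s_N)
    (length ``b`` or ``K``); ``targets`` the measured expectation(s) E_j,
    one per time step or a single time-independent value.  ``multipliers``
    is filled by :func:`maxcal_multipliers`.
    """

    observable: np.ndarray
    targets: np.ndarray
    multipliers: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.observable = np.asarray(self.observable, dtype=float).ravel()
        self.targets = np.atleast_1d(np.asarray(self.targets, dtype=float))


def maxcal_expectation(u: np.ndarray, beta: float) -> float:
    """Forward map: ``⟨Ũ⟩`` under ``P_i ∝ exp(β Ũ_i)`` (log-space)."""
    u = np.asarray(u, dtype=float)
    return float(np.exp(log_softmax(beta * u)) @ u)


def _solve_multiplier(u: np.ndarray, target: float, tol: float) -> float:
    lo, hi = float(u.min()), float(u.max())
    if hi == lo:
        if not np.isclose(target, lo):
            raise DomainError(
                f"target {target} unattainable: observable is constant {lo}"
            )
        return 0.0
    if not lo < target < hi:
        raise DomainError(
            f"target {target} outside the attainable open interval "
            f"({lo}, {hi}) of the observable"
        )
    f = lambda b: maxcal_expectation(u, b) - target
    a, c = -1.0, 1.0
    fa, fc = f(a), f(c)
    # ⟨Ũ⟩ is monotone increasing in β (its derivative is the variance), so a
    # geometric bracket expansion always finds a sign change.
    for _ in range(200):
        if fa <= 0.0 <= fc:
            break
        a *= 2.0
        c *= 2.0
        fa, fc = f(a), f(c)
    else:
        raise NumericalError("failed to bracket the max-caliber multiplier")
    return float(brentq(f, a, c, xtol=tol, rtol=8.881784197001252e-16))


def maxcal_multipliers(
    problem: MaxCalProblem,
    geometry: LatticeGeometry | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Fit the Lagrange multipliers β(j) so that ``⟨Ũ⟩_{P_j} = E_j``.

    ``P_j ∝ exp(β(j) Ũ)`` per time step j; a time-independent target yields a
    constant multiplier.  The one-dimensional root problem is monotone and is
    solved by bracketed bisection/Brent to ``tol``.  Targets outside the open
    range of the observable raise :class:`DomainError` naming the feasible
    interval.
    """
    u = problem.observable
    betas = np.array([_solve_multiplier(u, t, tol) for t in problem.targets])
    problem.multipliers = betas
    return betas


def maxcal_reorientation_distribution(
    u: Sequence[float],
    beta: float,
    geometry: LatticeGeometry,
    n: int,
) -> ReorientationDistribution:
    """Node-level outcome distribution ``P(s^O) ∝ exp(β Σ_i Ũ_i s_i^O)``.

    Assumes independent cells within a node; ``u`` is the per-channel
    observable (length ``b``, zero-extended to rest channels, or ``K``).
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.size == geometry.b:
        u = np.concatenate([u, np.zeros(geometry.a)])
    if u.size != geometry.K:
        raise StructuralError(
            f"observable length {u.size} != b = {geometry.b} or K = {geometry.K}"
        )
    table = _outcome_table(geometry.K, (int(n),))
    energies = (beta * (table.astype(float) @ u))[None, :]
    probs, log_Z = _log_softmax_rows(energies)
    return ReorientationDistribution(
        outcomes=table, probabilities=probs[0], log_Z=float(log_Z[0])
    )


def persistence_rule_from_autocorrelation(
    g: Sequence[float],
    d: int,
    c_i0: Sequence[float] | int,
    geometry: LatticeGeometry,
) -> np.ndarray:
    """Per-step channel probabilities from a velocity autocorrelation series.

    For the observable ``g(k) = ⟨v_0 · v_k⟩`` the max-caliber channel
    probabilities are ``P_{i,k} ∝ exp(d g(k) (c_i0 · c_i))`` over the ``b``
    lattice directions.  Returns an array of shape ``(len(g), b)``.
    Computed in log-space, so large ``|g|`` cannot overflow.
    """
    g = np.asarray(g, dtype=float).ravel()
    if not np.all(np.isfinite(g)):
        raise NumericalError("autocorrelation series contains non-finite values")
    c = geometry.velocity_vectors[: geometry.b].astype(float)
    if np.isscalar(c_i0):
        c0 = c[int(c_i0)]
    else:
        c0 = np.asarray(c_i0, dtype=float)
        if c0.shape != (geometry.dimension,):
            raise StructuralError(
                f"initial direction shape {c0.shape} != ({geometry.dimension},)"
            )
    overlaps = c @ c0  # (b,)
    log_w = d * g[:, None] * overlaps[None, :]
    return softmax(log_w, axis=1)


def sample_channel_choices(
    u: Sequence[float], beta: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Synthetic data generator: channel indices drawn from ``P ∝ exp(β Ũ)``.

    Emulates observed single-cell channel choices under a known multiplier —
    the forward model whose inversion :func:`fit_multiplier_from_samples`
    tests.
    """
    u = np.asarray(u, dtype=float)
    p = softmax(beta * u)
    return rng.choice(u.size, size=size, p=p)


def fit_multiplier_from_samples(
    u: Sequence[float], choices: np.ndarray, tol: float = 1e-10
) -> float:
    """Recover the multiplier from sampled channel choices.

    The empirical mean of the observable over the observed choices is the
    max-caliber target; the multiplier solves the constraint equation.
    """
    u = np.asarray(u, dtype=float)
    target = float(u[np.asarray(choices, dtype=int)].mean())
    problem = MaxCalProblem(observable=u, targets=target)
    return float(maxcal_multipliers(problem)[0])
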