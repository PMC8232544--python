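"""Mean-field and linear-stability machinery.

Two analytical tracks are implemented, both for 1D lattices (b = 2) in the
low-density single-particle regime (at most one cell per node, weak
interaction), where the automaton's expected dynamics close on the mean
local density.

**Adhesion model.**  Linearising the adhesion rule's transition probability
and taking expectations yields a finite-difference equation (FDE) for the
mean density ρ(r, k) with a five-point stencil.  A discrete Fourier
transform of the linearised FDE gives the per-step growth factor of mode κ

    g(κ) = (2/K) [2βρ̄ − 1 + cos κ − 2βρ̄ cos²κ],

which vanishes at κ = 0 (mass conservation).  Setting dg/dκ = 0 gives the
dominant wavenumber condition ``cos κ_c = 1/(4βρ̄)``, valid for βρ̄ ≥ 1/4;
the critical wavelength λ_c = 2π/κ_c diverges at the aggregation threshold
(βρ̄)_c = 1/4 and tends to 4 lattice sites as βρ̄ → ∞.

**Invasion model.**  For the combined aggregation/alignment/resting rule the
mean-field dynamics is the lattice-Boltzmann equation (LBE)

    f_j(r + c_j, k+1) = ρ(r, k) T_j,

with single-particle probabilities T_j built from the rule energies.  Its
homogeneous steady state solves ``f_r = ρ̄ Π_r / (2 + a Π_r)`` with
``Π_r = exp(2 β_rest a f_r)``.  Linearising the LBE around the steady state
and Fourier-transforming yields the K×K Boltzmann propagator Γ(q) whose
eigenvalues Λ determine stability (|Λ| > 1: pattern growth at wavelength
2π/q) and the travelling (arg Λ ≠ 0) versus stationary character of the
unstable mode — giving the four migration phases: diffusive, collective,
aggregation and jammed.  Propagator derivatives are analytic with a built-in
central finite-difference cross-check on the real-space LBE map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, NumericalError

__all__ = [
    "AdhesionMeanFieldParams",
    "CriticalMode",
    "DispersionResult",
    "InvasionParams",
    "InvasionSteadyState",
    "PropagatorSpectrum",
    "PhaseResult",
    "PHASE_LABELS",
    "adhesion_fde_trajectory",
    "adhesion_growth_rate",
    "adhesion_dispersion",
    "adhesion_critical",
    "invasion_steady_state",
    "invasion_lbe_step",
    "invasion_propagator",
    "validate_invasion_propagator",
    "classify_phase",
    "phase_diagram",
]


# -- adhesion model ---------------------------------------------------------

@dataclass(frozen=True)
class AdhesionMeanFieldParams:
    """Parameters of the 1D adhesion mean-field model (b = 2, K = a + 2)."""

    beta: float
    rho_bar: float
    a: int = 0

    def __post_init__(self):
        if self.beta < 0 or self.rho_bar < 0:
            raise DomainError("beta and mean density must be non-negative")
        if self.a < 0:
            raise ConfigurationError("rest channels a must be >= 0")

    @property
    def K(self) -> int:
        return self.a + 2


def adhesion_fde_trajectory(
    rho0: np.ndarray, beta: float, a: int, steps: int
) -> np.ndarray:
    """Iterate the adhesion mean-field finite-difference equation.

    ``ρ(r,k+1) = (a/K)ρ(r) + (1/K)[ρ(r−1)+ρ(r+1)]
    + (β/K){ρ(r−1)[ρ(r)−ρ(r−2)] + ρ(r+1)[ρ(r)−ρ(r+2)]}``
    with periodic indexing.  Total density is conserved.  Returns an array of
    shape ``(steps+1, L)``.
    """
    rho = np.asarray(rho0, dtype=float).ravel()
    if rho.size < 5:
        raise ConfigurationError(
            "density profile must have at least 5 nodes (stencil width)"
        )
    K = a + 2
    if np.any(rho < 0) or np.any(rho > K):
        raise ConfigurationError(f"initial densities must lie in [0, K={K}]")
    out = np.empty((steps + 1, rho.size))
    out[0] = rho
    for k in range(steps):
        rm1, rp1 = np.roll(rho, 1), np.roll(rho, -1)
        rm2, rp2 = np.roll(rho, 2), np.roll(rho, -2)
        rho = (
            (a / K) * rho
            + (rm1 + rp1) / K
            + (beta / K) * (rm1 * (rho - rm2) + rp1 * (rho - rp2))
        )
        out[k + 1] = rho
    return out


def adhesion_growth_rate(
    kappa: float | np.ndarray, beta: float, rho_bar: float, a: int = 0
) -> float | np.ndarray:
    """Per-step linear growth factor of a density mode with wavenumber κ.

    ``g(κ) = (2/K)[2βρ̄ − 1 + cos κ − 2βρ̄ cos²κ]``; positive values mean the
    perturbation at κ grows.  ``g(0) = 0`` exactly (mass conservation).
    """
    K = a + 2
    br = beta * rho_bar
    cos = np.cos(kappa)
    # algebraically equal to 2*br - 1 + cos - 2*br*cos^2, but exact at kappa=0
    return (2.0 / K) * ((cos - 1.0) + 2 * br * (1.0 - cos**2))


@dataclass(frozen=True)
class CriticalMode:
    """Dominant unstable mode of the adhesion dispersion relation."""

    kappa_c: float | None
    wavelength: float | None
    unstable: bool


@dataclass(frozen=True)
class DispersionResult:
    """Growth factor over a κ grid plus the critical-mode summary."""

    kappa: np.ndarray
    growth: np.ndarray
    critical: CriticalMode


def adhesion_critical(beta_rho: float) -> CriticalMode:
    """Dominant wavenumber and critical wavelength of the adhesion model.

    For βρ̄ > 1/4: ``κ_c = arccos(1/(4βρ̄))``, ``λ_c = 2π/κ_c``, unstable.
    At βρ̄ = 1/4 the dominant mode sits at κ → 0 (λ_c infinite, marginal);
    below the threshold no non-trivial mode grows.  λ_c decreases towards 4
    lattice sites as βρ̄ → ∞.
    """
    if beta_rho < 0:
        raise DomainError("beta * rho must be non-negative")
    quarter = 0.25
    if beta_rho > quarter:
        kappa_c = float(np.arccos(1.0 / (4.0 * beta_rho)))
        return CriticalMode(
            kappa_c=kappa_c, wavelength=2 * np.pi / kappa_c, unstable=True
        )
    if beta_rho == quarter:
        return CriticalMode(kappa_c=0.0, wavelength=np.inf, unstable=False)
    return CriticalMode(kappa_c=None, wavelength=None, unstable=False)


def adhesion_dispersion(
    beta: float, rho_bar: float, a: int = 0, n_kappa: int = 256
) -> DispersionResult:
    """Growth factor on a κ grid over (0, π] plus the critical mode."""
    kappa = np.linspace(0.0, np.pi, n_kappa + 1)[1:]
    growth = adhesion_growth_rate(kappa, beta, rho_bar, a)
    return DispersionResult(
        kappa=kappa, growth=growth, critical=adhesion_critical(beta * rho_bar)
    )


# -- invasion model ---------------------------------------------------------

@dataclass(frozen=True)
class InvasionParams:
    """Parameters of the 1D invasion model (b = 2, K = a + 2)."""

    beta_agg: float
    beta_align: float
    beta_rest: float
    rho_bar: float
    a: int
    n_crit: float

    def __post_init__(self):
        if self.a < 0:
            raise ConfigurationError("rest channels a must be >= 0")
        if self.beta_rest != 0.0 and self.a < 1:
            raise ConfigurationError(
                "resting interaction requires at least one rest channel"
            )
        if self.n_crit <= 0:
            raise ConfigurationError("n_crit must be positive")
        if not 0 < self.rho_bar <= self.K:
            raise ConfigurationError(
                f"mean density must lie in (0, K={self.K}]"
            )

    @property
    def K(self) -> int:
        return self.a + 2


@dataclass(frozen=True)
class InvasionSteadyState:
    """Homogeneous steady state of the invasion LBE."""

    rho_bar: float
    f_v: float
    f_r: float
    Pi_r: float
    residual: float


def invasion_steady_state(
    rho_bar: float,
    a: int,
    beta_rest: float,
    tol: float = 1e-14,
    max_iter: int = 10_000,
) -> InvasionSteadyState:
    """Solve the homogeneous LBE fixed point.

    ``f_r = ρ̄ Π_r / (2 + a Π_r)`` with ``Π_r = exp(2 β_rest a f_r)`` and
    ``f_v = ρ̄ / (2 + a Π_r)``; solved by damped fixed-point iteration
    (damping 0.5) with a bracketed bisection fallback.  The returned state
    satisfies both steady-state relations to better than 1e-12.
    """
    if rho_bar <= 0:
        raise DomainError("mean density must be positive")
    if a == 0 or beta_rest == 0.0:
        Pi = float(np.exp(0.0)) if a == 0 else 1.0
        f = rho_bar / (2.0 + a)
        return InvasionSteadyState(
            rho_bar=rho_bar, f_v=f, f_r=f if a else 0.0, Pi_r=1.0, residual=0.0
        )

    def rhs(fr: float) -> float:
        # rho * Pi / (2 + a*Pi) computed without overflowing exp
        x = 2.0 * beta_rest * a * fr
        if x >= 0:
            return rho_bar / (2.0 * np.exp(-x) + a)
        return rho_bar * np.exp(x) / (2.0 + a * np.exp(x))

    fr = rho_bar / (2.0 + a)
    damping = 0.5
    converged = False
    for _ in range(max_iter):
        new = (1.0 - damping) * fr + damping * rhs(fr)
        if abs(new - fr) < tol:
            fr = new
            converged = True
            break
        fr = new
    if not converged or abs(fr - rhs(fr)) > 1e-12:
        # bracketed bisection fallback on g(f) = f - rhs(f)
        lo, hi = 0.0, max(1.0, rho_bar / a) + 1.0
        g = lambda f: f - rhs(f)
        if g(lo) > 0 or g(hi) < 0:
            raise NumericalError(
                f"steady-state solver failed; residual {abs(fr - rhs(fr)):.3e}"
            )
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) <= 0:
                lo = mid
            else:
                hi = mid
        fr = 0.5 * (lo + hi)
    x = 2.0 * beta_rest * a * fr
    Pi = float(np.inf) if x > 709.0 else float(np.exp(x))
    fv = rho_bar * np.exp(-x) / (2.0 * np.exp(-x) + a) if x >= 0 else (
        rho_bar / (2.0 + a * Pi)
    )
    residual = max(abs(fr - rhs(fr)), abs(rho_bar - 2 * fv - a * fr))
    if residual > 1e-12:
        raise NumericalError(
            f"steady state did not converge: residual {residual:.3e}"
        )
    return InvasionSteadyState(
        rho_bar=rho_bar, f_v=fv, f_r=fr, Pi_r=Pi, residual=residual
    )


def _lbe_probabilities(
    F: np.ndarray, params: InvasionParams
) -> np.ndarray:
    """Single-particle probabilities T_j per node, shape (L, K).

    Channel order: +1, −1, then a rest channels.  Fields are built from the
    mean occupancies of the two lattice neighbours.
    """
    rho = F.sum(axis=1)
    j = F[:, 0] - F[:, 1]
    rest = F[:, 2:].sum(axis=1)
    rho_p, rho_m = np.roll(rho, -1), np.roll(rho, 1)
    g_agg = rho_p * (1 - rho_p / params.n_crit) - rho_m * (1 - rho_m / params.n_crit)
    g_align = np.roll(j, -1) + np.roll(j, 1)
    rest_N = np.roll(rest, -1) + np.roll(rest, 1)
    E = np.empty_like(F)
    drive = params.beta_agg * g_agg + params.beta_align * g_align
    E[:, 0] = drive
    E[:, 1] = -drive
    E[:, 2:] = (params.beta_rest * rest_N)[:, None]
    shift = E.max(axis=1, keepdims=True)
    w = np.exp(E - shift)
    return w / w.sum(axis=1, keepdims=True)


def invasion_lbe_step(F: np.ndarray, params: InvasionParams) -> np.ndarray:
    """One step of the mean-field lattice-Boltzmann map on a periodic 1D lattice.

    ``F`` holds expected channel occupancies, shape ``(L, K)`` with channel
    order (+1, −1, rest...).  Implements
    ``f_j(r + c_j, k+1) = ρ(r, k) T_j(r, k)``.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != params.K:
        raise ConfigurationError(f"F must have shape (L, K={params.K})")
    T = _lbe_probabilities(F, params)
    rho = F.sum(axis=1)
    post = rho[:, None] * T
    out = np.empty_like(post)
    out[:, 0] = np.roll(post[:, 0], 1)   # +1 movers arrive from r-1
    out[:, 1] = np.roll(post[:, 1], -1)  # -1 movers arrive from r+1
    out[:, 2:] = post[:, 2:]
    return out


@dataclass(frozen=True)
class PropagatorSpectrum:
    """Boltzmann propagator Γ(q), its eigenvalues and the dominant one."""

    q: float
    Gamma: np.ndarray
    eigenvalues: np.ndarray

    @property
    def dominant(self) -> complex:
        return self.eigenvalues[np.argmax(np.abs(self.eigenvalues))]


def _propagator_pieces(params: InvasionParams, steady: InvasionSteadyState):
    """Steady-state T vector and the q-independent derivative blocks.

    Returns ``(T, D_plus, D_minus)`` where ``D_±[m, n] = ρ̄ ∂T_m/∂f_n(r ± 1)``
    evaluated at the homogeneous steady state.
    """
    K = params.K
    a = params.a
    Z = 2.0 + a * steady.Pi_r
    T = np.empty(K)
    T[0] = T[1] = 1.0 / Z
    T[2:] = steady.Pi_r / Z

    # dE_m/df_n(r±1) at the steady state
    c_m = np.zeros(K)
    c_m[0], c_m[1] = 1.0, -1.0
    agg_slope = 1.0 - 2.0 * params.rho_bar / params.n_crit
    w_n = np.zeros(K)
    w_n[0], w_n[1] = 1.0, -1.0  # d j(r') / d f_n(r')
    rest_n = np.zeros(K)
    rest_n[2:] = 1.0

    def dE(sign: float) -> np.ndarray:
        # (K, K): row m, column n -> dE_m / df_n(r + sign*1)
        out = np.zeros((K, K))
        for m in range(2):
            out[m, :] = params.beta_agg * c_m[m] * sign * agg_slope
            out[m, :] += params.beta_align * c_m[m] * w_n
        out[2:, :] = params.beta_rest * rest_n[None, :]
        return out

    def dT(dEmat: np.ndarray) -> np.ndarray:
        s = T @ dEmat  # Σ_k T_k dE_k/df_n, shape (K,)
        return T[:, None] * (dEmat - s[None, :])

    D_plus = params.rho_bar * dT(dE(+1.0))
    D_minus = params.rho_bar * dT(dE(-1.0))
    return T, D_plus, D_minus


def invasion_propagator(
    q: float,
    params: InvasionParams,
    steady: InvasionSteadyState | None = None,
    validate: bool = False,
) -> PropagatorSpectrum:
    """Boltzmann propagator Γ(q) of the linearised LBE and its eigenvalues.

    ``Γ_{m,n}(q) = e^{−i c_m q} [T_m + Σ_{ℓ=±1} e^{i c_ℓ q}
    ρ̄ ∂T_m/∂f_n(r + c_ℓ)]`` with analytic derivatives evaluated at the
    homogeneous steady state.  With ``validate=True`` the analytic matrix is
    cross-checked against central finite differences of the real-space LBE
    map (step 1e-6) and a :class:`NumericalError` is raised on disagreement
    above 1e-5.
    """
    if steady is None:
        steady = invasion_steady_state(params.rho_bar, params.a, params.beta_rest)
    T, D_plus, D_minus = _propagator_pieces(params, steady)
    K = params.K
    c = np.zeros(K)
    c[0], c[1] = 1.0, -1.0
    phase_m = np.exp(-1j * c * q)
    Gamma = phase_m[:, None] * (
        T[:, None] * np.ones((1, K))
        + np.exp(1j * q) * D_plus
        + np.exp(-1j * q) * D_minus
    )
    if validate:
        fd = _finite_difference_propagator(q, params, steady)
        err = np.abs(Gamma - fd).max()
        if err > 1e-5:
            raise NumericalError(
                f"analytic propagator disagrees with finite differences "
                f"(max abs error {err:.3e} at q={q})"
            )
    return PropagatorSpectrum(q=q, Gamma=Gamma, eigenvalues=np.linalg.eigvals(Gamma))


def _finite_difference_propagator(
    q: float,
    params: InvasionParams,
    steady: InvasionSteadyState,
    L: int = 16,
    h: float = 1e-6,
) -> np.ndarray:
    """Γ(q) from central finite differences of the real-space LBE map."""
    K = params.K
    F0 = np.empty((L, K))
    F0[:, 0] = F0[:, 1] = steady.f_v
    F0[:, 2:] = steady.f_r
    r0 = L // 2
    J = np.zeros((L, K, K))  # J[r', m, n] = d f_m(r') / d f_n(r0)
    for n in range(K):
        Fp, Fm = F0.copy(), F0.copy()
        Fp[r0, n] += h
        Fm[r0, n] -= h
        J[:, :, n] = (invasion_lbe_step(Fp, params) - invasion_lbe_step(Fm, params)) / (
            2 * h
        )
    delta = (np.arange(L) - r0 + L // 2) % L - L // 2  # r' - r0, minimal image
    phases = np.exp(-1j * q * delta)
    return np.tensordot(phases, J, axes=(0, 0))


def validate_invasion_propagator(
    params: InvasionParams,
    q_values: np.ndarray | None = None,
    tol: float = 1e-5,
) -> float:
    """Max abs deviation between analytic and finite-difference Γ over q values.

    Raises :class:`NumericalError` above ``tol``.
    """
    steady = invasion_steady_state(params.rho_bar, params.a, params.beta_rest)
    if q_values is None:
        q_values = np.array([0.0, np.pi / 3, np.pi, 4.9])
    worst = 0.0
    for q in np.atleast_1d(q_values):
        analytic = invasion_propagator(float(q), params, steady).Gamma
        fd = _finite_difference_propagator(float(q), params, steady)
        worst = max(worst, float(np.abs(analytic - fd).max()))
    if worst > tol:
        raise NumericalError(
            f"propagator validation failed: max abs error {worst:.3e} > {tol}"
        )
    return worst


# -- phase classification ---------------------------------------------------

PHASE_LABELS = ("diffusive", "collective", "aggregation", "jammed")


@dataclass(frozen=True)
class PhaseResult:
    """Outcome of the linear-stability phase classification."""

    label: str
    max_modulus: float
    q_star: float
    dominant: complex
    steady: InvasionSteadyState


def _spectra_over_grid(
    params: InvasionParams, steady: InvasionSteadyState, q_grid: np.ndarray
) -> np.ndarray:
    """Eigenvalues for every q in one vectorised eigensolve, (len(q), K)."""
    T, D_plus, D_minus = _propagator_pieces(params, steady)
    K = params.K
    c = np.zeros(K)
    c[0], c[1] = 1.0, -1.0
    phase_m = np.exp(-1j * np.outer(q_grid, c))  # (Q, K)
    base = T[None, :, None] * np.ones((1, K, K))
    mats = phase_m[:, :, None] * (
        base
        + np.exp(1j * q_grid)[:, None, None] * D_plus[None]
        + np.exp(-1j * q_grid)[:, None, None] * D_minus[None]
    )
    return np.linalg.eigvals(mats)


def classify_phase(
    beta_agg: float,
    beta_align: float,
    beta_rest: float,
    rho_bar: float,
    a: int,
    n_crit: float,
    q_points: int = 256,
    rest_fraction_threshold: float = 0.75,
    arg_tolerance: float = 1e-6,
    stability_eps: float = 1e-9,
    validate: bool = True,
) -> PhaseResult:
    """Classify the migration mode of the invasion model at one parameter set.

    Stable everywhere (max_{q≠0} |Λ| ≤ 1 + ε): ``jammed`` if the resting
    fraction a·f_r/ρ̄ of the steady state is ≥ the threshold, else
    ``diffusive``.  Unstable: ``collective`` if the dominant mode travels
    (non-zero argument of Λ at the maximising q) or is a homogeneous-drift
    mode — the flux instability whose maximum sits at the edge of the q
    grid (κ → 0, or its staggered-momentum aliases at q = π and 2π − κ;
    the dispersion analysis treats κ = 0, π as trivial solutions).
    Otherwise the unstable mode is a stationary finite-wavelength pattern:
    ``aggregation``.  Thresholds are configurable; they are classification
    conventions, not model parameters.
    """
    if q_points < 256:
        raise ConfigurationError("q grid must have at least 256 points")
    params = InvasionParams(
        beta_agg=beta_agg,
        beta_align=beta_align,
        beta_rest=beta_rest,
        rho_bar=rho_bar,
        a=a,
        n_crit=n_crit,
    )
    steady = invasion_steady_state(rho_bar, a, beta_rest)
    if validate:
        validate_invasion_propagator(params, q_values=np.array([np.pi / 3]))
    q_grid = 2 * np.pi * np.arange(1, q_points) / q_points  # (0, 2π) open
    eigs = _spectra_over_grid(params, steady, q_grid)
    mods = np.abs(eigs)
    flat = np.argmax(mods)
    qi, ei = np.unravel_index(flat, mods.shape)
    max_mod = float(mods[qi, ei])
    dominant = complex(eigs[qi, ei])
    q_star = float(q_grid[qi])
    if max_mod <= 1.0 + stability_eps:
        rest_fraction = a * steady.f_r / rho_bar if rho_bar > 0 else 0.0
        label = "jammed" if rest_fraction >= rest_fraction_threshold else "diffusive"
    else:
        dq = q_grid[0]
        edge = min(q_star, abs(q_star - np.pi), 2 * np.pi - q_star) <= 1.5 * dq
        travelling = abs(np.angle(dominant)) > arg_tolerance
        label = "collective" if (travelling or edge) else "aggregation"
    return PhaseResult(
        label=label,
        max_modulus=max_mod,
        q_star=q_star,
        dominant=dominant,
        steady=steady,
    )


def phase_diagram(
    beta_agg_values: np.ndarray,
    beta_align_values: np.ndarray,
    beta_rest_levels: np.ndarray,
    rho_bar: float,
    a: int,
    n_crit: float,
    q_points: int = 256,
    **classify_kwargs,
) -> pd.DataFrame:
    """Phase labels over a (β_agg × β_align) grid at each β_rest level.

    Returns a tidy DataFrame with columns ``beta_rest, beta_agg, beta_align,
    label, max_modulus, q_star``.  Deterministic; the propagator is
    self-validated once per β_rest level.
    """
    records = []
    for beta_rest in np.atleast_1d(beta_rest_levels):
        validated = False
        for beta_agg in np.atleast_1d(beta_agg_values):
            for beta_align in np.atleast_1d(beta_align_values):
                res = classify_phase(
                    float(beta_agg),
                    float(beta_align),
                    float(beta_rest),
                    rho_bar,
                    a,
                    n_crit,
                    q_points=q_points,
                    validate=not validated,
                    **classify_kwargs,
                )
                validated = True
                records.append(
                    {
                        "beta_rest": float(beta_rest),
                        "beta_agg": float(beta_agg),
                        "beta_align": float(beta_align),
                        "label": res.label,
                        "max_modulus": res.max_modulus,
                        "q_star": res.q_star,
                    }
                )
    return pd.DataFrame.from_records(records)
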