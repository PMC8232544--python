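"""The LGCA update cycle: reorientation, birth/death, switching, propagation.

One automaton step applies, in order, the stochastic reorientation operator
O (cells at a node redistribute among channels with Boltzmann probabilities
from the rule energy), the birth/death operator R, the phenotype-switch
operator S, and finally the deterministic propagation operator P which
translocates every cell in a velocity channel to the neighbouring node in
that direction (composition ``s' = s^{S∘R∘O}`` read right-to-left, then P;
the time step increments with P).

Reorientation is *synchronous*: all nodes draw their new configuration from
the pre-update lattice.  One uniform variate per node is drawn in canonical
row-major node order before any update, so runs are bit-reproducible for a
given seed regardless of internal vectorisation.

Outcome enumeration is exact: all ``Π_σ C(K, n_σ)`` mass-conserving
configurations are enumerated (no Monte-Carlo estimate of the partition
function); ``K`` is capped at 16 to bound the enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import CapabilityError, ConfigurationError, NumericalError
from .lattice import LatticeGeometry, LatticeState
from .rules import Neighbourhood, OutcomeKinematics, ReorientationRule

__all__ = [
    "ReorientationDistribution",
    "DemographicRates",
    "Trajectory",
    "enumerate_outcomes",
    "reorientation_probabilities",
    "sample_reorientation",
    "apply_reorientation",
    "apply_propagation",
    "apply_birth_death",
    "apply_phenotype_switch",
    "step",
    "run",
]

MAX_ENUMERATION_K = 16


@dataclass(frozen=True)
class ReorientationDistribution:
    """Enumerated Boltzmann distribution over mass-conserving outcomes."""

    outcomes: np.ndarray  # (m, |Σ|·K) uint8
    probabilities: np.ndarray  # (m,)
    log_Z: float

    @property
    def Z(self) -> float:
        return float(np.exp(self.log_Z))


@dataclass(frozen=True)
class DemographicRates:
    """Per-step per-cell birth/death probabilities and phenotype switching.

    ``switch_matrix`` rows give per-step probabilities of switching from
    phenotype σ to each other phenotype; the remainder to 1 is the
    probability of keeping the current phenotype.
    """

    birth: float = 0.0
    death: float = 0.0
    switch_matrix: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.birth <= 1.0 or not 0.0 <= self.death <= 1.0:
            raise ConfigurationError("birth/death rates must lie in [0, 1]")
        if self.switch_matrix is not None:
            m = np.asarray(self.switch_matrix, dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ConfigurationError("switch matrix must be square")
            if np.any(m < 0) or np.any(m.sum(axis=1) > 1 + 1e-12):
                raise ConfigurationError(
                    "switch matrix rows must be non-negative and sum to <= 1"
                )
            object.__setattr__(self, "switch_matrix", m)


# -- outcome enumeration ----------------------------------------------------

@lru_cache(maxsize=4096)
def _outcome_table(K: int, counts: tuple[int, ...]) -> np.ndarray:
    if K > MAX_ENUMERATION_K:
        raise CapabilityError(
            f"K = {K} exceeds the exact-enumeration bound "
            f"{MAX_ENUMERATION_K}; reduce the number of rest channels"
        )
    per_phenotype = []
    for n in counts:
        if not 0 <= n <= K:
            raise ConfigurationError(f"count {n} outside [0, K={K}]")
        block = np.zeros((0, K), dtype=np.uint8)
        rows = []
        for combo in itertools.combinations(range(K), n):
            row = np.zeros(K, dtype=np.uint8)
            row[list(combo)] = 1
            rows.append(row)
        block = np.stack(rows) if rows else np.zeros((1, K), dtype=np.uint8)
        per_phenotype.append(block)
    # Cartesian product over phenotypes, first phenotype varying slowest.
    table = per_phenotype[0]
    for block in per_phenotype[1:]:
        m1, m2 = table.shape[0], block.shape[0]
        table = np.concatenate(
            [np.repeat(table, m2, axis=0), np.tile(block, (m1, 1))], axis=1
        )
    table.setflags(write=False)
    return table


@lru_cache(maxsize=4096)
def _outcome_kinematics(
    geometry: LatticeGeometry, counts: tuple[int, ...]
) -> OutcomeKinematics:
    table = _outcome_table(geometry.K, counts)
    blocks = table.reshape(-1, geometry.phenotypes, geometry.K)
    moving = blocks[:, :, : geometry.b].sum(axis=1)
    c = geometry.velocity_vectors[: geometry.b].astype(float)
    J = moving @ c
    N = 0.5 * (moving @ geometry.velocity_vectors[geometry.nematic_map].astype(float))
    n_rest = blocks[:, :, geometry.b :].sum(axis=(1, 2)).astype(float)
    return OutcomeKinematics(J=J, N=N, n_rest=n_rest)


def enumerate_outcomes(
    counts: Sequence[int] | int, K: int
) -> np.ndarray:
    """All node configurations with the given per-phenotype cell counts.

    Returns a ``(Π_σ C(K, n_σ), |Σ|·K)`` 0/1 array in canonical
    (lexicographic channel-combination) order.
    """
    if np.isscalar(counts):
        counts = (int(counts),)
    return _outcome_table(int(K), tuple(int(n) for n in counts))


def _log_softmax_rows(energies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise probabilities and log normalisation, overflow-safe."""
    shift = energies.max(axis=-1, keepdims=True)
    w = np.exp(energies - shift)
    Z = w.sum(axis=-1, keepdims=True)
    return w / Z, (np.log(Z) + shift)[..., 0]


def reorientation_probabilities(
    s: np.ndarray,
    s_N: Neighbourhood,
    rule: ReorientationRule,
    geometry: LatticeGeometry,
) -> ReorientationDistribution:
    """Enumerated transition distribution of the reorientation operator.

    Outcome weights are ``exp(E(s^O, s_N))`` over all configurations with the
    same per-phenotype cell counts as ``s``; with all sensitivities zero the
    distribution is uniform (random walk).
    """
    s = np.asarray(s, dtype=np.uint8).ravel()
    counts = tuple(
        int(x) for x in s.reshape(geometry.phenotypes, geometry.K).sum(axis=1)
    )
    table = _outcome_table(geometry.K, counts)
    kin = _outcome_kinematics(geometry, counts)
    fields = rule.neighbourhood_fields(s_N, geometry)
    fields = {k: np.asarray(v, dtype=float)[None, ...] for k, v in fields.items()}
    fields["_n_nodes"] = 1
    energies = np.asarray(rule.outcome_energies(kin, fields), dtype=float)
    energies = energies.reshape(1, table.shape[0])
    if not np.all(np.isfinite(energies)):
        raise NumericalError(f"rule '{rule.name}' produced non-finite energies")
    probs, log_Z = _log_softmax_rows(energies)
    return ReorientationDistribution(
        outcomes=table, probabilities=probs[0], log_Z=float(log_Z[0])
    )


def _select_outcomes(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF selection: one uniform per row of ``probs``."""
    cum = np.cumsum(probs, axis=-1)
    idx = (u[:, None] > cum).sum(axis=-1)
    return np.minimum(idx, probs.shape[-1] - 1)


def sample_reorientation(
    s: np.ndarray,
    s_N: Neighbourhood,
    rule: ReorientationRule,
    geometry: LatticeGeometry,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``size`` outcome configurations for a single node, ``(size, C)``."""
    dist = reorientation_probabilities(s, s_N, rule, geometry)
    idx = _select_outcomes(
        np.broadcast_to(dist.probabilities, (size, dist.probabilities.size)),
        rng.random(size),
    )
    return dist.outcomes[idx]


def apply_reorientation(
    state: LatticeState, rule: ReorientationRule, rng: np.random.Generator
) -> LatticeState:
    """Synchronous reorientation of every node (pre-update neighbourhoods).

    Per-phenotype cell counts of every node are conserved exactly.
    """
    g = state.geometry
    rule.validate(state)
    fields = rule.node_fields(state)
    n_nodes = g.n_nodes
    occ = state.occupancy.reshape(n_nodes, g.channels)
    counts = occ.reshape(n_nodes, g.phenotypes, g.K).sum(axis=2)
    # one uniform per node, canonical row-major order
    u = rng.random(n_nodes)
    new_occ = occ.copy()
    signatures, inverse = np.unique(counts, axis=0, return_inverse=True)
    for gi, sig in enumerate(signatures):
        idx = np.nonzero(inverse == gi)[0]
        key = tuple(int(x) for x in sig)
        table = _outcome_table(g.K, key)
        m = table.shape[0]
        if m == 1:
            new_occ[idx] = table[0]
            continue
        kin = _outcome_kinematics(g, key)
        fslice = {k: v[idx] for k, v in fields.items()}
        fslice["_n_nodes"] = idx.size
        energies = np.asarray(rule.outcome_energies(kin, fslice), dtype=float)
        if not np.all(np.isfinite(energies)):
            raise NumericalError(
                f"rule '{rule.name}' produced non-finite energies"
            )
        probs, _ = _log_softmax_rows(energies)
        sel = _select_outcomes(probs, u[idx])
        new_occ[idx] = table[sel]
    return replace(
        state.copy(), occupancy=new_occ.reshape(state.occupancy.shape)
    )


def apply_propagation(state: LatticeState) -> LatticeState:
    """Deterministic translocation of moving cells; increments the time step.

    ``s_j(r + c_j, k+1) = s'_j(r, k)`` for velocity channels; rest channels
    stay in place.  Each target channel receives from exactly one source, so
    exclusion cannot be violated and total momentum is conserved exactly.
    """
    g = state.geometry
    occ = state.occupancy.reshape(g.shape + (g.phenotypes, g.K))
    new = occ.copy()
    axes = tuple(range(g.dimension))
    for j in range(g.b):
        shift = tuple(int(c) for c in g.velocity_vectors[j])
        new[..., j] = np.roll(occ[..., j], shift=shift, axis=axes)
    return replace(
        state.copy(),
        occupancy=new.reshape(state.occupancy.shape),
        time_step=state.time_step + 1,
    )


def apply_birth_death(
    state: LatticeState, rates: DemographicRates, rng: np.random.Generator
) -> LatticeState:
    """Independent per-cell death, then birth into a free channel.

    Each cell dies with probability ``death``; each survivor attempts one
    birth with probability ``birth`` into a uniformly chosen free channel of
    its node (same phenotype).  If the node has no free channel the birth
    fails, so exclusion is preserved.
    """
    if rates.birth == 0.0 and rates.death == 0.0:
        return state.copy()
    g = state.geometry
    occ = state.occupancy.reshape(g.n_nodes, g.phenotypes, g.K).copy()
    if rates.death > 0.0:
        survive = rng.random(occ.shape) >= rates.death
        occ &= survive
    if rates.birth > 0.0:
        n_surv = occ.sum(axis=2, dtype=np.int64)
        attempts = rng.binomial(n_surv, rates.birth)
        for node, phen in zip(*np.nonzero(attempts)):
            for _ in range(attempts[node, phen]):
                free = np.nonzero(occ[node, phen] == 0)[0]
                if free.size == 0:
                    break
                occ[node, phen, free[rng.integers(free.size)]] = 1
    return replace(state.copy(), occupancy=occ.reshape(state.occupancy.shape))


def apply_phenotype_switch(
    state: LatticeState,
    switch_matrix: np.ndarray | None,
    rng: np.random.Generator,
) -> LatticeState:
    """Stochastic phenotype transitions; cells keep their channel.

    A cell of phenotype σ moves to phenotype τ's block with probability
    ``switch_matrix[σ, τ]`` provided the same channel index in the target
    block is free; otherwise the switch fails.  Total cell count is
    conserved.  With one phenotype (or no matrix) this is the identity.
    """
    g = state.geometry
    if switch_matrix is None or g.phenotypes == 1:
        return state.copy()
    m = np.asarray(switch_matrix, dtype=float)
    if m.shape != (g.phenotypes, g.phenotypes):
        raise ConfigurationError(
            f"switch matrix shape {m.shape} != ({g.phenotypes}, {g.phenotypes})"
        )
    if np.any(m < 0) or np.any(m.sum(axis=1) > 1 + 1e-12):
        raise ConfigurationError("switch matrix rows must sum to <= 1")
    occ = state.occupancy.reshape(g.n_nodes, g.phenotypes, g.K).copy()
    nodes, phens, chans = np.nonzero(occ)
    u = rng.random(nodes.size)
    for cell in range(nodes.size):
        node, sigma, chan = nodes[cell], phens[cell], chans[cell]
        if occ[node, sigma, chan] == 0:  # already moved away (cannot happen)
            continue
        cum = np.cumsum(m[sigma])
        tau = int(np.searchsorted(cum, u[cell], side="right"))
        if tau >= g.phenotypes or tau == sigma:
            continue  # stay
        if occ[node, tau, chan] == 0:
            occ[node, sigma, chan] = 0
            occ[node, tau, chan] = 1
    return replace(state.copy(), occupancy=occ.reshape(state.occupancy.shape))


def step(
    state: LatticeState,
    rule: ReorientationRule,
    rng: np.random.Generator,
    rates: DemographicRates | None = None,
) -> LatticeState:
    """One full automaton step: O, then R, then S, then P."""
    rates = rates or DemographicRates()
    out = apply_reorientation(state, rule, rng)
    if rates.birth or rates.death:
        out = apply_birth_death(out, rates, rng)
    if rates.switch_matrix is not None:
        out = apply_phenotype_switch(out, rates.switch_matrix, rng)
    return apply_propagation(out)


@dataclass
class Trajectory:
    """Recorded occupancy snapshots of a run (step 0 = initial state)."""

    geometry: LatticeGeometry
    occupancy: np.ndarray  # (steps+1, *shape, channels)
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, k: int) -> LatticeState:
        return LatticeState(
            geometry=self.geometry, occupancy=self.occupancy[k], time_step=k
        )

    def density(self) -> np.ndarray:
        """Total cell number per node per step, ``(steps+1, *shape)``."""
        return self.occupancy.sum(axis=-1, dtype=np.int64)

    def flux(self) -> np.ndarray:
        """Node flux per step, ``(steps+1, *shape, d)``."""
        g = self.geometry
        occ = self.occupancy.reshape(
            self.occupancy.shape[:-1] + (g.phenotypes, g.K)
        )
        moving = occ[..., : g.b].sum(axis=-2, dtype=np.int64)
        return moving @ g.velocity_vectors[: g.b]


def run(
    state: LatticeState,
    rule: ReorientationRule,
    steps: int,
    seed: int | np.random.Generator,
    rates: DemographicRates | None = None,
    record: bool = True,
) -> Trajectory | LatticeState:
    """Run the automaton for ``steps`` steps from ``state``.

    With ``record=True`` returns a :class:`Trajectory` holding a snapshot per
    step (length ``steps + 1``); otherwise returns only the final state.
    """
    if steps < 0:
        raise ConfigurationError("steps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = state.copy()
    if record:
        snaps = np.empty(
            (steps + 1,) + state.occupancy.shape, dtype=np.uint8
        )
        snaps[0] = current.occupancy
    for k in range(steps):
        current = step(current, rule, rng, rates)
        if record:
            snaps[k + 1] = current.occupancy
    if record:
        return Trajectory(
            geometry=state.geometry,
            occupancy=snaps,
            seed=seed if isinstance(seed, int) else None,
        )
    return current
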