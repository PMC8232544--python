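"""Reorientation rules: interaction energies inducing Boltzmann transitions.

A reorientation rule assigns an energy ``E(s^O, s_N)`` to every candidate
post-interaction node configuration ``s^O`` given the von Neumann
neighbourhood configuration ``s_N`` (and, for taxis/guidance rules, static
environment fields).  The reorientation operator then draws ``s^O`` with
probability ``exp(E) / Z`` among the mass-conserving outcomes.

All built-in energies are functions of the outcome only through its flux
``J(s^O)``, nematic vector ``N(s^O)`` and resting count ``n_rest(s^O)``,
and of the neighbourhood only through a handful of *fields*:

* density gradient        ``G(s_N)      = Σ_p n(s_p) c_p``          (adhesion)
* local cell momentum     ``D(s_N)      = Σ_p J(s_p)``              (alignment)
* signal gradient         ``G_sig(s_N)  = Σ_p c_p c_sig^p``         (chemotaxis)
* logistic density grad.  ``g_agg(s_N)  = Σ_p n_p (1 − n_p/n_crit) c_p``
* neighbourhood flux      ``g_align(s_N)= Σ_p j(s_p)``
* neighbourhood resting   ``n_rest(s_N) = Σ_p n_rest(s_p)``

With all sensitivities zero every energy vanishes and the induced
distribution is the uniform random walk.  Energies are evaluated in batch
over many nodes; weights are normalised in log-space by the operator layer,
so arbitrarily large sensitivities are safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import CapabilityError, ConfigurationError, StructuralError
from .lattice import LatticeGeometry, LatticeState

__all__ = [
    "Neighbourhood",
    "ReorientationRule",
    "OutcomeKinematics",
    "random_walk_rule",
    "chemotaxis_rule",
    "haptotaxis_rule",
    "contact_guidance_rule",
    "alignment_rule",
    "adhesion_rule",
    "invasion_rule",
    "director_field_rule",
    "make_rule",
    "RULE_NAMES",
]


@dataclass(frozen=True)
class Neighbourhood:
    """Explicit neighbourhood input for single-node rule evaluation.

    ``configs`` holds the ``b`` neighbour node configurations in channel
    order (shape ``(b, |Σ|·K)``); ``signal`` the scalar signal concentration
    at each neighbour; ``field`` the environment vector at the central node.
    """

    configs: np.ndarray
    signal: np.ndarray | None = None
    field: np.ndarray | None = None


@dataclass(frozen=True)
class OutcomeKinematics:
    """Per-outcome quantities the energies may depend on.

    ``J``: flux vectors, shape ``(m, d)``; ``N``: nematic vectors ``(m, d)``;
    ``n_rest``: occupied rest channels ``(m,)``.
    """

    J: np.ndarray
    N: np.ndarray
    n_rest: np.ndarray


def _neighbour_stack(arr: np.ndarray, geometry: LatticeGeometry) -> np.ndarray:
    """Stack ``arr`` evaluated at the b neighbours: out[p][r] = arr[r + c_p]."""
    axes = tuple(range(geometry.dimension))
    out = [
        np.roll(arr, shift=tuple(-int(c) for c in geometry.velocity_vectors[p]),
                axis=axes)
        for p in range(geometry.b)
    ]
    return np.stack(out, axis=0)


def _neighbour_observables(nb: Neighbourhood, geometry: LatticeGeometry):
    """Per-neighbour n, J, n_rest from explicit neighbour configurations."""
    configs = np.asarray(nb.configs, dtype=np.int64)
    if configs.shape != (geometry.b, geometry.channels):
        raise StructuralError(
            f"neighbourhood configs shape {configs.shape} != "
            f"{(geometry.b, geometry.channels)}"
        )
    blocks = configs.reshape(geometry.b, geometry.phenotypes, geometry.K)
    n = blocks.sum(axis=(1, 2))
    moving = blocks[:, :, : geometry.b].sum(axis=1)
    J = moving @ geometry.velocity_vectors[: geometry.b]
    n_rest = blocks[:, :, geometry.b :].sum(axis=(1, 2))
    return n, J.astype(float), n_rest


class ReorientationRule:
    """Base class; subclasses provide fields and batch energies."""

    name: str = "abstract"
    requires_signal = False
    requires_field = False

    def sensitivities(self) -> tuple[float, ...]:
        return ()

    def validate(self, state: LatticeState) -> None:
        if self.requires_signal and state.signal is None:
            raise ConfigurationError(
                f"rule '{self.name}' requires a scalar signal field on the lattice"
            )
        if self.requires_field and state.field is None:
            raise ConfigurationError(
                f"rule '{self.name}' requires a vector environment field"
            )

    def node_fields(self, state: LatticeState) -> dict[str, np.ndarray]:
        """Per-node neighbourhood fields from the pre-update lattice.

        Returns a mapping name → array with leading axis = flattened nodes.
        """
        raise NotImplementedError

    def neighbourhood_fields(
        self, nb: Neighbourhood, geometry: LatticeGeometry
    ) -> dict[str, np.ndarray]:
        """Fields for a single explicitly given neighbourhood."""
        raise NotImplementedError

    def outcome_energies(
        self, kin: OutcomeKinematics, fields: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        """Energies, shape ``(n_nodes, m_outcomes)``; field arrays are
        sliced to the node subset before the call."""
        raise NotImplementedError


def _flatten(field: np.ndarray, geometry: LatticeGeometry) -> np.ndarray:
    return field.reshape((geometry.n_nodes,) + field.shape[geometry.dimension:])


class RandomWalkRule(ReorientationRule):
    """Unbiased shuffling of cells among channels (energy ≡ 0)."""

    name = "randomwalk"

    def sensitivities(self):
        return ()

    def node_fields(self, state):
        return {}

    def neighbourhood_fields(self, nb, geometry):
        return {}

    def outcome_energies(self, kin, fields):
        n_nodes = fields["_n_nodes"]
        return np.zeros((n_nodes, kin.J.shape[0]))


class _LinearFluxRule(ReorientationRule):
    """Energy β · g(s_N) · J(s^O) for a per-node vector field g."""

    field_key = "g"

    def __init__(self, beta: float):
        self.beta = float(beta)

    def sensitivities(self):
        return (self.beta,)

    def outcome_energies(self, kin, fields):
        g = np.atleast_2d(fields[self.field_key])
        return self.beta * (g @ kin.J.T)


class ChemotaxisRule(_LinearFluxRule):
    """Bias up the gradient of a static scalar signal field."""

    name = "chemotaxis"
    requires_signal = True
    field_key = "G_sig"

    def node_fields(self, state):
        g = state.geometry
        sig = _neighbour_stack(state.signal, g)  # (b, *shape)
        c = g.velocity_vectors[: g.b].astype(float)
        G_sig = np.tensordot(sig, c, axes=(0, 0))  # (*shape, d)
        return {"G_sig": _flatten(G_sig, g)}

    def neighbourhood_fields(self, nb, geometry):
        if nb.signal is None:
            raise ConfigurationError(
                "chemotaxis requires signal concentrations at the neighbours"
            )
        sig = np.asarray(nb.signal, dtype=float)
        c = geometry.velocity_vectors[: geometry.b].astype(float)
        return {"G_sig": sig @ c}


class HaptotaxisRule(_LinearFluxRule):
    """Directional bias along a static environment vector field E."""

    name = "haptotaxis"
    requires_field = True
    field_key = "E"

    def node_fields(self, state):
        return {"E": _flatten(state.field, state.geometry)}

    def neighbourhood_fields(self, nb, geometry):
        if nb.field is None:
            raise ConfigurationError("haptotaxis requires the vector field E")
        return {"E": np.asarray(nb.field, dtype=float)}


class ContactGuidanceRule(HaptotaxisRule):
    """Orientational (sign-free) bias along the axis of E: β |E · J(s^O)|."""

    name = "contact_guidance"

    def outcome_energies(self, kin, fields):
        E = np.atleast_2d(fields["E"])
        return self.beta * np.abs(E @ kin.J.T)


class AlignmentRule(_LinearFluxRule):
    """Polar velocity alignment: β D(s_N) · J(s^O), D the neighbour momentum."""

    name = "alignment"
    field_key = "D"

    def node_fields(self, state):
        g = state.geometry
        D = _neighbour_stack(state.flux(), g).sum(axis=0).astype(float)
        return {"D": _flatten(D, g)}

    def neighbourhood_fields(self, nb, geometry):
        _, J, _ = _neighbour_observables(nb, geometry)
        return {"D": J.sum(axis=0)}


class AdhesionRule(_LinearFluxRule):
    """Cell-cell attraction: β G(s_N) · J(s^O), G the density gradient field."""

    name = "adhesion"
    field_key = "G"

    def node_fields(self, state):
        g = state.geometry
        n = _neighbour_stack(state.density(), g)  # (b, *shape)
        c = g.velocity_vectors[: g.b].astype(float)
        G = np.tensordot(n, c, axes=(0, 0))
        return {"G": _flatten(G, g)}

    def neighbourhood_fields(self, nb, geometry):
        n, _, _ = _neighbour_observables(nb, geometry)
        c = geometry.velocity_vectors[: geometry.b].astype(float)
        return {"G": n.astype(float) @ c}


class DirectorFieldRule(ReorientationRule):
    """Fixed director field G: energy β J·G (polar) or β N·G (nematic)."""

    name = "director_field"

    def __init__(self, G: np.ndarray, beta: float = 1.0, nematic: bool = False):
        self.G = np.asarray(G, dtype=float)
        self.beta = float(beta)
        self.nematic = bool(nematic)

    def sensitivities(self):
        return (self.beta,)

    def node_fields(self, state):
        g = state.geometry
        return {"G": np.broadcast_to(self.G, (g.n_nodes, g.dimension))}

    def neighbourhood_fields(self, nb, geometry):
        return {"G": self.G}

    def outcome_energies(self, kin, fields):
        G = np.atleast_2d(fields["G"])
        vec = kin.N if self.nematic else kin.J
        return self.beta * (G @ vec.T)


class InvasionRule(ReorientationRule):
    """Combined aggregation / alignment / resting rule (1D, b = 2).

    Energy ``β_agg j(s^O) g_agg + β_align j(s^O) g_align
    + β_rest n_rest(s^O) n_rest(s_N)`` with the logistic density gradient
    ``g_agg = Σ_j n(r+c_j)[1 − n(r+c_j)/n_crit] c_j`` modelling homeostatic
    saturation of attraction at the carrying density ``n_crit``.
    """

    name = "invasion"

    def __init__(
        self,
        beta_agg: float,
        beta_align: float,
        beta_rest: float,
        n_crit: float,
    ):
        if n_crit <= 0:
            raise ConfigurationError("n_crit must be positive")
        self.beta_agg = float(beta_agg)
        self.beta_align = float(beta_align)
        self.beta_rest = float(beta_rest)
        self.n_crit = float(n_crit)

    def sensitivities(self):
        return (self.beta_agg, self.beta_align, self.beta_rest)

    def validate(self, state):
        if state.geometry.dimension != 1:
            raise CapabilityError("invasion rule is defined on 1D lattices only")
        super().validate(state)

    def _check_geometry(self, geometry: LatticeGeometry) -> None:
        if geometry.dimension != 1:
            raise CapabilityError("invasion rule is defined on 1D lattices only")

    def node_fields(self, state):
        g = state.geometry
        self._check_geometry(g)
        n = _neighbour_stack(state.density(), g).astype(float)  # (2, L)
        j = _neighbour_stack(state.flux()[..., 0], g).astype(float)
        rest = _neighbour_stack(state.resting(), g).astype(float)
        c = g.velocity_vectors[: g.b, 0].astype(float)  # (+1, -1)
        g_agg = np.tensordot(n * (1.0 - n / self.n_crit), c, axes=(0, 0))
        return {
            "g_agg": g_agg.ravel(),
            "g_align": j.sum(axis=0).ravel(),
            "nrest_N": rest.sum(axis=0).ravel(),
        }

    def neighbourhood_fields(self, nb, geometry):
        self._check_geometry(geometry)
        n, J, n_rest = _neighbour_observables(nb, geometry)
        c = geometry.velocity_vectors[: geometry.b, 0].astype(float)
        n = n.astype(float)
        return {
            "g_agg": float(np.dot(n * (1.0 - n / self.n_crit), c)),
            "g_align": float(J[:, 0].sum()),
            "nrest_N": float(n_rest.sum()),
        }

    def outcome_energies(self, kin, fields):
        g_agg = np.atleast_1d(fields["g_agg"])[:, None]
        g_align = np.atleast_1d(fields["g_align"])[:, None]
        nrest_N = np.atleast_1d(fields["nrest_N"])[:, None]
        j_out = kin.J[:, 0][None, :]
        rest_out = kin.n_rest[None, :]
        return (
            self.beta_agg * j_out * g_agg
            + self.beta_align * j_out * g_align
            + self.beta_rest * rest_out * nrest_N
        )


# -- factory ----------------------------------------------------------------

def random_walk_rule() -> RandomWalkRule:
    return RandomWalkRule()


def chemotaxis_rule(beta: float) -> ChemotaxisRule:
    return ChemotaxisRule(beta)


def haptotaxis_rule(beta: float) -> HaptotaxisRule:
    return HaptotaxisRule(beta)


def contact_guidance_rule(beta: float) -> ContactGuidanceRule:
    return ContactGuidanceRule(beta)


def alignment_rule(beta: float) -> AlignmentRule:
    return AlignmentRule(beta)


def adhesion_rule(beta: float) -> AdhesionRule:
    return AdhesionRule(beta)


def invasion_rule(
    beta_agg: float, beta_align: float, beta_rest: float, n_crit: float
) -> InvasionRule:
    return InvasionRule(beta_agg, beta_align, beta_rest, n_crit)


def director_field_rule(
    G: np.ndarray, beta: float = 1.0, nematic: bool = False
) -> DirectorFieldRule:
    return DirectorFieldRule(G, beta=beta, nematic=nematic)


_FACTORIES = {
    "randomwalk": random_walk_rule,
    "chemotaxis": chemotaxis_rule,
    "haptotaxis": haptotaxis_rule,
    "contact_guidance": contact_guidance_rule,
    "alignment": alignment_rule,
    "adhesion": adhesion_rule,
    "invasion": invasion_rule,
}

RULE_NAMES = tuple(_FACTORIES)


def make_rule(name: str, **params) -> ReorientationRule:
    """Instantiate a built-in rule by its configuration name."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown rule {name!r}; available: {', '.join(RULE_NAMES)}"
        ) from None
    try:
        return factory(**params)
    except TypeError as exc:
        raise ConfigurationError(f"bad parameters for rule {name!r}: {exc}") from exc
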