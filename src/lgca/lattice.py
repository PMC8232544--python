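"""Lattice geometry, node configurations and node-level observables.

A lattice-gas cellular automaton (LGCA) node carries ``K = a + b`` channels
per phenotype: ``b`` *velocity channels* associated with the unit vectors
pointing to the nearest neighbours, and ``a`` *rest channels* with zero
velocity.  Occupation numbers are 0/1 (exclusion principle: at most one cell
per channel per phenotype), so a node hosts up to ``|Σ|·K`` cells.

Channel ordering is normative throughout the package: the velocity channels
come first, in angular order

* 1D (``b = 2``): ``+1, −1``
* 2D square (``b = 4``): ``(+1,0), (0,+1), (−1,0), (0,−1)``

i.e. ``c_p = (cos 2π(p−1)/b, sin 2π(p−1)/b)``, followed by the ``a`` rest
channels.  The nematic alignment vector's index arithmetic
``N(s) = ½ Σ_p c_{[2(p−1) mod b]+1} s_p`` relies on this order: opposite
channels fold onto the same nematic direction (angle doubling).

Node indexing is 0-based and row-major for 2D; environment-field files use
the same flat order.  Boundaries are periodic (the mean-field machinery
assumes translation invariance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigurationError, StructuralError

__all__ = [
    "LatticeGeometry",
    "LatticeState",
    "NodeObservables",
    "create_lattice",
    "node_observables",
    "neighbourhood_of",
    "initialize_random",
    "initialize_homogeneous",
]


@dataclass(frozen=True)
class LatticeGeometry:
    """Static description of the lattice: dimension, extents and channels.

    Parameters
    ----------
    dimension:
        1 or 2 (square lattice).
    shape:
        Number of nodes per axis.
    a:
        Number of rest (zero-velocity) channels per phenotype.
    phenotypes:
        Number of cell phenotypes ``|Σ|`` sharing the lattice (default 1).
        Occupations are stored as concatenated per-phenotype blocks of
        length ``K``.
    boundary:
        Only ``"periodic"`` is supported.
    """

    dimension: int
    shape: tuple[int, ...]
    a: int
    phenotypes: int = 1
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ConfigurationError(
                f"unsupported dimension {self.dimension!r}; only 1D and 2D "
                "square lattices are supported"
            )
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != self.dimension:
            raise ConfigurationError(
                f"shape {shape} does not match dimension {self.dimension}"
            )
        if any(s <= 0 for s in shape):
            raise ConfigurationError(f"non-positive lattice extents in {shape}")
        if self.a < 0:
            raise ConfigurationError("number of rest channels must be >= 0")
        if self.phenotypes < 1:
            raise ConfigurationError("at least one phenotype required")
        if self.boundary != "periodic":
            raise ConfigurationError(
                f"unsupported boundary {self.boundary!r}; only 'periodic'"
            )

    @property
    def b(self) -> int:
        """Number of velocity channels (2 in 1D, 4 on the 2D square lattice)."""
        return 2 * self.dimension

    @property
    def K(self) -> int:
        """Node capacity per phenotype, ``K = a + b``."""
        return self.a + self.b

    @property
    def channels(self) -> int:
        """Total channels stored per node, ``|Σ|·K``."""
        return self.phenotypes * self.K

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @cached_property
    def velocity_vectors(self) -> np.ndarray:
        """``(K, dimension)`` integer array of channel vectors c_j.

        Rows ``0..b-1`` are the unit velocity vectors in angular order; rows
        ``b..K-1`` are zero (rest channels).
        """
        c = np.zeros((self.K, self.dimension), dtype=np.int64)
        if self.dimension == 1:
            c[0, 0] = 1
            c[1, 0] = -1
        else:
            c[0] = (1, 0)
            c[1] = (0, 1)
            c[2] = (-1, 0)
            c[3] = (0, -1)
        return c

    @cached_property
    def nematic_map(self) -> np.ndarray:
        """Velocity-channel index p → index of the nematic direction c_{2θ}.

        Implements ``[2(p−1) mod b] + 1`` (1-based) for the angle-doubling map;
        opposite channels land on the same entry.
        """
        p = np.arange(self.b)
        return (2 * p) % self.b

    def opposite_channel(self, p: int) -> int:
        """Index of the channel carrying ``−c_p`` (velocity channels only)."""
        if not 0 <= p < self.b:
            raise StructuralError(f"channel {p} is not a velocity channel")
        return (p + self.b // 2) % self.b

    def wrap(self, r: Sequence[int]) -> tuple[int, ...]:
        return tuple(int(x) % s for x, s in zip(r, self.shape))


class NodeObservables(NamedTuple):
    """Per-node summary quantities of a configuration."""

    n: int
    n_sigma: tuple[int, ...]
    J: np.ndarray
    N: np.ndarray
    n_rest: int


@dataclass
class LatticeState:
    """Occupation state of the whole lattice plus optional environment fields.

    ``occupancy`` has shape ``(*shape, |Σ|·K)`` with uint8 entries in {0, 1}.
    ``signal`` (scalar per node) and ``field`` (vector per node) are static
    environment inputs used by taxis/guidance rules.
    """

    geometry: LatticeGeometry
    occupancy: np.ndarray
    time_step: int = 0
    signal: np.ndarray | None = None
    field: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = self.geometry
        expected = g.shape + (g.channels,)
        occ = np.asarray(self.occupancy, dtype=np.uint8)
        if occ.shape != expected:
            raise StructuralError(
                f"occupancy shape {occ.shape} != expected {expected}"
            )
        if occ.max(initial=0) > 1:
            raise StructuralError("occupation numbers must be 0 or 1")
        self.occupancy = occ
        if self.signal is not None:
            sig = np.asarray(self.signal, dtype=float)
            if sig.shape != g.shape:
                raise StructuralError(
                    f"signal field shape {sig.shape} != lattice shape {g.shape}"
                )
            if np.any(sig < 0):
                raise StructuralError("signal concentrations must be non-negative")
            self.signal = sig
        if self.field is not None:
            E = np.asarray(self.field, dtype=float)
            if E.shape != g.shape + (g.dimension,):
                raise StructuralError(
                    f"vector field shape {E.shape} != {g.shape + (g.dimension,)}"
                )
            self.field = E

    def copy(self) -> "LatticeState":
        return replace(self, occupancy=self.occupancy.copy())

    # -- lattice-wide observables ------------------------------------------

    def per_phenotype(self) -> np.ndarray:
        """Occupancy reshaped to ``(*shape, |Σ|, K)``."""
        g = self.geometry
        return self.occupancy.reshape(g.shape + (g.phenotypes, g.K))

    def density(self) -> np.ndarray:
        """Total cell number n(r) per node, shape ``shape``."""
        return self.occupancy.sum(axis=-1, dtype=np.int64)

    def flux(self) -> np.ndarray:
        """Node flux J(r) (sum of occupied velocity vectors), ``(*shape, d)``."""
        g = self.geometry
        occ = self.per_phenotype()
        moving = occ[..., : g.b].sum(axis=-2, dtype=np.int64)  # (*shape, b)
        return moving @ g.velocity_vectors[: g.b]

    def resting(self) -> np.ndarray:
        """Number of occupied rest channels per node."""
        g = self.geometry
        return self.per_phenotype()[..., g.b :].sum(axis=(-2, -1), dtype=np.int64)

    def total_cells(self) -> int:
        return int(self.occupancy.sum(dtype=np.int64))


def create_lattice(
    dimension: int,
    shape: Sequence[int],
    a: int = 0,
    boundary: str = "periodic",
    phenotypes: int = 1,
) -> LatticeState:
    """Create an empty lattice (all occupations zero) with the given geometry."""
    geom = LatticeGeometry(
        dimension=dimension,
        shape=tuple(shape),
        a=a,
        phenotypes=phenotypes,
        boundary=boundary,
    )
    occ = np.zeros(geom.shape + (geom.channels,), dtype=np.uint8)
    return LatticeState(geometry=geom, occupancy=occ)


def node_observables(s: np.ndarray, geometry: LatticeGeometry) -> NodeObservables:
    """Observables of a single node configuration ``s`` (length ``|Σ|·K``).

    Returns cell number ``n``, per-phenotype counts, flux ``J``, nematic
    alignment vector ``N`` and the occupied rest-channel count.
    """
    s = np.asarray(s, dtype=np.int64).ravel()
    g = geometry
    if s.size != g.channels:
        raise StructuralError(
            f"configuration length {s.size} != |Σ|·K = {g.channels}"
        )
    if np.any((s != 0) & (s != 1)):
        raise StructuralError("occupation numbers must be 0 or 1")
    blocks = s.reshape(g.phenotypes, g.K)
    n_sigma = tuple(int(x) for x in blocks.sum(axis=1))
    moving = blocks[:, : g.b].sum(axis=0)
    J = moving @ g.velocity_vectors[: g.b]
    N = 0.5 * (moving @ g.velocity_vectors[g.nematic_map])
    n_rest = int(blocks[:, g.b :].sum())
    return NodeObservables(
        n=int(s.sum()), n_sigma=n_sigma, J=J.astype(float), N=N, n_rest=n_rest
    )


def neighbourhood_of(
    r: Sequence[int] | int, lattice: LatticeState | LatticeGeometry
) -> list[tuple[int, ...]]:
    """Ordered von Neumann neighbours of node ``r`` (periodic wrap).

    Neighbour ``p`` is the node ``r + c_p``; ordering follows the velocity
    channel order.
    """
    geom = lattice if isinstance(lattice, LatticeGeometry) else lattice.geometry
    if np.isscalar(r):
        r = (int(r),)
    r = tuple(int(x) for x in r)
    if len(r) != geom.dimension or any(
        not 0 <= x < s for x, s in zip(r, geom.shape)
    ):
        raise IndexError(f"node {r} outside lattice of shape {geom.shape}")
    return [
        geom.wrap(tuple(x + c for x, c in zip(r, geom.velocity_vectors[p])))
        for p in range(geom.b)
    ]


def initialize_random(
    lattice: LatticeState,
    mean_density: float,
    seed: int | np.random.Generator,
) -> LatticeState:
    """Seeded homogeneous random initial state.

    Each channel is occupied independently with probability ``ρ̄/K`` so the
    expected cell number per node (per phenotype) is ``ρ̄``.  The same seed
    reproduces the state bit-for-bit.
    """
    g = lattice.geometry
    if not 0 <= mean_density <= g.K:
        raise ConfigurationError(
            f"mean density {mean_density} outside [0, K={g.K}]"
        )
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    p = mean_density / g.K
    occ = (rng.random(g.shape + (g.channels,)) < p).astype(np.uint8)
    return replace(lattice.copy(), occupancy=occ, time_step=0)


def initialize_homogeneous(
    lattice: LatticeState,
    mean_density: float,
    seed: int | np.random.Generator,
) -> LatticeState:
    """Density-homogeneous random initial state.

    Every node receives ``⌊ρ̄⌋`` cells per phenotype (plus one more with
    probability equal to the fractional part), placed into channels chosen
    uniformly without replacement.  For integer ρ̄ the cell number is
    *identical* at every node, so the only initial disorder is in the
    channel assignment — the discrete analogue of perturbing a homogeneous
    state, appropriate for studying the emergence of patterns from a
    uniform density.
    """
    g = lattice.geometry
    if not 0 <= mean_density <= g.K:
        raise ConfigurationError(
            f"mean density {mean_density} outside [0, K={g.K}]"
        )
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    base = int(np.floor(mean_density))
    frac = mean_density - base
    n_nodes = g.n_nodes
    counts = base + (rng.random((n_nodes, g.phenotypes)) < frac)
    # occupy the n smallest of K random keys per node/phenotype block
    keys = rng.random((n_nodes, g.phenotypes, g.K))
    order = np.argsort(keys, axis=-1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(g.K)[None, None, :], axis=-1)
    occ = (ranks < counts[..., None]).astype(np.uint8)
    occ = occ.reshape(g.shape + (g.channels,))
    return replace(lattice.copy(), occupancy=occ, time_step=0)
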