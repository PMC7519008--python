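"""Spin configurations, the 0/1 Hamiltonian, and the exact ±1 mapping.

The model places a binary state on every node of an undirected network:

    H = -(1/2) * sum_{i,j} J A_ij s_i s_j  -  h * sum_i s_i

with a uniform coupling ``J`` along the edges (``J > 0`` rewards pairs of
active genes, ``J < 0`` penalises them) and a uniform external field
``h``.  The double sum runs over ordered pairs, so the factor 1/2 counts
each edge once.  Two spin conventions are supported:

* ``gene``: states in {0, 1} — the asymmetric, lattice-gas-like model
  that is the subject of this package;
* ``classical``: states in {-1, +1} — the standard Ising convention.

The substitution ``s'_i = 2(s_i - 1/2)`` maps the gene model exactly onto
a classical model with a quartered coupling, a degree-dependent local
field, and an additive constant:

    H_gene(s) = -(1/2) sum J' A_ij s'_i s'_j - sum_i h'_i s'_i + E0
    J'   = J / 4
    h'_i = h/2 + (J/4) k_i
    E0   = -(J/4) |E| - N h / 2

where ``k_i`` is the degree of node ``i`` and ``|E|`` the number of
edges.  The intrinsic local field that survives at ``h = 0`` encodes the
asymmetry of the 0/1 states; it vanishes on the average node when
``h = (J/2) k_bar = J m`` on a BA network — the origin of the critical
field law ``h_c ≈ J m``.  The identity holds configuration by
configuration and is verified against brute-force enumeration in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConventionError, DimensionError, InvalidParameterError
from .network import Network

__all__ = [
    "GENE",
    "CLASSICAL",
    "SpinConfiguration",
    "ModelParams",
    "MappedModel",
    "hamiltonian",
    "order_parameter",
    "delta_energy",
    "map_spins",
    "map_to_classical",
    "save_spins",
    "load_spins",
]

GENE = "gene"
CLASSICAL = "classical"

_ALPHABET = {GENE: (0, 1), CLASSICAL: (-1, 1)}


@dataclass
class SpinConfiguration:
    """A length-N vector of node states in a declared spin convention."""

    states: np.ndarray
    convention: str = GENE

    def __post_init__(self):
        if self.convention not in _ALPHABET:
            raise ConventionError(f"unknown spin convention {self.convention!r}")
        self.states = np.asarray(self.states, dtype=np.int8)
        lo, hi = _ALPHABET[self.convention]
        ok = (self.states == lo) | (self.states == hi)
        if not np.all(ok):
            raise ConventionError(
                f"states must be in {{{lo}, {hi}}} for the {self.convention} convention")

    @property
    def n(self) -> int:
        return int(self.states.size)

    @classmethod
    def all_active(cls, n: int) -> "SpinConfiguration":
        return cls(np.ones(n, dtype=np.int8), GENE)

    @classmethod
    def all_inactive(cls, n: int) -> "SpinConfiguration":
        return cls(np.zeros(n, dtype=np.int8), GENE)

    @classmethod
    def random(cls, n: int, rng: np.random.Generator,
               convention: str = GENE) -> "SpinConfiguration":
        lo, hi = _ALPHABET[convention]
        states = np.where(rng.random(n) < 0.5, lo, hi).astype(np.int8)
        return cls(states, convention)

    def copy(self) -> "SpinConfiguration":
        return SpinConfiguration(self.states.copy(), self.convention)


@dataclass(frozen=True)
class ModelParams:
    """Coupling J, external field h, and temperature T (k_B = 1).

    ``T = 0`` is treated as the deterministic beta -> infinity limit.
    """

    J: float
    h: float
    T: float

    def __post_init__(self):
        if self.T < 0:
            raise InvalidParameterError(f"temperature must be >= 0 (got T={self.T})")

    @property
    def beta(self) -> float:
        return np.inf if self.T == 0 else 1.0 / self.T


def _check_pairing(config: SpinConfiguration, network: Network) -> None:
    if config.n != network.n_nodes:
        raise DimensionError(
            f"configuration length {config.n} does not match network size "
            f"{network.n_nodes}")


def hamiltonian(config: SpinConfiguration, network: Network,
                params: ModelParams) -> float:
    """Total energy of a configuration (either convention)."""
    _check_pairing(config, network)
    s = config.states.astype(np.float64)
    e = network.edges
    coupling = float(np.sum(s[e[:, 0]] * s[e[:, 1]])) if e.size else 0.0
    return -params.J * coupling - params.h * float(s.sum())


def order_parameter(config: SpinConfiguration) -> float:
    """Mean state M = (1/N) sum_i s_i; in [0,1] (gene) or [-1,1] (classical)."""
    if config.n == 0:
        raise InvalidParameterError("order parameter of an empty configuration")
    return float(config.states.mean())


def delta_energy(config: SpinConfiguration, network: Network,
                 params: ModelParams, i: int) -> float:
    """Energy change from flipping node ``i``, computed in O(degree(i)).

    Gene convention flips 0 <-> 1; classical flips s <-> -s.  Equals the
    difference of two full Hamiltonian evaluations.
    """
    _check_pairing(config, network)
    if not 0 <= i < network.n_nodes:
        raise IndexError(f"node id {i} out of range for N={network.n_nodes}")
    nbr = network.neighbors(i)
    local = params.h + params.J * float(config.states[nbr].sum())
    old = int(config.states[i])
    new = (1 - old) if config.convention == GENE else -old
    return -local * (new - old)


def map_spins(config: SpinConfiguration) -> SpinConfiguration:
    """Elementwise 0 -> -1, 1 -> +1 (gene convention in, classical out)."""
    if config.convention != GENE:
        raise ConventionError("map_spins expects a gene-convention configuration")
    return SpinConfiguration((2 * config.states.astype(np.int16) - 1).astype(np.int8),
                             CLASSICAL)


@dataclass
class MappedModel:
    """Classical-spin image of a gene-spin model on a fixed network.

    ``energy(s')`` evaluates the pure classical part
    ``-(1/2) sum J' A s' s' - sum h'_i s'_i``; the exact identity is
    ``H_gene(s) = energy(map_spins(s)) + E0``, so the partition functions
    relate as ``Z_gene = exp(-beta * E0) * Z_classical``.
    """

    J_prime: float
    h_prime: np.ndarray
    E0: float
    network: Network = field(repr=False)

    def energy(self, config: SpinConfiguration) -> float:
        if config.convention != CLASSICAL:
            raise ConventionError("MappedModel.energy expects classical spins")
        _check_pairing(config, self.network)
        s = config.states.astype(np.float64)
        e = self.network.edges
        coupling = float(np.sum(s[e[:, 0]] * s[e[:, 1]])) if e.size else 0.0
        return -self.J_prime * coupling - float(self.h_prime @ s)


def map_to_classical(network: Network, params: ModelParams) -> MappedModel:
    """Exact transformation of the 0/1 model to a ±1 model.

    Returns the quartered coupling ``J' = J/4``, the per-node local field
    ``h'_i = h/2 + (J/4) k_i``, and the additive constant
    ``E0 = -(J/4)|E| - N h/2`` that make the energy identity hold for
    every configuration.
    """
    k = network.degree_sequence.astype(np.float64)
    j_prime = params.J / 4.0
    h_prime = params.h / 2.0 + (params.J / 4.0) * k
    e0 = -(params.J / 4.0) * network.n_edges - network.n_nodes * params.h / 2.0
    return MappedModel(J_prime=j_prime, h_prime=h_prime, E0=e0, network=network)


def save_spins(config: SpinConfiguration, path) -> None:
    """Serialise a configuration as single-column text, one state per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# convention={config.convention}\n")
        for s in config.states:
            fh.write(f"{int(s)}\n")


def load_spins(path) -> SpinConfiguration:
    states = []
    convention = GENE
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "convention=" in line:
                    convention = line.split("convention=")[1].strip()
                continue
            states.append(int(line))
    return SpinConfiguration(np.asarray(states, dtype=np.int8), convention)
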