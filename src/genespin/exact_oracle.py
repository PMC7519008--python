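"""Brute-force enumeration over all 2^N spin configurations.

This module is a test instrument: on graphs with at most 20 nodes it
computes the exact partition function and Boltzmann expectations by
summing over the full configuration space, and it verifies the exact
0/1 <-> ±1 mapping (energy identity and partition-function relation)
configuration by configuration.  Energies are shifted by their minimum
before exponentiation so that low temperatures do not overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import SizeCapError
from .network import Network
from .spin_model import CLASSICAL, GENE, ModelParams, map_to_classical

__all__ = ["SIZE_CAP", "ExactSummary", "MappingReport",
           "enumerate_boltzmann", "verify_mapping"]

SIZE_CAP = 20


def _check_size(network: Network) -> None:
    if network.n_nodes > SIZE_CAP:
        raise SizeCapError(
            f"exact enumeration capped at N <= {SIZE_CAP} (got N={network.n_nodes})")


def _all_states(n: int, convention: str) -> np.ndarray:
    bits = ((np.arange(1 << n, dtype=np.int64)[:, None] >> np.arange(n)) & 1)
    s = bits.astype(np.int8)
    if convention == CLASSICAL:
        s = (2 * s.astype(np.int16) - 1).astype(np.int8)
    return s


def _energies(network: Network, J: float, h, states: np.ndarray) -> np.ndarray:
    """Energies of every configuration; ``h`` may be a scalar or a per-node vector."""
    e = network.edges
    pair = np.zeros(states.shape[0], dtype=np.float64)
    for i, j in e:
        pair += states[:, i].astype(np.float64) * states[:, j]
    field = states.astype(np.float64) @ np.broadcast_to(
        np.asarray(h, dtype=np.float64), (network.n_nodes,))
    return -J * pair - field


@dataclass(frozen=True)
class ExactSummary:
    """Exact partition function and Boltzmann expectations."""

    Z: float
    log_Z: float
    mean_M: float
    mean_H: float
    convention: str


def _summarise(states: np.ndarray, energies: np.ndarray, beta: float,
               convention: str) -> ExactSummary:
    m_all = states.mean(axis=1)
    if math.isinf(beta):  # deterministic limit: uniform over ground states
        ground = energies == energies.min()
        return ExactSummary(Z=math.inf, log_Z=math.inf,
                            mean_M=float(m_all[ground].mean()),
                            mean_H=float(energies.min()), convention=convention)
    e_min = energies.min()
    w = np.exp(-beta * (energies - e_min))
    wsum = w.sum()
    log_z = float(-beta * e_min + np.log(wsum))
    z = float(np.exp(log_z)) if log_z < 700 else math.inf
    return ExactSummary(Z=z, log_Z=log_z,
                        mean_M=float((m_all * w).sum() / wsum),
                        mean_H=float((energies * w).sum() / wsum),
                        convention=convention)


def enumerate_boltzmann(network: Network, params: ModelParams,
                        convention: str = GENE) -> ExactSummary:
    """Exact Z, <M>, and <H> by summing over all 2^N configurations."""
    _check_size(network)
    states = _all_states(network.n_nodes, convention)
    energies = _energies(network, params.J, params.h, states)
    return _summarise(states, energies, params.beta, convention)


@dataclass(frozen=True)
class MappingReport:
    """Residuals of the exact gene -> classical transformation."""

    max_energy_residual: float
    partition_residual: float
    E0: float
    J_prime: float

    @property
    def passed(self) -> bool:
        return self.max_energy_residual < 1e-8 and self.partition_residual < 1e-8


def verify_mapping(network: Network, params: ModelParams) -> MappingReport:
    """Check H_gene(s) = H_classical(s') + E0 for all 2^N configurations.

    Also checks the induced partition-function relation
    ``Z_gene = exp(-beta E0) * Z_classical`` (evaluated in log space).
    Both residuals must be below 1e-8 for the mapping to pass.
    """
    _check_size(network)
    mapped = map_to_classical(network, params)
    gene_states = _all_states(network.n_nodes, GENE)
    gene_E = _energies(network, params.J, params.h, gene_states)
    # the same enumeration index maps s -> s' = 2s - 1
    classical_states = (2 * gene_states.astype(np.int16) - 1).astype(np.int8)
    classical_E = _energies(network, mapped.J_prime, mapped.h_prime, classical_states)
    resid = np.abs(gene_E - classical_E - mapped.E0)
    scale = max(1.0, float(np.abs(gene_E).max()))
    max_energy_residual = float(resid.max()) / scale
    beta = params.beta
    if math.isinf(beta):
        partition_residual = 0.0 if max_energy_residual == 0.0 else max_energy_residual
    else:
        gene_summary = _summarise(gene_states, gene_E, beta, GENE)
        cls_summary = _summarise(classical_states, classical_E, beta, CLASSICAL)
        delta_log = gene_summary.log_Z - (-beta * mapped.E0 + cls_summary.log_Z)
        partition_residual = float(abs(np.expm1(delta_log)))
    return MappingReport(max_energy_residual=max_energy_residual,
                         partition_residual=partition_residual,
                         E0=mapped.E0, J_prime=mapped.J_prime)
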