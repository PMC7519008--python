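"""Barabási–Albert scale-free networks and network file IO.

The graphs used throughout the package are simple undirected graphs with
0-based contiguous integer node ids.  Generated networks follow the usual
linear-growth / preferential-attachment construction: ``m0`` initially
unconnected seed nodes, then one node at a time, each attaching ``m``
distinct edges to existing nodes with probability proportional to their
current degree.  Because the seed nodes start with degree zero, the very
first attachment step (and any step where every candidate has degree zero)
falls back to uniform sampling without replacement; thereafter attachment
is strictly degree-proportional.

For such a network the ensemble-expected adjacency entry is
``<A_ij> = k_i k_j / (2 m N)`` and the mean degree approaches ``2 m``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    EdgeListParseError,
    InvalidParameterError,
    MissingMetadataError,
    SelfLoopError,
)

__all__ = [
    "Network",
    "BAParams",
    "DegreeStatistics",
    "generate_ba_network",
    "mean_degree",
    "expected_adjacency_entry",
    "degree_statistics",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
]


class Network:
    """A simple undirected graph with optional BA provenance metadata.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``; node ids are ``0..N-1``.
    edges:
        Iterable of node pairs.  Pairs are canonicalised to ``i < j``;
        duplicates (in either orientation) are collapsed; self-loops are
        rejected.
    m, m0:
        Preferential-attachment parameters recorded for generated
        networks; ``None`` for imported ones.
    """

    def __init__(self, n_nodes: int, edges, m: int | None = None, m0: int | None = None):
        if n_nodes < 0:
            raise InvalidParameterError("n_nodes must be non-negative")
        arr = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges,
                         dtype=np.int64)
        arr = arr.reshape(-1, 2)
        if arr.size:
            if arr.min() < 0 or arr.max() >= n_nodes:
                raise InvalidParameterError(
                    f"edge endpoints must lie in [0, {n_nodes})"
                )
            if np.any(arr[:, 0] == arr[:, 1]):
                bad = arr[arr[:, 0] == arr[:, 1]][0, 0]
                raise SelfLoopError(f"self-loop at node {bad} is not allowed")
            arr = np.sort(arr, axis=1)
            arr = np.unique(arr, axis=0)
        else:
            arr = arr.reshape(0, 2)
        self.n_nodes = int(n_nodes)
        self.edges = arr
        self.m = None if m is None else int(m)
        self.m0 = None if m0 is None else int(m0)
        deg = np.zeros(n_nodes, dtype=np.int64)
        if arr.size:
            deg = (np.bincount(arr[:, 0], minlength=n_nodes)
                   + np.bincount(arr[:, 1], minlength=n_nodes))
        self.degree_sequence = deg
        self._csr: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(indptr, indices)`` of the symmetric adjacency in CSR form."""
        if self._csr is None:
            rows = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            order = np.argsort(rows, kind="stable")
            indices = cols[order]
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.cumsum(np.bincount(rows, minlength=self.n_nodes), out=indptr[1:])
            self._csr = (indptr, indices.astype(np.int64))
        return self._csr

    def neighbors(self, i: int) -> np.ndarray:
        indptr, indices = self.adjacency_csr()
        return indices[indptr[i]:indptr[i + 1]]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_networkx(cls, g, m: int | None = None, m0: int | None = None) -> "Network":
        """Build a :class:`Network` from a networkx graph.

        Node labels are mapped to 0-based contiguous ids in sorted order
        (numeric sort where the labels are integer-like).
        """
        labels = list(g.nodes())
        try:
            labels = sorted(labels, key=int)
        except (TypeError, ValueError):
            labels = sorted(labels, key=str)
        index = {lab: i for i, lab in enumerate(labels)}
        edges = [(index[u], index[v]) for u, v in g.edges()]
        return cls(len(labels), edges, m=m, m0=m0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        meta = f", m={self.m}, m0={self.m0}" if self.m is not None else ""
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges}{meta})"


@dataclass(frozen=True)
class BAParams:
    """Generator parameters for an ensemble of BA networks."""

    n_nodes: int = 5000
    m: int = 5
    m0: int | None = None


def generate_ba_network(n_nodes: int, m: int, m0: int | None = None,
                        seed: int = 0) -> Network:
    """Grow a Barabási–Albert network by preferential attachment.

    ``m0`` defaults to ``m``.  Requires ``m <= m0 < n_nodes``.  The same
    seed always yields the identical edge set.
    """
    if m0 is None:
        m0 = m
    if m < 1:
        raise InvalidParameterError(f"m must be >= 1 (got m={m})")
    if m > m0:
        raise InvalidParameterError(
            f"attachment count m={m} exceeds initial node count m0={m0} "
            "(constraint m <= m0 violated)")
    if m0 >= n_nodes:
        raise InvalidParameterError(
            f"initial node count m0={m0} must be smaller than n_nodes={n_nodes} "
            "(constraint m0 < n_nodes violated)")
    rng = np.random.default_rng(seed)
    degree = np.zeros(n_nodes, dtype=np.float64)
    edges = np.empty((m * (n_nodes - m0), 2), dtype=np.int64)
    pos = 0
    for v in range(m0, n_nodes):
        weights = degree[:v]
        total = weights.sum()
        if total == 0.0:
            targets = rng.choice(v, size=m, replace=False)
        else:
            targets = rng.choice(v, size=m, replace=False, p=weights / total)
        for t in targets:
            edges[pos, 0] = t
            edges[pos, 1] = v
            pos += 1
        degree[targets] += 1.0
        degree[v] += m
    return Network(n_nodes, edges, m=m, m0=m0)


def mean_degree(network: Network) -> float:
    """Mean degree ``(1/N) sum_i k_i``; approaches ``2m`` for BA networks."""
    if network.n_nodes == 0:
        raise InvalidParameterError("network has no nodes")
    return float(network.degree_sequence.mean())


def expected_adjacency_entry(network: Network, i: int, j: int) -> float:
    """Annealed (ensemble-expected) adjacency entry ``k_i k_j / (2 m N)``.

    Requires generator metadata ``m``; the value is clipped to [0, 1].
    """
    if network.m is None:
        raise MissingMetadataError(
            "expected adjacency requires the BA attachment parameter m; "
            "this network was imported without generator metadata")
    if i == j:
        raise InvalidParameterError("expected adjacency is defined for i != j")
    k = network.degree_sequence
    p = k[i] * k[j] / (2.0 * network.m * network.n_nodes)
    return float(min(max(p, 0.0), 1.0))


@dataclass(frozen=True)
class DegreeStatistics:
    """Summary of a degree sequence.

    ``tail_exponent`` is the continuous maximum-likelihood power-law
    exponent fitted to degrees ``k >= k_min``; it is ``None`` for small
    (< 100 nodes) or degenerate degree distributions.
    """

    mean: float
    max: int
    tail_exponent: float | None
    k_min: int | None


def degree_statistics(network: Network) -> DegreeStatistics:
    k = network.degree_sequence
    mean = float(k.mean()) if k.size else 0.0
    kmax = int(k.max()) if k.size else 0
    exponent = None
    kmin_used = None
    if network.n_nodes >= 100:
        kmin = network.m if network.m is not None else max(1, int(k[k > 0].min()))
        tail = k[k >= kmin].astype(np.float64)
        if tail.size >= 10:
            logsum = float(np.log(tail / kmin).sum())
            if logsum > 0.0:  # degenerate (all k == kmin) gives 0
                exponent = 1.0 + tail.size / logsum
                kmin_used = int(kmin)
    return DegreeStatistics(mean=mean, max=kmax, tail_exponent=exponent, k_min=kmin_used)


def write_edge_list(network: Network, path) -> None:
    """Write the edge set as two whitespace-separated integer columns."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nodes={network.n_nodes} edges={network.n_edges}\n")
        for i, j in network.edges:
            fh.write(f"{i} {j}\n")


def read_edge_list(path, m: int | None = None, m0: int | None = None) -> Network:
    """Read an edge list (two integer columns, ``#`` comments ignored).

    Duplicate and reversed-duplicate lines are collapsed; self-loops are
    rejected.  ``n_nodes`` is taken as the largest id plus one.
    """
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"{path}: line {ln}: expected two columns, got {len(parts)}",
                    line_number=ln)
            try:
                i, j = int(parts[0]), int(parts[1])
            except ValueError:
                raise EdgeListParseError(
                    f"{path}: line {ln}: non-integer node id", line_number=ln) from None
            if i < 0 or j < 0:
                raise EdgeListParseError(
                    f"{path}: line {ln}: negative node id", line_number=ln)
            if i == j:
                raise SelfLoopError(f"{path}: line {ln}: self-loop at node {i}")
            edges.append((i, j))
    n_nodes = 1 + max((max(e) for e in edges), default=-1)
    return Network(n_nodes, edges, m=m, m0=m0)


def write_graphml(network: Network, path) -> None:
    import networkx as nx

    nx.write_graphml(network.to_networkx(), path)


def read_graphml(path, m: int | None = None, m0: int | None = None) -> Network:
    """Read nodes and edges from a GraphML file (attributes are ignored)."""
    import networkx as nx

    g = nx.read_graphml(path)
    g = nx.Graph(g)  # drop directionality / multi-edges if present
    net = Network.from_networkx(g, m=m, m0=m0)
    return net
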