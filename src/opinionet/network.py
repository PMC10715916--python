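"""Homophilic two-ring-lattice interaction networks with link rewiring.

The society is split into two equally sized social identity groups (red and
blue).  Each group forms a ring lattice with ``k_in`` in-group links per
agent; red agent i additionally links to the ``k_out`` circularly closest
blue agents.  Links are then rewired with probability ``p`` — Watts–Strogatz
style for in-group links, and by re-targeting the blue endpoint for
out-group links — which preserves the in-group and out-group edge counts
exactly and therefore the degree of homophily.

``p → 0`` gives a highly clustered, regular, local topology; ``p → 1`` gives
a highly random topology resembling a stochastic block model with prescribed
in-/out-group link counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np

__all__ = [
    "RED",
    "BLUE",
    "SocialNetwork",
    "NetworkStats",
    "build_homophilic_lattice",
    "rewire",
    "network_stats",
    "write_network_csvs",
    "read_network_csvs",
]

RED, BLUE = 0, 1
_IDENTITY_NAMES = {RED: "red", BLUE: "blue"}
_IDENTITY_CODES = {"red": RED, "blue": BLUE}


@dataclass
class SocialNetwork:
    """Undirected labelled interaction graph with link bookkeeping.

    Edges are stored owner-first in construction order: for in-group links
    the owner is the lower-offset lattice endpoint of the Watts–Strogatz
    sweep, for out-group links the red endpoint.  Rewiring retains the owner
    and re-targets the other endpoint.
    """

    n: int
    identity: np.ndarray  # int8 per node, RED=0 / BLUE=1
    edges: np.ndarray  # (E, 2) int32, owner first
    edge_is_ingroup: np.ndarray  # (E,) bool
    k_in: int
    k_out: int
    p: float = 0.0

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=np.int8)
        self.edges = np.asarray(self.edges, dtype=np.int32).reshape(-1, 2)
        self.edge_is_ingroup = np.asarray(self.edge_is_ingroup, dtype=bool)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_ingroup_edges(self) -> int:
        return int(self.edge_is_ingroup.sum())

    @property
    def n_outgroup_edges(self) -> int:
        return int((~self.edge_is_ingroup).sum())

    def group_nodes(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.identity == group)

    def neighbor_sets(self) -> list[set[int]]:
        nbrs: list[set[int]] = [set() for _ in range(self.n)]
        for u, v in self.edges:
            nbrs[u].add(int(v))
            nbrs[v].add(int(u))
        return nbrs

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour lists in CSR form (indptr, indices), neighbours sorted."""
        nbrs = self.neighbor_sets()
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        for i, s in enumerate(nbrs):
            indptr[i + 1] = indptr[i] + len(s)
        indices = np.empty(indptr[-1], dtype=np.int32)
        for i, s in enumerate(nbrs):
            indices[indptr[i] : indptr[i + 1]] = sorted(s)
        return indptr, indices

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n):
            g.add_node(i, identity=_IDENTITY_NAMES[int(self.identity[i])])
        g.add_edges_from((int(u), int(v)) for u, v in self.edges)
        return g


class NetworkStats(NamedTuple):
    clustering: float
    avg_path_length: float
    connected: bool


def _validate_degrees(n: int, k_in: int, k_out: int) -> None:
    if n == 1:
        if k_in != 0 or k_out != 0:
            raise ValueError("a single-agent society cannot have links")
        return
    if n % 2 != 0:
        raise ValueError(f"n must be even (two equal identity groups), got {n}")
    m = n // 2
    if not (0 <= k_in < m):
        raise ValueError(f"k_in must satisfy 0 <= k_in < n/2, got {k_in}")
    if not (0 <= k_out <= m):
        raise ValueError(f"k_out must satisfy 0 <= k_out <= n/2, got {k_out}")
    if k_in % 2 == 1 and m % 2 != 0:
        raise ValueError(
            "odd k_in requires an even group size (diametric matching)"
        )


def build_homophilic_lattice(n: int, k_in: int, k_out: int) -> SocialNetwork:
    """Deterministic homophilic lattice of two coupled identity rings.

    Nodes 0..n/2-1 are red, n/2..n-1 blue (construction indexing only).
    Each agent links to its ``k_in`` nearest same-group ring neighbours; for
    odd ``k_in`` the (k_in-1)/2 nearest on each side plus a perfect matching
    at the diametric offset keep the lattice regular.  Red agent i links to
    blue agents at circulant offsets i, i+1, ..., i+k_out-1 (mod n/2).
    """
    _validate_degrees(n, k_in, k_out)
    if n == 1:
        return SocialNetwork(
            n=1,
            identity=np.zeros(1, dtype=np.int8),
            edges=np.empty((0, 2), dtype=np.int32),
            edge_is_ingroup=np.empty(0, dtype=bool),
            k_in=0,
            k_out=0,
        )
    m = n // 2
    identity = np.repeat(np.array([RED, BLUE], dtype=np.int8), m)
    edges: list[tuple[int, int]] = []
    is_in: list[bool] = []
    # in-group ring lattices, Watts-Strogatz sweep order: offset-major
    for base in (0, m):
        for s in range(1, k_in // 2 + 1):
            for i in range(m):
                edges.append((base + i, base + (i + s) % m))
                is_in.append(True)
        if k_in % 2 == 1:
            half = m // 2
            for i in range(half):
                edges.append((base + i, base + i + half))
                is_in.append(True)
    # out-group circulant links, owned by the red endpoint
    for i in range(m):
        for o in range(k_out):
            edges.append((i, m + (i + o) % m))
            is_in.append(False)
    return SocialNetwork(
        n=n,
        identity=identity,
        edges=np.array(edges, dtype=np.int32).reshape(-1, 2),
        edge_is_ingroup=np.array(is_in, dtype=bool),
        k_in=k_in,
        k_out=k_out,
        p=0.0,
    )


def rewire(
    net: SocialNetwork, p: float, rng: np.random.Generator
) -> SocialNetwork:
    """Rewire each link with probability ``p``, preserving link counts.

    In-group links follow the Watts–Strogatz procedure restricted to the
    owner's identity group: the non-owner endpoint is replaced by a uniformly
    chosen same-group node that is neither the owner nor already a
    neighbour.  Out-group links keep their red (owner) endpoint and
    re-target the blue endpoint to a uniformly chosen out-group node of the
    owner, avoiding duplicates.  A link with no legal target stays in place.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    edges = net.edges.copy()
    nbrs = net.neighbor_sets()
    group_members = {g: set(map(int, net.group_nodes(g))) for g in (RED, BLUE)}
    for e in range(edges.shape[0]):
        if rng.random() >= p:
            continue
        u, v = int(edges[e, 0]), int(edges[e, 1])
        if net.edge_is_ingroup[e]:
            pool = group_members[int(net.identity[u])]
            candidates = sorted(pool - nbrs[u] - {u})
        else:
            pool = group_members[1 - int(net.identity[u])]
            candidates = sorted(pool - nbrs[u])
        if not candidates:
            continue
        w = candidates[int(rng.integers(len(candidates)))]
        nbrs[u].discard(v)
        nbrs[v].discard(u)
        nbrs[u].add(w)
        nbrs[w].add(u)
        edges[e, 1] = w
    return SocialNetwork(
        n=net.n,
        identity=net.identity.copy(),
        edges=edges,
        edge_is_ingroup=net.edge_is_ingroup.copy(),
        k_in=net.k_in,
        k_out=net.k_out,
        p=p,
    )


def network_stats(net: SocialNetwork) -> NetworkStats:
    """Global clustering coefficient and mean shortest-path length.

    The clustering coefficient is the average of local clustering
    coefficients; the path length is averaged over the largest connected
    component when the graph is disconnected (``connected`` flags this).
    """
    if net.n == 0:
        raise ValueError("empty network")
    g = net.to_networkx()
    clustering = nx.average_clustering(g)
    connected = nx.is_connected(g)
    if connected:
        component = g
    else:
        component = g.subgraph(max(nx.connected_components(g), key=len))
    if component.number_of_nodes() < 2:
        apl = 0.0
    else:
        apl = nx.average_shortest_path_length(component)
    return NetworkStats(float(clustering), float(apl), connected)


def write_network_csvs(net: SocialNetwork, edge_path, node_path) -> None:
    """Export edge list and node table as deterministic CSVs.

    Edges are written as sorted (min, max) pairs in lexicographic order so
    repeated exports diff cleanly.
    """
    pairs = sorted((min(int(u), int(v)), max(int(u), int(v))) for u, v in net.edges)
    with open(edge_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_a", "node_b"])
        w.writerows(pairs)
    with open(node_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "identity"])
        for i in range(net.n):
            w.writerow([i, _IDENTITY_NAMES[int(net.identity[i])]])


def read_network_csvs(edge_path, node_path) -> SocialNetwork:
    """Load a network exported by :func:`write_network_csvs`.

    Edge ownership and k_in/k_out metadata are reconstructed from the node
    identities (owner = red endpoint for out-group edges, lower id for
    in-group edges); average degrees are recomputed from the counts.
    """
    with open(node_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    n = len(rows)
    identity = np.zeros(n, dtype=np.int8)
    for row in rows:
        identity[int(row["node_id"])] = _IDENTITY_CODES[row["identity"]]
    edges: list[tuple[int, int]] = []
    is_in: list[bool] = []
    with open(edge_path, newline="") as fh:
        for row in csv.DictReader(fh):
            a, b = int(row["node_a"]), int(row["node_b"])
            if identity[a] == identity[b]:
                edges.append((min(a, b), max(a, b)))
                is_in.append(True)
            else:
                owner, other = (a, b) if identity[a] == RED else (b, a)
                edges.append((owner, other))
                is_in.append(False)
    edges_arr = np.array(edges, dtype=np.int32).reshape(-1, 2)
    is_in_arr = np.array(is_in, dtype=bool)
    n_in = int(is_in_arr.sum())
    n_out = int((~is_in_arr).sum())
    return SocialNetwork(
        n=n,
        identity=identity,
        edges=edges_arr,
        edge_is_ingroup=is_in_arr,
        k_in=(2 * n_in) // n if n else 0,
        k_out=(2 * n_out) // n if n else 0,
    )
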