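"""Two-layer network construction and characterization.

A :class:`LayeredNetwork` holds two intra-connected subnetworks (layers A
and B, e.g. the right and left cortical hemispheres) plus a bipartite
inter-layer adjacency (e.g. callosal fibers).  The module covers three ways
of obtaining one:

* loading a labeled edge list (a real connectome with hemisphere labels),
* the synthetic modular generator: an Erdos-Renyi subnetwork rewired by
  degree-preserving double-edge swaps until a target average clustering
  coefficient is reached, then joined to a second copy by uniformly random
  inter-layer links,
* small deterministic toy fixtures for testing.

All adjacency matrices are dense binary ``numpy`` arrays; layer A nodes are
indexed ``0 .. n_a-1`` and layer B nodes ``n_a .. n_a+n_b-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.io
import scipy.sparse


class LabelingError(ValueError):
    """An edge endpoint has no layer label."""


class EdgeInputError(ValueError):
    """Malformed edge input (e.g. a self-loop)."""


class CapacityError(ValueError):
    """More inter-layer links requested than distinct cross pairs exist."""


class EmptyLayerError(ValueError):
    """Statistics requested for a layer with no nodes."""


class RewiringConvergenceError(RuntimeError):
    """Target clustering not reached within the proposal budget.

    Attributes
    ----------
    achieved : float
        Average local clustering coefficient at the point of failure.
    """

    def __init__(self, message: str, achieved: float):
        super().__init__(message)
        self.achieved = achieved


def _validate_intra(adj: np.ndarray, name: str) -> None:
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"{name} must be square, got shape {adj.shape}")
    if not np.array_equal(adj, adj.T):
        raise ValueError(f"{name} must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")


@dataclass(frozen=True)
class LayeredNetwork:
    """Two intra-layer adjacencies plus the inter-layer adjacency.

    Parameters
    ----------
    adj_a, adj_b : ndarray
        Symmetric binary intra-layer adjacency matrices with zero diagonal.
    adj_ab : ndarray, shape (n_a, n_b)
        Binary inter-layer adjacency; ``adj_ab[i, j] = 1`` links node ``i``
        of layer A to node ``j`` of layer B.
    node_ids : tuple
        Original node labels, layer A first then layer B; preserved through
        filtering so that rows can be traced back to the input.
    """

    adj_a: np.ndarray
    adj_b: np.ndarray
    adj_ab: np.ndarray
    node_ids: tuple = field(default=())

    def __post_init__(self):
        adj_a = np.asarray(self.adj_a, dtype=np.int8)
        adj_b = np.asarray(self.adj_b, dtype=np.int8)
        adj_ab = np.asarray(self.adj_ab, dtype=np.int8)
        _validate_intra(adj_a, "adj_a")
        _validate_intra(adj_b, "adj_b")
        if adj_ab.shape != (adj_a.shape[0], adj_b.shape[0]):
            raise ValueError(
                f"adj_ab shape {adj_ab.shape} inconsistent with layer sizes "
                f"({adj_a.shape[0]}, {adj_b.shape[0]})"
            )
        if not np.isin(adj_ab, (0, 1)).all():
            raise ValueError("adj_ab entries must be 0 or 1")
        object.__setattr__(self, "adj_a", adj_a)
        object.__setattr__(self, "adj_b", adj_b)
        object.__setattr__(self, "adj_ab", adj_ab)
        ids = self.node_ids
        if not ids:
            ids = tuple(range(adj_a.shape[0] + adj_b.shape[0]))
        if len(ids) != adj_a.shape[0] + adj_b.shape[0]:
            raise ValueError("node_ids length must equal total node count")
        object.__setattr__(self, "node_ids", tuple(ids))

    @property
    def n_a(self) -> int:
        return self.adj_a.shape[0]

    @property
    def n_b(self) -> int:
        return self.adj_b.shape[0]

    @property
    def n_total(self) -> int:
        return self.n_a + self.n_b

    @property
    def l_out(self) -> int:
        """Number of inter-layer links."""
        return int(self.adj_ab.sum())

    @property
    def k_in(self) -> np.ndarray:
        """Intra-layer degree of every node (layer A first, then B)."""
        return np.concatenate(
            [self.adj_a.sum(axis=1), self.adj_b.sum(axis=1)]
        ).astype(np.int64)

    @property
    def k_out(self) -> np.ndarray:
        """Inter-layer degree of every node (layer A first, then B)."""
        return np.concatenate(
            [self.adj_ab.sum(axis=1), self.adj_ab.sum(axis=0)]
        ).astype(np.int64)

    def layer_of(self, index: int) -> str:
        return "A" if index < self.n_a else "B"


@dataclass(frozen=True)
class NetworkStats:
    """Per-layer summary statistics of a :class:`LayeredNetwork`."""

    mean_degree_a: float
    mean_degree_b: float
    clustering_a: float
    clustering_b: float
    n_intra_links_a: int
    n_intra_links_b: int
    n_inter_links: int


def load_layered_edge_list(
    edges: Iterable[tuple], layer_of: Mapping
) -> LayeredNetwork:
    """Build a :class:`LayeredNetwork` from a labeled edge list.

    Every node in ``layer_of`` is kept (including nodes with no incident
    edge, so that isolated-node filtering remains meaningful); every edge
    endpoint must be labeled ``"A"`` or ``"B"``.  Duplicate edges collapse
    to a single link and storage is symmetric.
    """
    nodes_a = [n for n, lab in layer_of.items() if lab == "A"]
    nodes_b = [n for n, lab in layer_of.items() if lab == "B"]
    bad = [n for n, lab in layer_of.items() if lab not in ("A", "B")]
    if bad:
        raise LabelingError(f"labels must be 'A' or 'B'; got {bad[:5]!r}")
    index = {n: i for i, n in enumerate(nodes_a)}
    index.update({n: len(nodes_a) + i for i, n in enumerate(nodes_b)})
    n_a, n_b = len(nodes_a), len(nodes_b)
    adj_a = np.zeros((n_a, n_a), dtype=np.int8)
    adj_b = np.zeros((n_b, n_b), dtype=np.int8)
    adj_ab = np.zeros((n_a, n_b), dtype=np.int8)
    for u, v in edges:
        if u == v:
            raise EdgeInputError(f"self-loop on node {u!r}")
        if u not in index or v not in index:
            missing = u if u not in index else v
            raise LabelingError(f"node {missing!r} has no layer label")
        iu, iv = index[u], index[v]
        if iu < n_a and iv < n_a:
            adj_a[iu, iv] = adj_a[iv, iu] = 1
        elif iu >= n_a and iv >= n_a:
            adj_b[iu - n_a, iv - n_a] = adj_b[iv - n_a, iu - n_a] = 1
        else:
            if iu >= n_a:  # orient A -> B
                iu, iv = iv, iu
            adj_ab[iu, iv - n_a] = 1
    return LayeredNetwork(adj_a, adj_b, adj_ab, tuple(nodes_a + nodes_b))


def remove_isolated_nodes(net: LayeredNetwork) -> LayeredNetwork:
    """Drop every node with no intra- and no inter-layer link.

    Adjacency is reindexed contiguously per layer; ``node_ids`` keeps the
    surviving nodes' original labels.  An empty result is allowed.
    """
    degree = net.k_in + net.k_out
    keep = degree >= 1
    keep_a = keep[: net.n_a]
    keep_b = keep[net.n_a :]
    ids = np.asarray(net.node_ids, dtype=object)
    new_ids = tuple(ids[: net.n_a][keep_a]) + tuple(ids[net.n_a :][keep_b])
    return LayeredNetwork(
        net.adj_a[np.ix_(keep_a, keep_a)],
        net.adj_b[np.ix_(keep_b, keep_b)],
        net.adj_ab[np.ix_(keep_a, keep_b)],
        new_ids,
    )


def average_clustering(adj: np.ndarray) -> float:
    """Average local (Watts-Strogatz) clustering coefficient.

    Nodes of degree < 2 contribute 0, as in the standard convention.
    """
    g = nx.from_numpy_array(np.asarray(adj))
    if g.number_of_nodes() == 0:
        raise EmptyLayerError("clustering of an empty graph is undefined")
    return nx.average_clustering(g)


def compute_stats(net: LayeredNetwork) -> NetworkStats:
    """Per-layer mean degree, average clustering, and link counts.

    Clustering is computed on each layer's intra-adjacency only: inter-layer
    links do not contribute triangles.
    """
    if net.n_a == 0 or net.n_b == 0:
        raise EmptyLayerError("both layers must be non-empty for statistics")
    la = int(net.adj_a.sum()) // 2
    lb = int(net.adj_b.sum()) // 2
    return NetworkStats(
        mean_degree_a=2.0 * la / net.n_a,
        mean_degree_b=2.0 * lb / net.n_b,
        clustering_a=average_clustering(net.adj_a),
        clustering_b=average_clustering(net.adj_b),
        n_intra_links_a=la,
        n_intra_links_b=lb,
        n_inter_links=net.l_out,
    )


def generate_modular_subnetwork(
    n: int,
    mean_degree: float,
    c_target: float,
    seed=None,
    max_steps: int = 5_000_000,
    tol: float = 0.01,
    return_history: bool = False,
):
    """Generate one highly clustered subnetwork by greedy rewiring.

    Starts from an Erdos-Renyi G(n, m) graph with ``m = n * mean_degree / 2``
    edges and applies degree-preserving double-edge swaps, accepting a
    proposed swap only if it keeps the graph simple and strictly increases
    the average local clustering coefficient.  Rewiring stops as soon as the
    clustering reaches ``c_target`` or after ``max_steps`` proposals.

    Returns the dense adjacency matrix (and, if ``return_history``, the list
    of clustering values after each accepted swap, starting with the initial
    value).  Raises :class:`RewiringConvergenceError` if the budget is
    exhausted more than ``tol`` below the target.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= c_target <= 1.0:
        raise ValueError("c_target must be in [0, 1]")
    m2 = n * mean_degree
    if abs(m2 - round(m2)) > 1e-9 or round(m2) % 2:
        raise ValueError("n * mean_degree must be an even integer")
    m = int(round(m2)) // 2
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))

    nbrs = [set(g.neighbors(i)) for i in range(n)]
    edges = [tuple(e) for e in g.edges()]
    deg = np.array([len(s) for s in nbrs], dtype=np.int64)
    # per-node weight of one triangle in the average local clustering
    w = np.zeros(n)
    mask = deg >= 2
    w[mask] = 2.0 / (deg[mask] * (deg[mask] - 1.0)) / n
    tri = nx.triangles(g)
    c_avg = float(sum(tri[i] * w[i] * n for i in range(n))) / n
    history = [c_avg]

    accepted = 0
    if c_avg < c_target:
        for _ in range(max_steps):
            i, j = rng.integers(m, size=2)
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if rng.random() < 0.5:
                x, y = y, x
            if len({u, v, x, y}) < 4:
                continue
            # proposed swap: (u,v),(x,y) -> (u,x),(v,y)
            if x in nbrs[u] or y in nbrs[v]:
                continue
            c_uv = nbrs[u] & nbrs[v]
            c_xy = nbrs[x] & nbrs[y]
            c_ux = (nbrs[u] - {v}) & (nbrs[x] - {y})
            c_vy = (nbrs[v] - {u}) & (nbrs[y] - {x})
            delta = (
                w[u] * (len(c_ux) - len(c_uv))
                + w[v] * (len(c_vy) - len(c_uv))
                + w[x] * (len(c_ux) - len(c_xy))
                + w[y] * (len(c_vy) - len(c_xy))
                - sum(w[t] for t in c_uv)
                - sum(w[t] for t in c_xy)
                + sum(w[t] for t in c_ux)
                + sum(w[t] for t in c_vy)
            )
            if delta <= 1e-13:
                continue
            nbrs[u].remove(v)
            nbrs[v].remove(u)
            nbrs[x].remove(y)
            nbrs[y].remove(x)
            nbrs[u].add(x)
            nbrs[x].add(u)
            nbrs[v].add(y)
            nbrs[y].add(v)
            edges[i] = (u, x)
            edges[j] = (v, y)
            c_avg += delta
            accepted += 1
            history.append(c_avg)
            if c_avg >= c_target:
                break
        if c_avg < c_target - tol:
            raise RewiringConvergenceError(
                f"clustering {c_avg:.4f} < target {c_target} after "
                f"{max_steps} proposals ({accepted} accepted)",
                achieved=c_avg,
            )

    adj = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        adj[u, v] = adj[v, u] = 1

    comp = max(nx.connected_components(nx.from_numpy_array(adj)), key=len)
    if len(comp) < 0.95 * n:
        warnings.warn(
            f"giant component covers only {len(comp)}/{n} nodes after rewiring",
            stacklevel=2,
        )
    if return_history:
        return adj, history
    return adj


def interlayer_pair_permutation(n_a: int, n_b: int, seed=None) -> np.ndarray:
    """Random permutation of all ``n_a * n_b`` cross pairs (flat indices).

    Taking the first ``l`` entries for increasing ``l`` yields nested
    inter-link sets, which reduces realization variance along an
    inter-link-count sweep axis.
    """
    rng = np.random.default_rng(seed)
    return rng.permutation(n_a * n_b)


def add_interlayer_links(
    adj_a: np.ndarray,
    adj_b: np.ndarray,
    l_out: int,
    seed=None,
    pair_order: np.ndarray | None = None,
) -> LayeredNetwork:
    """Join two intra-layer adjacencies by ``l_out`` random inter-links.

    Exactly ``l_out`` distinct cross pairs are selected uniformly at random
    without replacement; the intra-layer adjacencies are left untouched.
    A precomputed ``pair_order`` (see :func:`interlayer_pair_permutation`)
    may be supplied to obtain nested link sets across calls.
    """
    n_a, n_b = adj_a.shape[0], adj_b.shape[0]
    if not 0 <= l_out <= n_a * n_b:
        raise CapacityError(
            f"l_out={l_out} outside [0, {n_a * n_b}] for layer sizes "
            f"({n_a}, {n_b})"
        )
    if pair_order is None:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(n_a * n_b, size=l_out, replace=False)
    else:
        chosen = np.asarray(pair_order)[:l_out]
    adj_ab = np.zeros(n_a * n_b, dtype=np.int8)
    adj_ab[chosen] = 1
    return LayeredNetwork(adj_a, adj_b, adj_ab.reshape(n_a, n_b))


def toy_fixture(kind: str, size: int = 6, seed=None) -> LayeredNetwork:
    """Deterministic small two-layer networks for tests.

    ``two_rings``
        Each layer a ``size``-cycle, one inter-link between node 0 of each.
    ``two_cliques``
        Each layer a complete graph on ``size`` nodes, one inter-link.
    ``paper_toy``
        The minimal labeled-edge-list example: two nodes in layer A joined
        by one edge, one node in layer B linked to the second A node.
    """
    if size < 3:
        raise ValueError("size must be >= 3")
    if kind == "two_rings":
        ring = np.zeros((size, size), dtype=np.int8)
        idx = np.arange(size)
        ring[idx, (idx + 1) % size] = 1
        ring[(idx + 1) % size, idx] = 1
        ab = np.zeros((size, size), dtype=np.int8)
        ab[0, 0] = 1
        return LayeredNetwork(ring, ring.copy(), ab)
    if kind == "two_cliques":
        clique = np.ones((size, size), dtype=np.int8) - np.eye(size, dtype=np.int8)
        ab = np.zeros((size, size), dtype=np.int8)
        ab[0, 0] = 1
        return LayeredNetwork(clique, clique.copy(), ab)
    if kind == "paper_toy":
        return load_layered_edge_list(
            [(1, 2), (2, 3)], {1: "A", 2: "A", 3: "B"}
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# file I/O: TSV edge lists / layer maps and Matrix Market adjacency triples

def read_edge_list_tsv(path) -> list[tuple[str, str]]:
    """Read whitespace- or tab-separated node pairs; a third (weight) column
    is ignored, since the model is unweighted."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise EdgeInputError(f"malformed edge line: {line!r}")
        out.append((parts[0], parts[1]))
    return out


def read_layer_map_tsv(path) -> dict[str, str]:
    """Read a two-column node -> {A, B} layer map."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise LabelingError(f"malformed layer-map line: {line!r}")
        out[parts[0]] = parts[1]
    return out


def save_matrix_market(net: LayeredNetwork, prefix) -> list[Path]:
    """Write ``<prefix>_a.mtx``, ``<prefix>_b.mtx``, ``<prefix>_ab.mtx``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for suffix, mat in (("a", net.adj_a), ("b", net.adj_b), ("ab", net.adj_ab)):
        p = prefix.parent / f"{prefix.name}_{suffix}.mtx"
        scipy.io.mmwrite(p, scipy.sparse.coo_matrix(mat), field="integer")
        paths.append(p)
    return paths


def load_matrix_market(prefix) -> LayeredNetwork:
    """Load a network written by :func:`save_matrix_market`."""
    prefix = Path(prefix)
    mats = []
    for suffix in ("a", "b", "ab"):
        p = prefix.parent / f"{prefix.name}_{suffix}.mtx"
        mats.append(np.asarray(scipy.io.mmread(p).todense()))
    return LayeredNetwork(*mats)
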