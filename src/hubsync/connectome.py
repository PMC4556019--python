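"""Structural network construction and characterization.

Binary, undirected cortical networks: group-consensus thresholding of
per-subject adjacency matrices, degree-based hub (rich-club) selection,
normalized rich-club coefficients against degree-preserving nulls, and
assignment of nodes to functional modules (majority vote over label
counts, or modularity-based community detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "Connectome",
    "Partition",
    "SubjectStack",
    "consensus_matrix",
    "node_degrees",
    "select_hubs",
    "rich_club_coefficient",
    "majority_vote_modules",
    "detect_modules",
    "read_adjacency",
    "write_adjacency",
    "read_partition",
    "write_partition",
    "read_hub_list",
    "write_hub_list",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


def _validate_binary_symmetric(W: np.ndarray, *, name: str = "W") -> np.ndarray:
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {W.shape}")
    if W.shape[0] < 2:
        raise ValueError(f"{name} must have at least 2 nodes")
    vals = np.unique(W)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:10]}")
    W = W.astype(np.int8)
    if not np.array_equal(W, W.T):
        i, j = np.argwhere(W != W.T)[0]
        raise ValueError(f"{name} must be symmetric; {name}[{i},{j}] != {name}[{j},{i}]")
    if np.any(np.diag(W) != 0):
        i = int(np.flatnonzero(np.diag(W))[0])
        raise ValueError(f"{name} must have a zero diagonal; {name}[{i},{i}] != 0")
    return W


@dataclass(frozen=True)
class Connectome:
    """A binary undirected structural network.

    Parameters
    ----------
    W : (N, N) array of {0, 1}
        Symmetric adjacency matrix with zero diagonal.
    labels : sequence of str, optional
        Node identifiers; defaults to stringified 0-based indices.
    """

    W: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        W = _validate_binary_symmetric(self.W)
        object.__setattr__(self, "W", W)
        if not self.labels:
            object.__setattr__(self, "labels", tuple(str(i) for i in range(W.shape[0])))
        elif len(self.labels) != W.shape[0]:
            raise ValueError("labels length must match matrix size")
        else:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def N(self) -> int:
        return self.W.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.W.sum()) // 2

    @property
    def density(self) -> float:
        n = self.N
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1).astype(np.int64)

    def to_graph(self) -> nx.Graph:
        return nx.from_numpy_array(self.W)

    def edge_array(self) -> np.ndarray:
        """(E, 2) array of undirected edges with i < j."""
        iu, ju = np.triu_indices(self.N, k=1)
        mask = self.W[iu, ju] == 1
        return np.column_stack([iu[mask], ju[mask]])


@dataclass(frozen=True)
class Partition:
    """Node-to-module assignment plus a designated hub set.

    ``module_of[i]`` is the module id of node ``i``; ``hubs`` is the set of
    nodes treated as the rich club.  Module ids index the intra/inter-modular
    synchrony and mean-field influence sums.
    """

    module_of: np.ndarray
    hubs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        mod = np.asarray(self.module_of, dtype=np.int64)
        if mod.ndim != 1:
            raise ValueError("module_of must be 1-D")
        hubs = np.unique(np.asarray(self.hubs, dtype=np.int64))
        if hubs.size and (hubs.min() < 0 or hubs.max() >= mod.size):
            raise ValueError("hub ids outside node range")
        object.__setattr__(self, "module_of", mod)
        object.__setattr__(self, "hubs", hubs)

    @property
    def n_nodes(self) -> int:
        return self.module_of.size

    @property
    def module_ids(self) -> np.ndarray:
        return np.unique(self.module_of)

    def members(self, module_id: int) -> np.ndarray:
        out = np.flatnonzero(self.module_of == module_id)
        if out.size == 0:
            raise KeyError(f"no module with id {module_id}")
        return out

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.module_of, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def module_pairs(self) -> list[tuple[int, int]]:
        """All unordered distinct module pairs (alpha < beta)."""
        ids = self.module_ids
        return [(int(a), int(b)) for k, a in enumerate(ids) for b in ids[k + 1:]]

    def with_hubs(self, hubs: np.ndarray) -> "Partition":
        return Partition(self.module_of, hubs)


@dataclass(frozen=True)
class SubjectStack:
    """Per-subject binary adjacency matrices with identical node sets."""

    matrices: tuple[np.ndarray, ...]

    def __post_init__(self):
        if len(self.matrices) == 0:
            raise ValueError("subject stack is empty")
        mats = tuple(_validate_binary_symmetric(m, name=f"subject {k}")
                     for k, m in enumerate(self.matrices))
        if len({m.shape for m in mats}) != 1:
            raise ValueError("all subject matrices must share the same size")
        object.__setattr__(self, "matrices", mats)

    @property
    def S(self) -> int:
        return len(self.matrices)

    @property
    def N(self) -> int:
        return self.matrices[0].shape[0]


# ---------------------------------------------------------------------------
# Group consensus and degrees
# ---------------------------------------------------------------------------


def consensus_matrix(stack: SubjectStack, frac: float = 0.4) -> Connectome:
    """Group-consensus network: keep edges present in >= ``frac`` of subjects.

    The inclusive threshold follows the "at least" reading: an edge present
    in exactly ``frac * S`` subjects survives.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    counts = np.sum(np.stack(stack.matrices), axis=0)
    # guard against float-division wobble at the threshold: compare counts
    W = (counts >= frac * stack.S - 1e-12).astype(np.int8)
    np.fill_diagonal(W, 0)
    return Connectome(W)


def node_degrees(c: Connectome) -> np.ndarray:
    """Number of connections of each node."""
    return c.degrees()


def select_hubs(c: Connectome, n_hubs: int) -> np.ndarray:
    """The ``n_hubs`` highest-degree nodes, as a sorted index array.

    Ties at the degree cutoff are broken deterministically by
    (degree descending, node index ascending).
    """
    if not 1 <= n_hubs <= c.N:
        raise ValueError(f"n_hubs must be in [1, {c.N}], got {n_hubs}")
    deg = c.degrees()
    order = np.lexsort((np.arange(c.N), -deg))
    return np.sort(order[:n_hubs])


# ---------------------------------------------------------------------------
# Rich club
# ---------------------------------------------------------------------------


def _raw_rich_club(degrees: np.ndarray, edges: np.ndarray,
                   ks: np.ndarray) -> np.ndarray:
    """Density among nodes of degree > k, for each k in ``ks`` (NaN if < 2)."""
    edge_min_deg = np.minimum(degrees[edges[:, 0]], degrees[edges[:, 1]])
    sorted_emd = np.sort(edge_min_deg)
    sorted_deg = np.sort(degrees)
    out = np.empty(ks.size)
    for idx, k in enumerate(ks):
        m = degrees.size - np.searchsorted(sorted_deg, k, side="right")
        if m < 2:
            out[idx] = np.nan
            continue
        e = edges.shape[0] - np.searchsorted(sorted_emd, k, side="right")
        out[idx] = e / (m * (m - 1) / 2)
    return out


@njit(cache=True)
def _swap_kernel(edges, adj, pick, flip):  # pragma: no cover
    n_attempts = pick.shape[0]
    for t in range(n_attempts):
        a = pick[t, 0]
        b = pick[t, 1]
        if a == b:
            continue
        u, v = edges[a, 0], edges[a, 1]
        x, y = edges[b, 0], edges[b, 1]
        if flip[t]:
            x, y = y, x
        # proposed rewiring: (u, x) and (v, y)
        if u == x or v == y or adj[u, x] or adj[v, y]:
            continue
        adj[u, v] = adj[v, u] = False
        adj[x, y] = adj[y, x] = False
        adj[u, x] = adj[x, u] = True
        adj[v, y] = adj[y, v] = True
        edges[a, 0], edges[a, 1] = u, x
        edges[b, 0], edges[b, 1] = v, y


def _double_edge_swap(edges: np.ndarray, adj: np.ndarray, n_attempts: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving rewiring by repeated double-edge swaps (in place)."""
    E = edges.shape[0]
    pick = rng.integers(0, E, size=(n_attempts, 2))
    flip = rng.integers(0, 2, size=n_attempts).astype(np.bool_)
    _swap_kernel(edges, adj, pick, flip)
    return edges


def rich_club_coefficient(c: Connectome, k: int | None = None,
                          n_null: int = 100, seed: int = 0,
                          swaps_per_edge: int = 10):
    """Normalized rich-club coefficient phi(k).

    Raw phi(k) is the edge density among nodes of degree > k; it is divided
    by the mean raw coefficient over ``n_null`` degree-preserving rewired
    null networks (``swaps_per_edge * E`` double-edge-swap attempts each).
    Values above 1 indicate rich-club organization.  Where fewer than two
    nodes exceed the threshold the coefficient is not evaluable and NaN is
    returned.

    Returns a float when ``k`` is given, else a dict {k: phi_norm} for
    k = 0 .. max_degree - 1.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    deg = c.degrees()
    ks = np.array([k]) if k is not None else np.arange(int(deg.max()))
    raw = _raw_rich_club(deg, c.edge_array(), ks)

    rng = np.random.default_rng(seed)
    null_sum = np.zeros(ks.size)
    null_cnt = np.zeros(ks.size)
    E = c.n_edges
    for _ in range(n_null):
        edges = c.edge_array()
        adj = c.W.astype(bool).copy()
        _double_edge_swap(edges, adj, swaps_per_edge * E, rng)
        phi0 = _raw_rich_club(deg, edges, ks)
        ok = np.isfinite(phi0)
        null_sum[ok] += phi0[ok]
        null_cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = raw / (null_sum / np.maximum(null_cnt, 1))
    norm[null_cnt == 0] = np.nan
    if k is not None:
        return float(norm[0])
    return {int(kk): float(v) for kk, v in zip(ks, norm)}


# ---------------------------------------------------------------------------
# Module assignment
# ---------------------------------------------------------------------------


def majority_vote_modules(vote_counts) -> Partition:
    """Assign each node the module with the highest label count.

    ``vote_counts`` is a (node x module) non-negative count table (array or
    DataFrame whose columns are module ids).  Ties go to the lowest module
    id.  A node with an all-zero row has no evidence and raises.
    """
    if isinstance(vote_counts, pd.DataFrame):
        cols = np.asarray(vote_counts.columns)
        counts = vote_counts.to_numpy()
    else:
        counts = np.asarray(vote_counts)
        cols = np.arange(counts.shape[1])
    if counts.ndim != 2:
        raise ValueError("vote_counts must be 2-D (node x module)")
    if (counts < 0).any():
        raise ValueError("vote counts must be non-negative")
    zero_rows = np.flatnonzero(counts.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"node {int(zero_rows[0])} has all-zero vote counts")
    order = np.argsort(cols, kind="stable")
    # argmax over columns sorted by module id -> ties resolve to lowest id
    winners = cols[order][np.argmax(counts[:, order], axis=1)]
    return Partition(winners.astype(np.int64))


def detect_modules(c: Connectome, min_size: int = 8, seed: int = 0) -> Partition:
    """Modularity-based module detection with a minimum module size.

    Louvain modularity maximization (seeded), followed by merging any module
    smaller than ``min_size`` into the neighboring module it shares the most
    edges with, so every returned module has >= ``min_size`` nodes.
    """
    if not 1 <= min_size <= c.N:
        raise ValueError(f"min_size must be in [1, {c.N}]")
    communities = nx.community.louvain_communities(c.to_graph(), seed=seed)
    groups = [np.fromiter(cm, dtype=np.int64) for cm in communities]

    def inter_edges(a: np.ndarray, b: np.ndarray) -> int:
        return int(c.W[np.ix_(a, b)].sum())

    while len(groups) > 1:
        sizes = [g.size for g in groups]
        small = int(np.argmin(sizes))
        if sizes[small] >= min_size:
            break
        links = [inter_edges(groups[small], g) if j != small else -1
                 for j, g in enumerate(groups)]
        target = int(np.argmax(links))
        groups[target] = np.sort(np.concatenate([groups[target], groups[small]]))
        del groups[small]

    module_of = np.empty(c.N, dtype=np.int64)
    # stable ids: order modules by their smallest member node
    groups.sort(key=lambda g: int(g.min()))
    for mid, g in enumerate(groups):
        module_of[g] = mid
    return Partition(module_of)


# ---------------------------------------------------------------------------
# Text I/O (whitespace matrices, edge lists, TSV partitions, hub lists)
# ---------------------------------------------------------------------------


def read_adjacency(path) -> Connectome:
    """Read a binary adjacency from a whitespace N x N matrix or a
    2-column 0-based edge list (detected from the file shape)."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[0] == data.shape[1] and data.shape[0] > 2:
        return Connectome(_validate_binary_symmetric(data, name=str(path)))
    if data.shape[1] == 2:
        edges = data.astype(np.int64)
        n = int(edges.max()) + 1
        W = np.zeros((n, n), dtype=np.int8)
        W[edges[:, 0], edges[:, 1]] = 1
        W[edges[:, 1], edges[:, 0]] = 1
        np.fill_diagonal(W, 0)
        return Connectome(W)
    return Connectome(_validate_binary_symmetric(data, name=str(path)))


def write_adjacency(path, c: Connectome, *, edge_list: bool = False) -> None:
    if edge_list:
        header = "undirected edge list, 0-based node indices, i < j, one edge per line"
        np.savetxt(path, c.edge_array(), fmt="%d", header=header)
    else:
        header = f"binary symmetric adjacency, N={c.N}, 0-based node order"
        np.savetxt(path, c.W, fmt="%d", header=header)


def read_partition(path) -> Partition:
    """Read a TSV with columns node_id, module_id (0-based nodes)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["node_id", "module_id"], header=None,
                     dtype=np.int64)
    df = df.sort_values("node_id")
    nodes = df["node_id"].to_numpy()
    if not np.array_equal(nodes, np.arange(nodes.size)):
        raise ValueError(f"{path}: node ids must cover 0..N-1 exactly once")
    return Partition(df["module_id"].to_numpy())


def write_partition(path, p: Partition) -> None:
    with open(path, "w") as fh:
        fh.write("# node_id\tmodule_id (0-based)\n")
        for i, m in enumerate(p.module_of):
            fh.write(f"{i}\t{m}\n")


def read_hub_list(path) -> np.ndarray:
    hubs = np.loadtxt(path, comments="#", dtype=np.int64, ndmin=1)
    return np.unique(hubs)


def write_hub_list(path, hubs: np.ndarray) -> None:
    np.savetxt(path, np.sort(np.asarray(hubs, dtype=np.int64)), fmt="%d",
               header="hub node ids, one per line (0-based)")
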