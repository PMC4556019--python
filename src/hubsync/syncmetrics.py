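"""Synchronization observables.

Global order parameters (phase coherence r and synchronized-pair fraction
r_link), edgewise synchrony C, its binarization F, trial-averaged
synchronization probabilities r_ij, intra/inter-modular synchrony, and the
mean-field influence decomposition by functional module and hub set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, Partition
from .dynamics import Trajectory

__all__ = [
    "SyncEnsemble",
    "InfluenceProfile",
    "order_parameter_r",
    "edgewise_synchrony",
    "r_link",
    "binarize_synchrony",
    "sync_probability",
    "modular_synchrony",
    "module_influence",
    "group_influence",
    "write_matrix",
]

HUBS = "hubs"  # pseudo-module key for the hub set in influence/synchrony maps


@dataclass(frozen=True)
class SyncEnsemble:
    """Trial-aggregated synchrony at one coupling strength.

    ``C`` is the mean edgewise synchrony matrix, ``F_mean`` the
    trial-averaged binary synchrony (the probability r_ij that a pair is
    classified as synchronized), ``r``/``r_link`` the trial means of the two
    global order parameters.
    """

    C: np.ndarray
    F_mean: np.ndarray
    r: float
    r_link: float
    lam: float
    n_trials: int


@dataclass(frozen=True)
class InfluenceProfile:
    """Mean-field influence of each source group on one target node.

    Maps source group id (module id, or ``"hubs"``) to (D, R, phi): the
    number of the target's neighbors in the group, and the modulus/argument
    of their mean phasor.  Groups with D <= 1 have R fixed at 1 by
    construction and are flagged not-evaluable (R, phi = NaN).
    """

    target: int
    by_source: dict

    def evaluable(self, source) -> bool:
        d, r, _ = self.by_source[source]
        return d > 1 and np.isfinite(r)


def _theta_of(traj) -> np.ndarray:
    theta = traj.theta if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if theta.ndim != 2 or theta.shape[1] < 1:
        raise ValueError("need an (N, n_times) phase array with >= 1 sample")
    return theta


def order_parameter_r(traj) -> float:
    """Time-averaged modulus of the population-mean phasor.

    z(t) = (1/N) sum_j e^{i theta_j(t)} = r(t) e^{i Phi(t)}; the order
    parameter is the time mean of r(t): 0 for incoherence, 1 when all
    oscillators share a phase.
    """
    theta = _theta_of(traj)
    z = np.exp(1j * theta).mean(axis=0)
    return float(np.abs(z).mean())


def edgewise_synchrony(traj) -> np.ndarray:
    """Edgewise synchrony C_ij: modulus of the time-averaged phasor of the
    phase difference theta_i - theta_j.  Symmetric with unit diagonal; 1 for
    a constant lag, ~0 for a uniformly drifting difference."""
    theta = _theta_of(traj)
    Z = np.exp(1j * theta)
    C = np.abs(Z @ Z.conj().T) / theta.shape[1]
    np.fill_diagonal(C, 1.0)
    return np.minimum(C, 1.0)


def r_link(C: np.ndarray) -> float:
    """Mean off-diagonal edgewise synchrony: the fraction of node pairs
    interpreted as synchronized."""
    C = np.asarray(C)
    n = C.shape[0]
    if n < 2:
        raise ValueError("r_link needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    return float(C[off].mean())


def binarize_synchrony(C: np.ndarray, rl: float | None = None) -> np.ndarray:
    """Binary synchrony matrix F: the round(r_link * N(N-1)/2) unordered
    pairs with the largest C are marked 1 (mirrored), the rest 0.

    The edge count of F then matches the number of synchronized connections
    predicted by r_link.  Ties at the cutoff are broken by
    (C descending, i ascending, j ascending).  ``rl`` defaults to r_link(C)
    recomputed internally for consistency.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if rl is None:
        rl = r_link(C)
    n_mark = int(round(rl * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    vals = C[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    F = np.zeros((n, n), dtype=np.int8)
    sel = order[:n_mark]
    F[iu[sel], ju[sel]] = 1
    F[ju[sel], iu[sel]] = 1
    return F


def sync_probability(F_list) -> np.ndarray:
    """Trial-averaged binary synchrony r_ij = (1/n) sum_l F_ij(l): the
    probability that regions i and j are classified as synchronized."""
    F_list = list(F_list)
    if not F_list:
        raise ValueError("no trials supplied")
    shapes = {np.asarray(F).shape for F in F_list}
    if len(shapes) != 1:
        raise ValueError("inconsistent F shapes across trials")
    return np.mean([np.asarray(F, dtype=float) for F in F_list], axis=0)


def _as_nodes(p: Partition, group) -> np.ndarray:
    """A module id, the string 'hubs', or an explicit node collection."""
    if isinstance(group, str):
        if group != HUBS:
            raise KeyError(f"unknown group {group!r}")
        if p.hubs.size == 0:
            raise ValueError("partition has no hub set")
        return p.hubs
    if np.isscalar(group):
        return p.members(int(group))
    return np.unique(np.asarray(group, dtype=np.int64))


def modular_synchrony(r_ij: np.ndarray, p: Partition, alpha, beta=None) -> float:
    """Mean synchronization probability between (or within) node groups.

    For distinct groups: mean of r_ij over all cross pairs.  For
    ``alpha == beta`` (or ``beta`` omitted): mean over ordered within-group
    pairs i != j, i.e. denominator N_a (N_a - 1), so self-synchrony r_ii
    never enters and module size has no effect.  ``alpha``/``beta`` may be
    module ids, explicit node sets, or ``"hubs"``.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    a = _as_nodes(p, alpha)
    b = a if beta is None else _as_nodes(p, beta)
    same = a.size == b.size and np.array_equal(a, b)
    block = r_ij[np.ix_(a, b)]
    if same:
        if a.size < 2:
            raise ValueError("intra-group synchrony needs >= 2 nodes")
        return float((block.sum() - np.trace(block)) / (a.size * (a.size - 1)))
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap; inter-group synchrony undefined")
    return float(block.mean())


# ---------------------------------------------------------------------------
# Mean-field influence decomposition
# ---------------------------------------------------------------------------


def module_influence(theta_t: np.ndarray, c: Connectome, p: Partition,
                     target: int) -> InfluenceProfile:
    """Decompose the mean field seen by ``target`` into per-module and hub
    contributions at one time point.

    For each source group g, D_{k,g} counts the target's neighbors in g and
    R_{k,g} e^{i phi_{k,g}} is their mean phasor.  With D_{k,g} = 1 the
    radius is identically 1 and carries no coherence information, so such
    groups are flagged not-evaluable (NaN).
    """
    theta_t = np.asarray(theta_t, dtype=float)
    if theta_t.shape != (c.N,):
        raise ValueError("theta_t must have length N")
    nbr = np.flatnonzero(c.W[target])
    if nbr.size == 0:
        raise ValueError(f"node {target} is isolated; no mean field defined")
    groups: dict = {int(m): p.members(int(m)) for m in p.module_ids}
    if p.hubs.size:
        groups[HUBS] = p.hubs
    phasor = np.exp(1j * theta_t)
    out = {}
    for g, members in groups.items():
        sel = np.intersect1d(nbr, members)
        d = int(sel.size)
        if d <= 1:
            out[g] = (d, np.nan, np.nan)
        else:
            z = phasor[sel].mean()
            out[g] = (d, float(np.abs(z)), float(np.angle(z)))
    return InfluenceProfile(target=int(target), by_source=out)


def group_influence(traj, c: Connectome, p: Partition,
                    target_module, source) -> float:
    """Average influence R_{beta,source}: mean of R_{k,source} over the
    evaluable nodes k of the target module, then over sampled times.

    ``traj`` may be a Trajectory or an (N, n_times) phase array; ``source``
    is a module id, node set, or ``"hubs"``.  Returns NaN when no (node,
    time) instance is evaluable.
    """
    theta = _theta_of(traj)
    targets = _as_nodes(p, target_module)
    members = _as_nodes(p, source)
    src_mask = np.zeros(c.N, dtype=bool)
    src_mask[members] = True
    Wsrc = c.W.astype(float) * src_mask[None, :]
    D = Wsrc.sum(axis=1)  # D_{k,source} for every k
    Z = Wsrc @ np.exp(1j * theta)  # (N, n_times)
    ok = D[targets] > 1
    if not ok.any():
        return float("nan")
    k = targets[ok]
    R = np.abs(Z[k]) / D[k, None]
    return float(R.mean())


def write_matrix(path, M: np.ndarray, name: str = "matrix") -> None:
    np.savetxt(path, M, fmt="%.10g", delimiter="\t",
               header=f"{name}, N={M.shape[0]}, 0-based node order, TSV")
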