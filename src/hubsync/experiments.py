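"""Experiment orchestration.

Coupling-strength sweeps over many random-initial-condition trials,
targeted (hub-hub) versus random edge suppression, nodal frequency
perturbation with per-module dominant-frequency tracking, and the
statistical machinery (permutation tests, Bartlett's variance test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import Connectome, Partition
from .dynamics import OscillatorConfig, simulate_batch
from .syncmetrics import (HUBS, SyncEnsemble, binarize_synchrony,
                          edgewise_synchrony, group_influence, modular_synchrony,
                          r_link, sync_probability)

__all__ = [
    "SweepRecord",
    "FrequencyTrack",
    "run_sweep",
    "suppress_edges",
    "suppress_random_edges",
    "modularity_ratio",
    "perturb_frequencies",
    "dominant_module_frequency",
    "track_frequencies",
    "whole_brain_sync_point",
    "bartlett_frequency_test",
    "permutation_test",
]

# default coupling grid: 0.005 .. 0.075 in steps of 0.005, straddling the
# critical regime of the coupled-oscillator transition
DEFAULT_LAMBDA_GRID = tuple(round(0.005 * k, 3) for k in range(1, 16))


@dataclass(frozen=True)
class SweepRecord:
    """Per-coupling summaries of one sweep condition.

    ``ensembles`` maps lambda to a SyncEnsemble; ``modular`` maps lambda to
    {(alpha, beta): r_ab} including intra-module pairs (a, a), the hub
    pseudo-module ('hubs', 'hubs') and hub-module pairs (a, 'hubs');
    ``trial_stats`` maps lambda to per-trial scalar arrays (keys 'r',
    'r_link', 'intramod', 'global', 'intrahub') used by the permutation
    contrasts; ``influences`` (optional) maps lambda to
    {(target_module, source): R}.
    """

    condition: str
    lambda_grid: tuple[float, ...]
    n_trials: int
    base_seed: int
    ensembles: dict = field(default_factory=dict)
    modular: dict = field(default_factory=dict)
    trial_stats: dict = field(default_factory=dict)
    influences: dict | None = None


def run_sweep(c: Connectome, p: Partition, lambda_grid=DEFAULT_LAMBDA_GRID,
              n_trials: int = 100, base_seed: int = 0,
              cfg: OscillatorConfig | None = None, condition: str = "normal",
              compute_influences: bool = False, influence_trials: int = 10,
              ) -> SweepRecord:
    """Run ``n_trials`` Kuramoto trials at every coupling in ``lambda_grid``
    and aggregate all synchrony observables.

    Trial l at grid index g uses RNG seed ``base_seed + g * n_trials + l``,
    so records are fully reproducible and different couplings use disjoint
    streams.  Modular synchrony is computed from the trial-averaged binary
    synchrony r_ij; per-trial intramodular/global/intra-hub means of F are
    retained for permutation contrasts.
    """
    lambda_grid = tuple(float(l) for l in lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid is empty")
    base_cfg = cfg if cfg is not None else OscillatorConfig()
    module_ids = [int(m) for m in p.module_ids]
    groups = {m: p.members(m) for m in module_ids}
    offdiag = ~np.eye(c.N, dtype=bool)

    rec = SweepRecord(condition=condition, lambda_grid=lambda_grid,
                      n_trials=n_trials, base_seed=base_seed,
                      influences={} if compute_influences else None)
    for g, lam in enumerate(lambda_grid):
        run_cfg = OscillatorConfig(lam=lam, T=base_cfg.T, tau=base_cfg.tau,
                                   dt=base_cfg.dt, sample_dt=base_cfg.sample_dt)
        seed = base_seed + g * n_trials
        try:
            times, theta, omega = simulate_batch(run_cfg, c, n_trials, seed)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"simulation failed at lambda={lam} (trials seeded {seed}): {err}"
            ) from err
        C_sum = np.zeros((c.N, c.N))
        F_sum = np.zeros((c.N, c.N))
        tr = {k: np.empty(n_trials) for k in
              ("r", "r_link", "intramod", "global", "intrahub")}
        for l in range(n_trials):
            Z = np.exp(1j * theta[l])
            tr["r"][l] = np.abs(Z.mean(axis=0)).mean()
            C = np.abs(Z @ Z.conj().T) / theta.shape[2]
            np.fill_diagonal(C, 1.0)
            rl = C[offdiag].mean()
            F = binarize_synchrony(C, rl)
            C_sum += C
            F_sum += F
            tr["r_link"][l] = rl
            tr["global"][l] = F[offdiag].mean()
            tr["intramod"][l] = np.mean([
                modular_synchrony(F, p, m) for m in module_ids
                if groups[m].size >= 2])
            tr["intrahub"][l] = (modular_synchrony(F, p, HUBS)
                                 if p.hubs.size >= 2 else np.nan)
        r_ij = F_sum / n_trials
        ens = SyncEnsemble(C=C_sum / n_trials, F_mean=r_ij,
                           r=float(tr["r"].mean()),
                           r_link=float(tr["r_link"].mean()),
                           lam=lam, n_trials=n_trials)
        mod = {}
        for i, a in enumerate(module_ids):
            if groups[a].size >= 2:
                mod[(a, a)] = modular_synchrony(r_ij, p, a)
            for b in module_ids[i + 1:]:
                mod[(a, b)] = modular_synchrony(r_ij, p, a, b)
        if p.hubs.size >= 2:
            mod[(HUBS, HUBS)] = modular_synchrony(r_ij, p, HUBS)
            for a in module_ids:
                rest = np.setdiff1d(groups[a], p.hubs)
                if rest.size:  # hub-module synchrony over non-hub members
                    mod[(a, HUBS)] = modular_synchrony(r_ij, p, rest, HUBS)
        rec.ensembles[lam] = ens
        rec.modular[lam] = mod
        rec.trial_stats[lam] = tr
        if compute_influences:
            sources = module_ids + ([HUBS] if p.hubs.size else [])
            infl = {}
            k = min(influence_trials, n_trials)
            for beta in module_ids:
                for src in sources:
                    vals = [group_influence(theta[l], c, p, beta, src)
                            for l in range(k)]
                    infl[(beta, src)] = float(np.nanmean(vals))
            rec.influences[lam] = infl
    return rec


# ---------------------------------------------------------------------------
# Connectivity suppression
# ---------------------------------------------------------------------------


def suppress_edges(c: Connectome, K) -> tuple[Connectome, int]:
    """Remove every edge whose BOTH endpoints lie in node set ``K``
    (e.g. all hub-to-hub connections); edges from ``K`` to the rest of the
    network are untouched.  Returns the suppressed network and the number
    of edges removed."""
    K = np.asarray(list(K) if not isinstance(K, np.ndarray) else K, dtype=np.int64)
    if K.size and (K.min() < 0 or K.max() >= c.N):
        raise ValueError("node set outside network")
    W = c.W.copy()
    removed = int(W[np.ix_(K, K)].sum()) // 2
    W[np.ix_(K, K)] = 0
    return Connectome(W, c.labels), removed


def suppress_random_edges(c: Connectome, n_remove: int, seed: int = 0) -> Connectome:
    """Remove ``n_remove`` uniformly random edges (the density-matched
    reference condition for targeted suppression)."""
    edges = c.edge_array()
    if n_remove > edges.shape[0]:
        raise ValueError(f"cannot remove {n_remove} of {edges.shape[0]} edges")
    rng = np.random.default_rng(seed)
    drop = rng.choice(edges.shape[0], size=n_remove, replace=False)
    W = c.W.copy()
    W[edges[drop, 0], edges[drop, 1]] = 0
    W[edges[drop, 1], edges[drop, 0]] = 0
    return Connectome(W, c.labels)


def modularity_ratio(record: SweepRecord) -> dict[float, float]:
    """Per-coupling ratio of mean intramodular synchrony to whole-brain
    synchrony (mean off-diagonal r_ij).  > 1 means modules are internally
    more synchronized than the network at large; NaN where the global
    synchrony is zero."""
    out = {}
    for lam in record.lambda_grid:
        intra = [v for (a, b), v in record.modular[lam].items()
                 if a == b and a != HUBS]
        F_mean = record.ensembles[lam].F_mean
        off = ~np.eye(F_mean.shape[0], dtype=bool)
        denom = F_mean[off].mean()
        out[lam] = float(np.mean(intra) / denom) if denom > 0 else float("nan")
    return out


def per_trial_modularity_ratio(record: SweepRecord, lam: float) -> np.ndarray:
    """Trial-level intramodular/global synchrony ratios at one coupling
    (sample unit for the suppression permutation contrast)."""
    tr = record.trial_stats[float(lam)]
    with np.errstate(invalid="ignore", divide="ignore"):
        return tr["intramod"] / tr["global"]


# ---------------------------------------------------------------------------
# Frequency perturbation and tracking
# ---------------------------------------------------------------------------


def perturb_frequencies(omega: np.ndarray, K) -> np.ndarray:
    """Increase the intrinsic angular frequency of every node in ``K`` by
    one (composable: applying twice adds two)."""
    omega = np.asarray(omega, dtype=float).copy()
    K = np.asarray(list(K) if not isinstance(K, np.ndarray) else K, dtype=np.int64)
    if K.size and (K.min() < 0 or K.max() >= omega.size):
        raise ValueError("node set outside network")
    omega[K] += 1.0
    return omega


def dominant_module_frequency(traj, p: Partition | None = None, group=None,
                              sample_dt: float = 1.0) -> float:
    """Dominant angular frequency of a node group: the non-DC bin with
    maximal power in the DFT of the group-mean phasor signal
    s(t) = (1/N_g) sum_{j in g} e^{i theta_j(t)}.

    Robust to phase wrapping; resolution is one DFT bin, 2*pi / window
    length.  ``traj`` may be a Trajectory (its own sampling interval is
    used) or an (N, n_times) phase array with ``sample_dt`` given.
    """
    from .dynamics import Trajectory
    if isinstance(traj, Trajectory):
        theta = traj.theta
        if traj.times.size >= 2:
            sample_dt = float(traj.times[1] - traj.times[0])
    else:
        theta = np.asarray(traj, float)
    if theta.shape[1] < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    if group is None:
        nodes = np.arange(theta.shape[0])
    else:
        from .syncmetrics import _as_nodes
        nodes = (_as_nodes(p, group) if p is not None
                 else np.asarray(group, dtype=np.int64))
    if nodes.size == 0:
        raise ValueError("empty group")
    s = np.exp(1j * theta[nodes]).mean(axis=0)
    spec = np.abs(np.fft.fft(s)) ** 2
    freqs = 2 * np.pi * np.fft.fftfreq(s.size, d=sample_dt)
    spec[0] = 0.0  # exclude DC
    return float(abs(freqs[int(np.argmax(spec))]))


@dataclass(frozen=True)
class FrequencyTrack:
    """Per-module dominant frequencies along a coupling grid.

    ``freqs[lam][group]`` is the array of per-trial dominant angular
    frequencies of that group; groups are the partition's module ids plus
    ``"perturbed"`` when a perturbed node set was tracked.
    """

    condition: str
    lambda_grid: tuple[float, ...]
    freqs: dict

    def group_means(self, lam: float) -> dict:
        return {g: float(np.mean(v)) for g, v in self.freqs[float(lam)].items()}


def track_frequencies(c: Connectome, p: Partition,
                      lambda_grid=DEFAULT_LAMBDA_GRID, n_trials: int = 5,
                      base_seed: int = 0, perturbed=None,
                      cfg: OscillatorConfig | None = None,
                      condition: str = "normal") -> FrequencyTrack:
    """Track each module's dominant frequency across the coupling grid,
    optionally with the node set ``perturbed`` offset by +1 in frequency.

    The perturbed set (when given) is tracked as its own group
    ``"perturbed"``; module groups exclude perturbed members so that module
    tracks reflect the unperturbed portion of the network.
    """
    lambda_grid = tuple(float(l) for l in lambda_grid)
    base_cfg = cfg if cfg is not None else OscillatorConfig()
    offset = None
    pert_nodes = None
    if perturbed is not None:
        pert_nodes = np.asarray(list(perturbed) if not isinstance(perturbed, np.ndarray)
                                else perturbed, dtype=np.int64)
        offset = np.zeros(c.N)
        offset[pert_nodes] = 1.0
    groups = {}
    for m in p.module_ids:
        members = p.members(int(m))
        if pert_nodes is not None:
            members = np.setdiff1d(members, pert_nodes)
        if members.size:
            groups[int(m)] = members
    if pert_nodes is not None:
        groups["perturbed"] = pert_nodes

    sample_dt = base_cfg.sample_dt
    freqs: dict = {}
    for g, lam in enumerate(lambda_grid):
        run_cfg = OscillatorConfig(lam=lam, T=base_cfg.T, tau=base_cfg.tau,
                                   dt=base_cfg.dt, sample_dt=sample_dt)
        seed = base_seed + g * n_trials
        _, theta, _ = simulate_batch(run_cfg, c, n_trials, seed,
                                     omega_offset=offset)
        freqs[lam] = {
            name: np.array([
                dominant_module_frequency(theta[l], group=members,
                                          sample_dt=sample_dt)
                for l in range(n_trials)])
            for name, members in groups.items()}
    return FrequencyTrack(condition=condition, lambda_grid=lambda_grid,
                          freqs=freqs)


def whole_brain_sync_point(track: FrequencyTrack,
                           rel_tol: float = 0.05) -> float:
    """Smallest coupling at which the lowest group frequency is within
    ``rel_tol`` (default 5 %) of the highest — the whole-brain
    synchronization point.  NaN if the grid never reaches it."""
    if not track.lambda_grid:
        raise ValueError("empty frequency track")
    for lam in track.lambda_grid:
        means = track.group_means(lam)
        fmin, fmax = min(means.values()), max(means.values())
        if fmin >= (1 - rel_tol) * fmax:
            return float(lam)
    return float("nan")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def bartlett_frequency_test(groups) -> tuple[float, float]:
    """Bartlett's homogeneity-of-variance test across groups of per-trial
    modular dominant frequencies: (statistic, chi-square p-value)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        if np.var(g) == 0:
            raise ValueError(f"group {i} has zero variance; statistic undefined")
    stat, pval = stats.bartlett(*groups)
    return float(stat), float(pval)


def permutation_test(values_a, values_b, n_perm: int = 10_000, seed: int = 0,
                     statistic=None) -> float:
    """Two-sided label-shuffle permutation p-value with add-one smoothing.

    ``statistic(a, b)`` defaults to the difference of group means; the
    p-value is (1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1), hence bounded
    below by 1/(n_perm + 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic is None:
        statistic = lambda x, y: np.mean(x) - np.mean(y)
    t_obs = abs(statistic(a, b))
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        t = abs(statistic(perm[:a.size], perm[a.size:]))
        if t >= t_obs - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)
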