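import itertools

import numpy as np
import pytest
from scipy import stats

from hubsync.connectome import Connectome, Partition
from hubsync.dynamics import OscillatorConfig, simulate
from hubsync.experiments import (FrequencyTrack, bartlett_frequency_test,
                                 dominant_module_frequency, modularity_ratio,
                                 per_trial_modularity_ratio, permutation_test,
                                 perturb_frequencies, run_sweep,
                                 suppress_edges, suppress_random_edges,
                                 track_frequencies, whole_brain_sync_point)


@pytest.fixture(scope="module")
def tiny_sweep(small_net):
    c, p = small_net
    return run_sweep(c, p, lambda_grid=[0.0, 0.5], n_trials=5, base_seed=7)


class TestRunSweep:
    def test_deterministic_from_base_seed(self, small_net):
        c, p = small_net
        a = run_sweep(c, p, [0.05], n_trials=3, base_seed=1)
        b = run_sweep(c, p, [0.05], n_trials=3, base_seed=1)
        assert np.array_equal(a.ensembles[0.05].F_mean, b.ensembles[0.05].F_mean)
        assert a.ensembles[0.05].r == b.ensembles[0.05].r

    def test_uncoupled_floor_and_symmetric_modules(self, tiny_sweep):
        ens = tiny_sweep.ensembles[0.0]
        assert ens.r_link < 0.15  # incoherent floor
        intra = [v for (a, b), v in tiny_sweep.modular[0.0].items() if a == b]
        assert max(intra) < 0.25

    def test_strong_coupling_reaches_global_synchrony(self, tiny_sweep):
        assert tiny_sweep.ensembles[0.5].r > 0.99
        assert tiny_sweep.ensembles[0.5].r_link > 0.99

    def test_empty_grid_rejected(self, small_net):
        c, p = small_net
        with pytest.raises(ValueError):
            run_sweep(c, p, [], n_trials=1, base_seed=0)


class TestSuppression:
    def test_only_within_set_edges_removed(self):
        W = np.zeros((3, 3), dtype=int)
        W[0, 1] = W[1, 0] = W[0, 2] = W[2, 0] = 1
        c2, removed = suppress_edges(Connectome(W), [0, 1])
        assert removed == 1
        assert c2.W[0, 1] == 0 and c2.W[0, 2] == 1

    def test_empty_and_full_sets(self, small_net):
        c, _ = small_net
        same, n0 = suppress_edges(c, [])
        assert n0 == 0 and np.array_equal(same.W, c.W)
        empty, nall = suppress_edges(c, np.arange(c.N))
        assert nall == c.n_edges and empty.n_edges == 0

    def test_random_removal_matches_count_and_seeds(self, small_net):
        c, p = small_net
        _, n = suppress_edges(c, p.hubs)
        r1 = suppress_random_edges(c, n, seed=4)
        r2 = suppress_random_edges(c, n, seed=4)
        assert c.n_edges - r1.n_edges == n
        assert np.array_equal(r1.W, r2.W)
        assert np.array_equal(suppress_random_edges(c, 0, seed=1).W, c.W)

    def test_removing_more_than_available_rejected(self, triangle):
        with pytest.raises(ValueError):
            suppress_random_edges(triangle, 4)

    def test_modularity_ratio_is_one_at_full_sync(self, tiny_sweep):
        ratios = modularity_ratio(tiny_sweep)
        assert ratios[0.5] == pytest.approx(1.0, abs=0.01)
        assert np.isfinite(list(ratios.values())).all()
        per_trial = per_trial_modularity_ratio(tiny_sweep, 0.5)
        assert per_trial.shape == (5,)
        assert np.allclose(per_trial, 1.0, atol=0.02)


class TestPerturbation:
    def test_offset_and_composability(self):
        om = np.array([0.3, 0.7, 0.1])
        out = perturb_frequencies(om, [0])
        assert out[0] == pytest.approx(1.3)
        assert np.array_equal(out[1:], om[1:])
        assert perturb_frequencies(out, [0])[0] == pytest.approx(2.3)
        assert np.array_equal(perturb_frequencies(om, []), om)

    def test_attractor_survives_perturbation(self, small_net):
        # at strong coupling the perturbed system still fully synchronizes,
        # at the mean of the *perturbed* frequencies
        c, p = small_net
        rng = np.random.default_rng(0)
        om = perturb_frequencies(rng.uniform(0, 1, c.N), p.hubs)
        th0 = rng.uniform(-np.pi, np.pi, c.N)
        traj = simulate(OscillatorConfig(lam=1.0, omega=om, theta0=th0), c)
        from hubsync.syncmetrics import order_parameter_r
        assert order_parameter_r(traj) > 0.99
        freq = np.polyfit(traj.times, traj.theta.mean(axis=0), 1)[0]
        assert freq == pytest.approx(om.mean(), abs=1e-3)


class TestDominantFrequency:
    def test_single_uncoupled_node(self):
        t = np.arange(400.0)
        theta = (0.5 * t)[None, :]
        f = dominant_module_frequency(theta, group=[0], sample_dt=1.0)
        assert f == pytest.approx(0.5, abs=2 * np.pi / 400)

    def test_synchronized_group_common_frequency(self):
        t = np.arange(400.0)
        theta = np.vstack([0.8 * t + 0.1, 0.8 * t - 0.2, 0.8 * t])
        f = dominant_module_frequency(theta, group=[0, 1, 2], sample_dt=1.0)
        assert f == pytest.approx(0.8, abs=2 * np.pi / 400)

    def test_two_tone_group_picks_a_tone_not_the_mean(self):
        t = np.arange(400.0)
        theta = np.vstack([0.3 * t, 0.7 * t])
        f = dominant_module_frequency(theta, group=[0, 1], sample_dt=1.0)
        bin_w = 2 * np.pi / 400
        assert min(abs(f - 0.3), abs(f - 0.7)) < bin_w
        assert abs(f - 0.5) > 5 * bin_w

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dominant_module_frequency(np.zeros((2, 10)), group=[])


class TestSyncPoint:
    def mk_track(self, freqs_by_lam):
        return FrequencyTrack(condition="test",
                              lambda_grid=tuple(freqs_by_lam),
                              freqs={lam: {i: np.array([f])
                                           for i, f in enumerate(fs)}
                                     for lam, fs in freqs_by_lam.items()})

    def test_five_percent_criterion_boundary(self):
        met = self.mk_track({0.01: (1.0, 0.96)})
        assert whole_brain_sync_point(met) == 0.01
        not_met = self.mk_track({0.01: (1.0, 0.94)})
        assert np.isnan(whole_brain_sync_point(not_met))

    def test_first_crossing_returned(self):
        track = self.mk_track({0.01: (1.0, 0.5), 0.02: (1.0, 0.8),
                               0.03: (1.0, 0.97), 0.04: (1.0, 0.99)})
        assert whole_brain_sync_point(track) == 0.03


class TestBartlett:
    def test_statistic_matches_textbook_formula(self, rng):
        groups = [rng.normal(0, s, n) for s, n in ((1, 12), (2, 17), (1.5, 9))]
        stat, _ = bartlett_frequency_test(groups)
        # independent textbook computation
        k = len(groups)
        n_i = np.array([g.size for g in groups])
        s2 = np.array([g.var(ddof=1) for g in groups])
        N = n_i.sum()
        sp2 = ((n_i - 1) * s2).sum() / (N - k)
        num = (N - k) * np.log(sp2) - ((n_i - 1) * np.log(s2)).sum()
        den = 1 + (np.sum(1 / (n_i - 1)) - 1 / (N - k)) / (3 * (k - 1))
        assert stat == pytest.approx(num / den, abs=1e-8)

    def test_type_one_error_near_nominal(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 15) for _ in range(4)]
            _, p = bartlett_frequency_test(groups)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)

    def test_power_against_strong_heterogeneity(self, rng):
        reject = 0
        reps = 300
        for _ in range(reps):
            _, p = bartlett_frequency_test([rng.normal(0, 1, 50),
                                            rng.normal(0, 5, 50)])
            reject += p < 0.05
        assert reject / reps > 0.99

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            bartlett_frequency_test([[1.0, 1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            bartlett_frequency_test([[1.0, 2.0]])


class TestPermutation:
    def test_identical_groups_near_one(self, rng):
        a = rng.normal(0, 1, 30)
        p = permutation_test(a, a.copy(), n_perm=500, seed=1)
        assert p > 0.8

    def test_disjoint_support_hits_smoothing_floor(self):
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        p = permutation_test(a, b, n_perm=10_000, seed=3)
        assert p == pytest.approx(1 / 10_001)

    def test_matches_exhaustive_enumeration(self):
        a = np.array([2.1, 3.3, 1.8, 4.0, 2.9])
        b = np.array([4.8, 5.1, 3.9, 6.0, 5.5])
        pool = np.concatenate([a, b])
        t_obs = abs(a.mean() - b.mean())
        hits = total = 0
        for idx in itertools.combinations(range(10), 5):
            sel = np.zeros(10, dtype=bool)
            sel[list(idx)] = True
            t = abs(pool[sel].mean() - pool[~sel].mean())
            hits += t >= t_obs - 1e-12
            total += 1
        exact = hits / total
        est = permutation_test(a, b, n_perm=20_000, seed=0)
        assert est == pytest.approx(exact, abs=0.01)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([], [1.0], n_perm=10)


class TestFrequencyTracking:
    def test_perturbed_group_tracked_separately(self, small_net):
        c, p = small_net
        track = track_frequencies(c, p, lambda_grid=[0.02], n_trials=2,
                                  base_seed=3, perturbed=p.hubs)
        groups = track.freqs[0.02]
        assert "perturbed" in groups
        # perturbed set (+1 offset) runs markedly faster while incoherent
        means = track.group_means(0.02)
        mods = [v for g, v in means.items() if g != "perturbed"]
        assert means["perturbed"] > max(mods) + 0.5

    def test_strong_coupling_entrains_everyone(self, small_net):
        c, p = small_net
        track = track_frequencies(c, p, lambda_grid=[1.0], n_trials=2,
                                  base_seed=3, perturbed=p.hubs)
        means = track.group_means(1.0)
        assert max(means.values()) - min(means.values()) < 0.05
        assert whole_brain_sync_point(track) == 1.0


class TestMonotonicity:
    def test_mean_r_nondecreasing_in_coupling(self, human_net):
        # stochastic ordering across the transition, up to one standard error
        c, p = human_net
        grid = [0.005, 0.02, 0.04, 0.08]
        rec = run_sweep(c, p, grid, n_trials=20, base_seed=55)
        means = [rec.trial_stats[l]["r"].mean() for l in grid]
        sems = [rec.trial_stats[l]["r"].std(ddof=1) / np.sqrt(20) for l in grid]
        for i in range(len(grid) - 1):
            assert means[i + 1] >= means[i] - (sems[i] + sems[i + 1])
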