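# Methods

## Model and protocol

The dynamics are the classical Kuramoto model on a binary undirected graph:
`dθ_i/dt = ω_i + λ Σ_j W_ij sin(θ_j − θ_i)`. All edges carry equal weight,
so the only structural information entering the dynamics is the topology.
The model has no delays, no noise term and no inertia; the fully
synchronized state is the attractor for large `λ`, rotating at the mean of
the intrinsic frequencies (the coupling terms cancel pairwise on a
symmetric `W`, so the population-mean phase velocity equals `mean(ω)` at
every instant).

Protocol constants and their defaults:

| parameter | default | meaning |
|---|---|---|
| `λ` | swept, 0.005–0.075 | global coupling applied to every edge |
| `T` | 700 | total integration time |
| `τ` | 300 | transient discarded before analysis |
| `dt` | 0.05 | RK4 step |
| `sample_dt` | 1.0 | output spacing → 400 retained samples |
| `ω_i` | U[0, 1) | intrinsic angular frequency, radians/time |
| `θ_i(0)` | U[−π, π) | initial phase |
| trials | 100 per λ | independent random initial conditions |

`ω` is drawn on the half-open interval; the closed upper boundary is
measure-zero. One RNG stream per trial, seeded `base_seed + trial_index`
(grid position `g` offsets by `g · n_trials`), so every record is
reproducible bit-for-bit and conditions can be paired by seed.

### Integrator

Fixed-step classical RK4. Phases are integrated and stored unwrapped so
spectra and instantaneous frequencies are well defined; phasor metrics wrap
implicitly. The kernel evaluates the coupling through per-node neighbor
sums of `sin θ` / `cos θ` (identity
`Σ_j W_ij sin(θ_j−θ_i) = cos θ_i Σ sin θ_j − sin θ_i Σ cos θ_j`) with a
vectorized polynomial sin/cos (fdlibm minimax kernels after range
reduction, absolute error < 1e-13), batching trials in the contiguous
dimension. In the contracting (locked) regime halving `dt` moves sampled
phases by < 1e-6 over a full run; inside the critical regime the dynamics
is sensitive to initial conditions, so trajectory-level convergence
degrades there while the trial-averaged statistics remain stable — all
dynamical assertions in the tests therefore either use the locked regime or
aggregate over trials.

### Mean field

`R_k e^{iϕ_k} = (1/D_k) Σ_j W_kj e^{iθ_j}` gives each node's local field;
the drive on node `k` is `λ D_k R_k sin(ϕ_k − θ_k)`, which reconstructs the
equation of motion exactly (checked to 1e-10). Note the compact one-line
"mean-field form" sometimes quoted without the `λ D_k` factor is not
dimensionally consistent with the coupled equations; the package treats the
coupled form as ground truth and verifies the substituted identity.
Splitting the neighbor sum by source group (each module, or the hub set)
yields the influence measures `R_{k,α}`; entries with `D_{k,α} ≤ 1` are
flagged not-evaluable because a single-neighbor radius is identically 1.
Influence profiles are evaluated at each retained sample and averaged over
the window (the alternative — one instantaneous evaluation — is noisier but
unbiased; the choice does not affect any directional conclusion).

## Synchrony metrics

`C_ij` uses all ordered node pairs; being symmetric with unit diagonal, the
binarization `F` operates on the `N(N−1)/2` unordered pairs and marks the
`round(r_link · N(N−1)/2)` largest, mirrored symmetrically, so the edge
count of `F` matches the count implied by reading `r_link` as a
synchronized-pair fraction. A literal ordered-pair count would double-count
each symmetric pair; the unordered implementation preserves the intended
edge-count identity. Rounding (rather than floor/ceil) at the threshold,
and ties broken by (C descending, i ascending, j ascending), keep the
operation deterministic. Intramodular synchrony divides by `N_α(N_α − 1)`
(self-pairs excluded) so module size does not bias it. The hub set is
handled as a pseudo-module throughout; for hub-module synchrony the module
side excludes its hub members so the two groups are disjoint.

## Networks

### Construction from data-like inputs

Group consensus keeps an edge present in at least `frac` (default 40 %) of
subjects — inclusive, following the "at least" reading. Hubs are the
`n_hubs` highest-degree nodes with deterministic tie-break (degree
descending, index ascending). The rich-club coefficient normalizes the
density among nodes of degree > k by the mean over degree-preserving
rewired nulls (double-edge swaps, 10·E attempts per null; 100–1000 nulls
depending on context); the null model and ensemble size are free choices
here since only the φ > 1 region is interpreted. Module detection is
Louvain modularity maximization (seeded) followed by merging any module
below `min_size` (default 8) into its most strongly connected neighbor
module; any modularity-maximizing method would do — planted-partition
recovery, not a particular algorithm's output, is the contract, and Louvain
recovers the planted 6-block networks at ~95 % label agreement where greedy
agglomeration stalls near 70 %. Majority-vote module assignment takes an
abstract node × module count table and assigns each node its argmax count,
ties to the lowest module id.

### Synthetic generator

The generator emulates only what the analysis consumes — topology: a
planted-partition (stochastic block) graph with hub densification.
Human-scale defaults: 219 nodes, 11 modules with sizes drawn from 11–31 and
nudged (within that range) to sum to 219, `p_intra = 0.35`,
`p_inter = 0.03`, 18 % hubs allocated ≥ 1 per module and proportionally to
module size, `p_hub_hub = 0.8`, and extra hub-to-periphery wiring
`p_hub_out = 0.15` (applied as a union with the block probability). These
values give within-module density ≈ 3× the overall density (≈ 0.12), hub
degrees that dominate the degree sequence (planted hubs = the top-degree
set), and a normalized rich-club coefficient ≈ 1.2–1.3 over the hub-degree
range. The macaque-style variant uses 78 nodes, 6 modules of ≥ 8,
`p_intra = 0.9`, `p_inter = 0.115`, 15 hubs with `p_hub_hub = 0.75`,
`p_hub_out = 0.08`, landing at density 0.276 ± 0.02 (regenerating with
shifted seeds when a draw falls outside the band); the strong block
contrast reflects the crisp modularity of tract-tracing connectomes.
Disconnected draws are repaired by adding minimal random bridging edges
(density drift ≪ 0.5 %). Subject stacks keep template edges with `p_keep`
(default 0.9) and add spurious edges with `p_spurious` (default 0.005) per
subject, making the 40 %-consensus recovery an explicit binomial-tail
exercise.

What the generator does *not* emulate: spatial embedding and distance-
dependent wiring, degree-sequence details of measured connectomes,
tractography biases, weighted connections. Consequently passing tests show
that the analysis machinery recovers planted structure and reproduces the
hub-centric contrasts on networks with the stated block/rich-club
statistics — not that any particular empirical effect size would be
reproduced on a measured connectome. On the synthetic network the
synchronization transition sits near λ ≈ 0.01–0.02 (its mean degree and
hub wiring differ from the measured networks, which transition near
0.02–0.04), so the experiment grids are positioned around the measured
transition of the synthetic network itself.

## Experiments

A sweep runs `n_trials` independent trials per coupling; per-trial `C`,
`r_link` and `F` are aggregated into `r_ij` and modular synchrony, and
per-trial intramodular/global/intra-hub means of `F` are retained as the
sample units for permutation contrasts. Desk-scale defaults use 100 trials
per coupling (configurable up to 10³); the contrasts of interest are
directional and already decisive at that scale.

Suppression removes every edge inside the hub set (`W_mn = 0` for
`m, n ∈ K`; hub-to-periphery edges untouched) and, as a control, an equal
number of uniformly random edges. Conditions are paired by seed: both use
identical initial-condition draws. The modularity ratio is the mean
intramodular synchrony over modules divided by the mean off-diagonal
`r_ij`.

Perturbation adds +1 to the intrinsic frequency of a node set (hubs, a
random set of equal size, or one module). Dominant module frequencies come
from the DFT of the group-mean phasor (robust to wrapping; resolution
2π/400 ≈ 0.016 rad/time, DC bin excluded); module groups exclude perturbed
members so they track the unperturbed portion. Whole-brain synchronization
is the smallest grid coupling at which the lowest group frequency is within
5 % of the highest. Because dominant frequencies are discrete bin values,
fully synchronized conditions produce exactly zero variance across modules;
Bartlett's test (provided for variance-homogeneity questions) is undefined
there and raises, so the acceptance summary reports the variance contrast
with a permutation test instead.

Permutation tests are two-sided on the difference of group means with
add-one smoothing, `p ≥ 1/(n_perm + 1)`; the sample unit is stated per
contrast (pair-level `r_ij` values for the hub-lead contrast, per-trial
ratios for suppression, per-trial across-module variances for
perturbation). Bartlett's statistic follows the standard chi-square form
via `scipy.stats.bartlett`.

## Degenerate inputs and numerical edges

- Isolated nodes: mean field undefined → NaN sentinels; influence of a
  group reached through ≤ 1 edge → not-evaluable.
- Rich club with < 2 surviving nodes at a threshold → NaN.
- `r_link` requires N ≥ 2; intra-group synchrony requires group size ≥ 2.
- Non-finite integration states raise with the failing trial and time.
- All text readers validate symmetry/binarity/zero-diagonal and report
  every violation with coordinates.

## Known limitations

Binary, undirected coupling only (no weights, delays, or directionality);
the generator's block model omits spatial constraints; dominant-frequency
resolution is one DFT bin, so sub-bin frequency differences are invisible;
and the greedy/Louvain modularity family gives no optimality guarantee —
only planted-structure recovery is asserted.
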