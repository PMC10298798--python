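# Methods

## Generative model

Activity `s` (N neurons × M time steps, entries in [0, 1]) is modeled
through membership weights `t` (A × N, columns on the probability simplex)
and ensemble activities `ω` (M × A, entries in [0, 1]). Each ensemble μ
carries four parameters: an affinity `n_μ` (Dirichlet-distributed across
ensembles), an activity rate `p_μ` (beta), and synchronization rates
`λ_1,μ`, `λ_0,μ` (beta) giving the propensity of member neurons to be active
while the ensemble is active or inactive. The likelihood is built so that
`(t, ω, s)` enter only through seven families of sufficient statistics —
weighted co-activation sums such as
`α̃₁,μ = Σ_k ω_kμ Σ_i t_μi s_ik` — which makes the parameters conjugate and
lets them be integrated out in closed form. The resulting marginalized
joint is a product of (multivariate) beta functions of prior-plus-statistic
arguments. When `t` is one-hot and `ω`, `s` binary, every statistic reduces
exactly to the integer count used by the binary hard-clustering baseline
(BIM); the continuous model is a strict generalization.

All beta functions are evaluated through `gammaln`; statistics reach
O(N·M) ≈ 10⁵ and direct `gamma` would overflow. The length-1 multivariate
beta is defined as 1 so the A = 1 edge case is well formed. The joint is
only ever used through differences in log space; its normalizing constant is
never materialized.

Prior hyperparameters default to 1 in every family (uniform betas, symmetric
Dirichlet) — the least-informative conjugate choice; they are overridable
via `MCMCConfig(prior_value=...)`.

## MCMC

One sweep performs, in order:

1. **ω phase.** For every (k, μ), a binary concentration state G* is drawn
   with P(G*=1) equal to the mean activity of ensemble μ at the other time
   steps. The entry moves to `(ω+α_ω)/(1+α_ω)` (G*=1) or `ω/(1+α_ω)`
   (G*=0) and is accepted by Metropolis–Hastings, where the reverse-move
   probability is that of the complementary state evaluated on the
   pre-update ω. In `bim` mode the proposal is the deterministic 0/1
   inversion with unit proposal ratio.
2. **t phase.** For every neuron, a concentration ensemble G* is drawn in
   proportion to ensemble sizes excluding that neuron; the whole membership
   column is shrunk by `1/(1+α_t)` and G* receives the released mass. The
   proposal ratio is the size ratio of the reverse and forward concentration
   ensembles on pre-update weights. In `bim` mode the proposal is the
   size-proportional categorical move with an extra `α_new`-weighted "new
   ensemble" outcome.
3. **Hyperparameter refresh.** Posterior values `α̂ = α_prior + α̃(state)`
   are recomputed from the *fixed* prior template — they are not accumulated
   into the prior of later sweeps, which would double-count data and
   diverge; acceptance ratios therefore always use the prior template, as in
   the marginalized joint where priors and statistics enter additively once.

Acceptance ratios are computed incrementally: an ω entry touches only its
ensemble's p- and λ-family beta terms, a t column touches the Dirichlet and
λ terms (the p terms cancel). The incremental path is exact and is verified
against two full evaluations of the joint to 1e-9 in the tests.

Design points that the update rules leave open, resolved here:

- **Reverse concentration state for t.** The reverse-move probability needs
  a "concentration ensemble before update" G⁰. We keep, per neuron, the
  most recently accepted G* (initialized to the argmax of the initial
  column) and use its pre-update size. For ω the reverse state is the
  binary complement of the proposed one.
- **Synchronous updates.** All acceptance decisions in a phase are computed
  against the same pre-sweep state and applied at once. This mirrors the
  parallel formulation of the algorithm and makes sweeps
  order-independent.
- **Non-reversibility.** The deterministic shrink-and-renormalize maps do
  not admit an exact reverse density, so the chain is not exactly
  reversible; the printed formulas are implemented as given and detailed
  balance is deliberately not asserted as a test property. One observable
  consequence: at small `α_t` the stationary behavior keeps membership
  spread over many ensembles (soft clustering), concentrating only as
  `α_t` grows — the granularity-control behavior that motivates the method.
- **Ensemble count.** In soft mode the slot count A_init (default 16) is an
  upper bound and never grows (`α_new = 0`); the reported count is the
  number of slots with total membership above `0.01·N`. In `bim` mode
  (default 50 slots, half the benchmark's neuron count) a "new ensemble"
  proposal claims the first empty slot, and is rejected if none is free.
- **Trials and convergence.** `run_inference` runs `n_trials` independent
  chains seeded `seed + r`, each for exactly `n_sweeps` sweeps (default
  1000); results aggregate across trials through the co-assignment matrix U
  to average out initial-condition dependence.

Default transition parameters: `α_ω = 1000` (drives ensemble activity
essentially binary in one accepted move), `α_t ∈ [0.1, 0.8]` with 0.5 as the
package default — the studied granularity range.

## Synthetic benchmark

The forward model emulates calcium imaging of a small structured network:

- **Network.** 8 structural ensembles, sizes (20, 10, 10, 10, 20, 10, 10,
  10). Within an ensemble: excitatory synapses (weight 0.08) with
  probability 0.5 and symmetric gap junctions (weight 0.3) with probability
  0.8. Across ensembles, only E1→E2 (+0.08), E1→E3 (−0.08), E6→E5 (+0.08),
  E7→E5 (−0.08), each with probability 0.5. E4 and E8 are deliberately
  unconnected to the rest.
- **Dynamics.** Leaky integrate-and-fire with membrane time constant 0.05
  (E1–E4) or 0.1 (E5–E8), rest 0, resistance 1, threshold 0.2, spike value
  1, reset 0, Gaussian noise magnitude 0.2, integrated by Euler–Maruyama
  with step `dτ = 0.001` time units. Chemical input is a logistic gate of
  the presynaptic potential (half-point 0.3, width 0.1); gap input is ohmic
  in the potential difference (and sums to zero network-wide by symmetry).
- **Inputs.** Scenario 1: constant 0.3 to all neurons. Scenario 2: one
  shared square wave (8 equal epochs, alternating on/off). Scenario 3: four
  staggered schedules, identical within the pairs {E1,E5}, {E2,E6},
  {E3,E7}, {E4,E8} (group g on during epochs g and g+4 of 8). The epoch
  boundaries are a package choice — only the qualitative on/off block
  structure is prescribed by the benchmark.
- **Fluorescence.** dF/dτ = (f(V) − F)/τ_F with τ_F = 0.1, calcium taken
  proportional to V with unit constant, and Hill response
  f(c) = F_max c^h/(K_D^h + c^h) (F_max = 5, K_D = 0.3, h = 3; zero for
  negative c). Integrated at full resolution; every 10th substep is kept as
  one of M = 2000 recorded frames (total simulated time 20 units, ≥ 50
  steps per membrane time constant). Frames are min–max rescaled per neuron
  to [0, 1]; for the binary baseline, a sample is a spike when it strictly
  exceeds both neighbors and a height threshold (default 0.3) — plateaus
  and endpoints are never peaks.

What the generator does *not* emulate: calcium buffering/extrusion,
indicator photophysics, measurement noise in the optics, and slow drifts of
real recordings. Passing the recovery and granularity tests therefore shows
the inference behaves correctly on data matching its own assumptions and on
LIF-generated non-stationary data, not that it is robust to every artifact
of real imaging.

Reduced study sizes: tests and the acceptance script use a scaled network
(sizes (8, 4, 4, 4, 8, 4, 4, 4), N = 40, M = 500 frames) and 300–1000
sweeps, the package's standard quick-benchmark configuration; the full
N = 100, M = 2000 setup is available through the same functions and CLI.

## Analysis

`U_ij = Σ_r Σ_μ t^r_μi t^r_μj` aggregates co-assignment over trials (raw
sum by default; per-trial normalization divides by the trial count so the
diagonal is bounded by 1 — useful when comparing across configurations).
`Ũ_ij = Σ_k s_ik s_jk` summarizes raw activity; for binary data it is the
integer co-activation count. Dendrograms use the distance
`D = max(U) − U` with zero diagonal and average linkage by default
(complete/single available); the linkage and transform are package choices —
dendrogram comparisons are qualitative. Partitions are extracted by cutting
at a cluster count or height; trees export to Newick and merge-table CSV.

A consequence worth noting: with per-trial normalization, fully soft
memberships give `U ≈ 1/A_init` uniformly, the *minimum* of mean pairwise
similarity, and hence near-zero dendrogram distances; hard clustering gives
block-structured U and large distances. The granularity effect of `α_t` is
therefore quantified here as the mean off-diagonal dendrogram distance
increasing with `α_t`.

## Numerical choices and limitations

- Zero-probability proposals (empty reverse ensemble, zero proposal mass)
  are treated as immediate rejections with a logged warning.
- Label permutation symmetry of the joint is exact; inferred ensemble
  labels are arbitrary and only partition structure is meaningful.
- Constant fluorescence rows cannot be rescaled and raise an error rather
  than silently producing NaNs.
- Single-neuron (N = 1) or single-frame (M = 1) inputs are rejected by the
  concentration proposals, whose definitions require a nonempty complement.
- The sampler is single-threaded and deterministic for a given seed; trial
  r of a run uses seed `base + r`.
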