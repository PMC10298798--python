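"""Metropolis–Hastings sampler with Dirichlet-process-style proposals.

One sweep alternates: (a) for every (time step, ensemble) pair, propose a
concentration move of the ensemble activity ``omega`` toward 0 or 1 and
accept by Metropolis–Hastings; (b) for every neuron, propose concentrating
its membership column on a "concentration ensemble" drawn in proportion to
ensemble size and accept likewise; (c) refresh the posterior hyperparameters
from the fixed prior template and the current state.  All acceptance
decisions within a phase are computed against the same pre-sweep state and
applied synchronously.

Acceptance ratios are computed incrementally: a single-entry change of
``omega`` touches only the p- and lambda-family beta terms of its ensemble,
and a single-column change of ``t`` touches the Dirichlet term plus the
lambda terms; everything else cancels.  The incremental path is tested
against full re-evaluations of the marginalized joint.

In ``bim`` mode the sampler is the binary baseline: one-hot memberships,
binary ensemble activity, deterministic 0/1 inversion proposals for
``omega``, and a size-proportional categorical proposal for membership that
may open a new (empty) ensemble slot with weight ``alpha_new``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .model import (
    ActivityMatrix,
    PriorHyperparameters,
    compute_sufficient_stats,
    log_beta,
    log_marginal_joint,
    posterior_hyperparameters,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MCMCConfig",
    "SamplerState",
    "InferenceResult",
    "initialize_state",
    "propose_concentration_t",
    "apply_weight_transition",
    "weight_hastings_ratio",
    "propose_concentration_omega",
    "apply_omega_transition",
    "bim_weight_proposal",
    "weight_log_posterior_ratio",
    "omega_log_posterior_ratio",
    "sweep",
    "run_inference",
    "effective_ensemble_count",
]


@dataclass
class MCMCConfig:
    """Sampler settings.

    Defaults follow the soft-clustering study conditions: 16 initial
    ensemble slots, 10 independent trials of 1000 sweeps, omega transition
    parameter 1000 (drives ensemble activity toward binary), and a membership
    transition parameter alpha_t controlling clustering granularity (larger
    values harden the clustering; the study sweeps {0.1, 0.3, 0.5, 0.8}).
    ``alpha_new`` only applies in ``bim`` mode, where new ensembles may open;
    in soft mode it must be 0 (the slot count A_init is the upper bound).
    """

    n_ensembles: int = 16          # A_init
    n_trials: int = 10             # r_max
    n_sweeps: int = 1000           # gamma_max
    alpha_t: float = 0.5
    alpha_omega: float = 1000.0
    alpha_new: float = 0.0
    mode: str = "soft"
    seed: int = 0
    prior_value: float = 1.0

    def __post_init__(self):
        if self.mode not in ("soft", "bim"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.n_ensembles, self.n_trials, self.n_sweeps) < 1:
            raise ValueError("n_ensembles, n_trials, n_sweeps must be >= 1")
        if self.alpha_t < 0 or self.alpha_omega < 0 or self.alpha_new < 0:
            raise ValueError("transition parameters must be nonnegative")
        if self.mode == "soft" and self.alpha_new != 0:
            raise ValueError("alpha_new must be 0 in soft mode")

    def make_prior(self) -> PriorHyperparameters:
        return PriorHyperparameters.uniform(self.n_ensembles, self.prior_value)


@dataclass
class SamplerState:
    """Mutable sampler state: one MCMC chain."""

    t: np.ndarray                       # (A, N) membership weights
    omega: np.ndarray                   # (M, A) ensemble activity
    last_concentration: np.ndarray      # (N,) most recent accepted G*_i
    posterior: PriorHyperparameters     # current hat-values
    sweep_index: int = 0
    accept_t: int = 0
    accept_omega: int = 0
    proposals_t: int = 0
    proposals_omega: int = 0


@dataclass
class InferenceResult:
    """Final states and diagnostics of all independent trials."""

    memberships: list = field(default_factory=list)     # per trial (A, N)
    activities: list = field(default_factory=list)      # per trial (M, A)
    log_prob_traces: list = field(default_factory=list)  # per trial (n_sweeps,)
    effective_counts: list = field(default_factory=list)
    acceptance_rates: list = field(default_factory=list)
    seeds: list = field(default_factory=list)
    config: MCMCConfig | None = None

    @property
    def n_trials(self) -> int:
        return len(self.memberships)

    def best_trial(self) -> int:
        """Index of the trial with highest final log joint probability."""
        return int(np.argmax([tr[-1] for tr in self.log_prob_traces]))


def _as_values(s):
    return s.values if isinstance(s, ActivityMatrix) else np.asarray(s, dtype=float)


def initialize_state(s, config: MCMCConfig, rng: np.random.Generator) -> SamplerState:
    """Draw the initial state: uniform simplex columns for t and uniform
    [0, 1] entries for omega (soft mode), or uniform one-hot columns and
    fair-coin binary entries (bim mode)."""
    s = _as_values(s)
    N, M = s.shape
    A = config.n_ensembles
    if config.mode == "soft":
        # Dirichlet(1, ..., 1) columns == uniform on the simplex
        t = rng.dirichlet(np.ones(A), size=N).T
        omega = rng.random((M, A))
    else:
        labels = rng.integers(A, size=N)
        t = np.zeros((A, N))
        t[labels, np.arange(N)] = 1.0
        omega = rng.integers(2, size=(M, A)).astype(float)
    last = np.argmax(t, axis=0)
    prior = config.make_prior()
    posterior = posterior_hyperparameters(prior, compute_sufficient_stats(t, omega, s))
    return SamplerState(t=t, omega=omega, last_concentration=last,
                        posterior=posterior)


# ---------------------------------------------------------------------------
# elementary proposal operations
# ---------------------------------------------------------------------------

def concentration_t_probabilities(t: np.ndarray, i: int) -> np.ndarray:
    """P(G*_i = mu) = sum_{j != i} t_mu_j / (N - 1) over ensembles."""
    N = t.shape[1]
    if N < 2:
        raise ValueError("concentration proposal requires N >= 2 neurons")
    return (t.sum(axis=1) - t[:, i]) / (N - 1)


def propose_concentration_t(t: np.ndarray, i: int, rng: np.random.Generator) -> int:
    """Draw the concentration ensemble for neuron i, size-proportionally."""
    p = concentration_t_probabilities(t, i)
    return int(rng.choice(p.shape[0], p=p / p.sum()))


def apply_weight_transition(t_i: np.ndarray, g_star: int, alpha_t: float) -> np.ndarray:
    """Push t_i toward ensemble g_star by alpha_t and renormalize."""
    out = np.asarray(t_i, dtype=float) / (1.0 + alpha_t)
    out[g_star] += alpha_t / (1.0 + alpha_t)
    return out


def weight_hastings_ratio(t: np.ndarray, i: int, g_star: int, g0: int) -> float:
    """Ratio of pre-update ensemble sizes (excluding neuron i), g0 over g*.

    A zero denominator (empty target ensemble) makes the forward proposal
    impossible; the move is rejected by returning ratio 0.
    """
    sizes = t.sum(axis=1) - t[:, i]
    denom = sizes[g_star]
    if denom <= 0:
        logger.warning("empty concentration ensemble %d for neuron %d; rejecting",
                       g_star, i)
        return 0.0
    return float(sizes[g0] / denom)


def concentration_omega_probability(omega: np.ndarray, k: int, mu: int) -> float:
    """P(G*_{k mu} = 1) = sum_{l != k} omega_l_mu / (M - 1)."""
    M = omega.shape[0]
    if M < 2:
        raise ValueError("concentration proposal requires M >= 2 time steps")
    return float((omega[:, mu].sum() - omega[k, mu]) / (M - 1))


def propose_concentration_omega(omega: np.ndarray, k: int, mu: int,
                                rng: np.random.Generator) -> int:
    return int(rng.random() < concentration_omega_probability(omega, k, mu))


def apply_omega_transition(omega_km: float, g_star: int, alpha_omega: float) -> float:
    if g_star == 1:
        return (omega_km + alpha_omega) / (1.0 + alpha_omega)
    return omega_km / (1.0 + alpha_omega)


def bim_weight_proposal(t: np.ndarray, i: int, alpha_new: float,
                        rng: np.random.Generator) -> int:
    """Categorical proposal of the hard baseline: move neuron i to ensemble
    mu with probability prop. to its size (excluding i), or to a new ensemble
    with weight alpha_new.  Returns a label in [0, A] where A means "new"."""
    N = t.shape[1]
    sizes = t.sum(axis=1) - t[:, i]
    probs = np.append(sizes, alpha_new) / (N - 1 + alpha_new)
    return int(rng.choice(probs.shape[0], p=probs / probs.sum()))


def effective_ensemble_count(t: np.ndarray, eps: float | None = None) -> int:
    """Number of ensembles carrying total membership weight above ``eps``
    (default 0.01 * N)."""
    t = np.asarray(t, dtype=float)
    if eps is None:
        eps = 0.01 * t.shape[1]
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    return int(np.count_nonzero(t.sum(axis=1) > eps))


# ---------------------------------------------------------------------------
# incremental log posterior ratios
# ---------------------------------------------------------------------------

def _omega_log_ratio_matrix(s, t, omega, prior, omega_star):
    """(M, A) matrix of log posterior ratios, entry (k, mu) for changing
    omega[k, mu] alone to omega_star[k, mu] (all against the same base state).

    Only the mu-th p-family and lambda-family beta factors of the joint
    depend on omega[k, mu]; their increments are linear in d = omega* - omega
    with neuron-weighted activity coefficients.
    """
    stats = compute_sufficient_stats(t, omega, s)
    an, ap, bp, a1, b1, a0, b0 = prior.as_tuple()
    tan, tap, tbp, ta1, tb1, ta0, tb0 = stats.as_tuple()
    d = omega_star - omega                                   # (M, A)
    C = (t @ s).T                                            # (M, A) sum_i t_mu_i s_ik
    D = tan[None, :] - C                                     # sum_i t_mu_i (1-s_ik)

    base = (log_beta(ap + tap, bp + tbp)
            + log_beta(a1 + ta1, b1 + tb1)
            + log_beta(a0 + ta0, b0 + tb0))                  # (A,)
    prop = (log_beta(ap + tap + d, bp + tbp - d)
            + log_beta(a1 + ta1 + d * C, b1 + tb1 + d * D)
            + log_beta(a0 + ta0 - d * C, b0 + tb0 - d * D))  # (M, A)
    return prop - base[None, :]


def omega_log_posterior_ratio(s, t, omega, prior, k, mu, omega_new) -> float:
    """Incremental log P ratio for omega[k, mu] -> omega_new."""
    s = _as_values(s)
    omega_star = omega.copy()
    omega_star[k, mu] = omega_new
    return float(_omega_log_ratio_matrix(s, t, omega, prior, omega_star)[k, mu])


def _weight_log_ratio_vector(s, t, omega, prior, t_star):
    """(N,) vector of log posterior ratios, entry i for replacing column i of
    t alone by t_star[:, i] (all against the same base state).

    The Dirichlet term and the lambda terms depend on t; the p terms cancel.
    """
    stats = compute_sufficient_stats(t, omega, s)
    an, ap, bp, a1, b1, a0, b0 = prior.as_tuple()
    tan, tap, tbp, ta1, tb1, ta0, tb0 = stats.as_tuple()

    delta = t_star - t                                       # (A, N)
    P1 = s @ omega                                           # (N, A) sum_k s_ik omega_k_mu
    s_sum = s.sum(axis=1)                                    # (N,)
    M = omega.shape[0]
    # per-(i, mu) increments of the four lambda statistics
    dT = delta.T                                             # (N, A)
    d_a1 = dT * P1
    d_b1 = dT * (tap[None, :] - P1)
    d_a0 = dT * (s_sum[:, None] - P1)
    d_b0 = dT * (M - tap[None, :] - s_sum[:, None] + P1)

    x = an + tan
    base = (gammaln(x).sum() - gammaln(x.sum())
            + log_beta(a1 + ta1, b1 + tb1).sum()
            + log_beta(a0 + ta0, b0 + tb0).sum())
    xs = x[None, :] + dT                                     # (N, A)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = (gammaln(xs).sum(axis=1) - gammaln(xs.sum(axis=1))
                + log_beta(a1[None, :] + ta1[None, :] + d_a1,
                           b1[None, :] + tb1[None, :] + d_b1).sum(axis=1)
                + log_beta(a0[None, :] + ta0[None, :] + d_a0,
                           b0[None, :] + tb0[None, :] + d_b0).sum(axis=1))
    return prop - base


def weight_log_posterior_ratio(s, t, omega, prior, i, t_i_new) -> float:
    """Incremental log P ratio for replacing column i of t by t_i_new."""
    s = _as_values(s)
    t_star = t.copy()
    t_star[:, i] = t_i_new
    return float(_weight_log_ratio_vector(s, t, omega, prior, t_star)[i])


def accept_weight(state: SamplerState, s, prior, i, t_i_new, g_star, g0,
                  rng: np.random.Generator) -> bool:
    """Metropolis–Hastings accept/reject for one membership-column proposal."""
    s = _as_values(s)
    log_post = weight_log_posterior_ratio(s, state.t, state.omega, prior, i, t_i_new)
    hastings = weight_hastings_ratio(state.t, i, g_star, g0)
    if hastings <= 0:
        return False
    log_a = log_post + np.log(hastings)
    if not np.isfinite(log_a):
        if log_a > 0:  # +inf: certain acceptance
            return True
        logger.warning("non-finite acceptance ratio for neuron %d; rejecting", i)
        return False
    return bool(np.log(rng.random()) < min(0.0, log_a))


def accept_omega(state: SamplerState, s, prior, k, mu, omega_new, g_star,
                 rng: np.random.Generator) -> bool:
    """Metropolis–Hastings accept/reject for one ensemble-activity proposal.

    The reverse concentration state is the binary complement of the proposed
    one; both proposal probabilities are evaluated on the pre-update omega.
    """
    s = _as_values(s)
    log_post = omega_log_posterior_ratio(s, state.t, state.omega, prior, k, mu,
                                         omega_new)
    q1 = concentration_omega_probability(state.omega, k, mu)
    q = {1: q1, 0: 1.0 - q1}
    if q[g_star] <= 0:
        return False  # unreachable when g_star was drawn from q
    log_a = log_post + np.log(max(q[1 - g_star], 0.0)) - np.log(q[g_star]) \
        if q[1 - g_star] > 0 else -np.inf
    if not np.isfinite(log_a):
        return False
    return bool(np.log(rng.random()) < min(0.0, log_a))


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

def _sweep_omega(state: SamplerState, s, prior, config, rng):
    """Synchronous omega phase: all proposals evaluated on the pre-sweep
    state, accepted updates applied at once."""
    omega = state.omega
    M, A = omega.shape
    if config.mode == "soft":
        q1 = (omega.sum(axis=0)[None, :] - omega) / (M - 1)   # P(G*=1), (M, A)
        g_star = rng.random((M, A)) < q1
        omega_star = np.where(
            g_star,
            (omega + config.alpha_omega) / (1.0 + config.alpha_omega),
            omega / (1.0 + config.alpha_omega),
        )
        q_fwd = np.where(g_star, q1, 1.0 - q1)
        q_rev = np.where(g_star, 1.0 - q1, q1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_hastings = np.log(q_rev) - np.log(q_fwd)
    else:
        omega_star = 1.0 - omega                              # deterministic inversion
        log_hastings = np.zeros((M, A))
    log_post = _omega_log_ratio_matrix(s, state.t, omega, prior, omega_star)
    log_a = log_post + log_hastings
    accept = np.log(rng.random((M, A))) < np.minimum(0.0, log_a)
    accept &= np.isfinite(log_a)
    state.omega = np.where(accept, omega_star, omega)
    state.accept_omega += int(accept.sum())
    state.proposals_omega += M * A


def _draw_categorical_columns(probs, rng):
    """Vectorized categorical draw: probs is (A, N), columns sum to 1."""
    c = np.cumsum(probs, axis=0)
    u = rng.random(probs.shape[1]) * c[-1]
    return (u[None, :] < c).argmax(axis=0)


def _sweep_t(state: SamplerState, s, prior, config, rng):
    """Synchronous membership phase."""
    t = state.t
    A, N = t.shape
    sizes_excl = t.sum(axis=1)[:, None] - t                   # (A, N)
    if config.mode == "soft":
        g_star = _draw_categorical_columns(sizes_excl, rng)
        t_star = t / (1.0 + config.alpha_t)
        t_star[g_star, np.arange(N)] += config.alpha_t / (1.0 + config.alpha_t)
        g0 = state.last_concentration
        num = sizes_excl[g0, np.arange(N)]
        den = sizes_excl[g_star, np.arange(N)]
    else:
        ext = np.vstack([sizes_excl, np.full((1, N), config.alpha_new)])
        g_star = _draw_categorical_columns(ext, rng)
        cur = t.argmax(axis=0)
        # "new ensemble" -> first empty slot; reject if none is free
        occupied = t.sum(axis=1) > 0
        free = np.flatnonzero(~occupied)
        resolved = g_star.copy()
        new_mask = g_star == A
        if new_mask.any():
            resolved[new_mask] = free[0] if free.size else cur[new_mask]
        g_star = resolved
        t_star = np.zeros_like(t)
        t_star[g_star, np.arange(N)] = 1.0
        denom_ext = N - 1 + config.alpha_new
        num = sizes_excl[cur, np.arange(N)] / denom_ext
        den = np.where(new_mask & (free.size > 0),
                       config.alpha_new,
                       sizes_excl[g_star, np.arange(N)]) / denom_ext
        if new_mask.any() and free.size == 0:
            den = np.where(new_mask, np.inf, den)  # force rejection
        g0 = cur
    log_post = _weight_log_ratio_vector(s, t, state.omega, prior, t_star)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_hastings = np.log(num) - np.log(den)
    log_a = log_post + log_hastings
    accept = np.log(rng.random(N)) < np.minimum(0.0, log_a)
    accept &= np.isfinite(log_a) | (log_a == np.inf)
    t_new = t.copy()
    t_new[:, accept] = t_star[:, accept]
    state.t = t_new
    state.last_concentration = np.where(accept, g_star, g0)
    state.accept_t += int(accept.sum())
    state.proposals_t += N


def sweep(state: SamplerState, s, config: MCMCConfig,
          rng: np.random.Generator) -> SamplerState:
    """One full sweep: omega phase, t phase, hyperparameter refresh.

    The posterior hat-values are recomputed each sweep from the fixed prior
    template plus the current statistics; acceptance ratios always use the
    prior template, matching the additive structure of the marginalized
    joint.
    """
    s = _as_values(s)
    prior = config.make_prior()
    _sweep_omega(state, s, prior, config, rng)
    _sweep_t(state, s, prior, config, rng)
    state.posterior = posterior_hyperparameters(
        prior, compute_sufficient_stats(state.t, state.omega, s))
    state.sweep_index += 1
    return state


def run_inference(s, config: MCMCConfig) -> InferenceResult:
    """Run ``n_trials`` independent chains of ``n_sweeps`` sweeps each.

    Trial r is seeded with ``config.seed + r`` so trials are independent and
    the whole run is reproducible from the base seed.
    """
    s_arr = _as_values(s)
    prior = config.make_prior()
    result = InferenceResult(config=config)
    for r in range(config.n_trials):
        trial_seed = config.seed + r
        rng = np.random.default_rng(trial_seed)
        state = initialize_state(s_arr, config, rng)
        trace = np.empty(config.n_sweeps)
        for _ in range(config.n_sweeps):
            sweep(state, s_arr, config, rng)
            trace[state.sweep_index - 1] = log_marginal_joint(
                compute_sufficient_stats(state.t, state.omega, s_arr), prior)
        result.memberships.append(state.t)
        result.activities.append(state.omega)
        result.log_prob_traces.append(trace)
        result.effective_counts.append(effective_ensemble_count(state.t))
        result.acceptance_rates.append({
            "t": state.accept_t / max(state.proposals_t, 1),
            "omega": state.accept_omega / max(state.proposals_omega, 1),
        })
        result.seeds.append(trial_seed)
        logger.info("trial %d/%d done: logP=%.2f, %d effective ensembles",
                    r + 1, config.n_trials, trace[-1],
                    result.effective_counts[-1])
    return result
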