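"""Marginalized generative model for functional neuronal ensembles.

The model explains a neuron-by-time activity matrix ``s`` (entries in [0, 1])
through two latent objects: membership weights ``t`` (ensembles x neurons,
each column on the probability simplex) and ensemble activities ``omega``
(time x ensembles, entries in [0, 1]).  Per-ensemble parameters — a Dirichlet
affinity vector ``n``, a beta activity rate ``p`` and beta synchronization
rates ``lambda_1`` / ``lambda_0`` — are integrated out analytically against
conjugate priors, leaving a joint log-probability that depends on the data
only through seven families of sufficient statistics.  All beta/Dirichlet
normalizers are evaluated through log-gamma; the statistics reach O(N*M) and
direct gamma would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ActivityMatrix",
    "PriorHyperparameters",
    "SufficientStatistics",
    "compute_sufficient_stats",
    "log_multivariate_beta",
    "log_beta",
    "log_marginal_joint",
    "posterior_hyperparameters",
]

_FAMILIES = (
    "alpha_n",
    "alpha_p",
    "beta_p",
    "alpha_lam1",
    "beta_lam1",
    "alpha_lam0",
    "beta_lam0",
)


class ActivityMatrix:
    """Neuron-by-time activity, continuous in [0, 1] or strictly binary.

    Parameters
    ----------
    values : array-like of shape (n_neurons, n_timesteps)
        Activity of neuron ``i`` at time step ``k``.
    mode : {"continuous", "binary"}
        ``"binary"`` additionally requires every entry to be exactly 0 or 1
        (the regime of the hard-clustering baseline, BIM).
    """

    def __init__(self, values, mode: str = "continuous"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(
                f"activity must be 2-D (neurons x time), got ndim={values.ndim}"
            )
        if mode not in ("continuous", "binary"):
            raise ValueError(f"unknown mode {mode!r}")
        if not np.all(np.isfinite(values)):
            raise ValueError("activity contains non-finite entries")
        lo, hi = values.min(initial=0.0), values.max(initial=0.0)
        if lo < -1e-9 or hi > 1 + 1e-9:
            bad = np.argwhere((values < -1e-9) | (values > 1 + 1e-9))[0]
            raise ValueError(
                f"activity out of [0, 1] at row {bad[0]}, column {bad[1]}"
            )
        if mode == "binary" and not np.all((values == 0) | (values == 1)):
            bad = np.argwhere((values != 0) & (values != 1))[0]
            raise ValueError(
                f"binary mode requires 0/1 entries; offending entry at "
                f"row {bad[0]}, column {bad[1]}"
            )
        self.values = np.clip(values, 0.0, 1.0)
        self.mode = mode

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]

    def __repr__(self):  # pragma: no cover
        return (
            f"ActivityMatrix(n_neurons={self.n_neurons}, "
            f"n_timesteps={self.n_timesteps}, mode={self.mode!r})"
        )


@dataclass
class PriorHyperparameters:
    """The seven hyperparameter families of the conjugate priors.

    ``alpha_n`` parameterizes the Dirichlet prior on ensemble affinity;
    ``(alpha_p, beta_p)`` the beta prior on ensemble activity;
    ``(alpha_lam1, beta_lam1)`` the beta prior on neuron activity while the
    ensemble is active, and ``(alpha_lam0, beta_lam0)`` while it is inactive.
    Each is a length-A vector of strictly positive reals.
    """

    alpha_n: np.ndarray
    alpha_p: np.ndarray
    beta_p: np.ndarray
    alpha_lam1: np.ndarray
    beta_lam1: np.ndarray
    alpha_lam0: np.ndarray
    beta_lam0: np.ndarray

    def __post_init__(self):
        arrays = [np.asarray(getattr(self, f.name), dtype=float) for f in fields(self)]
        n = arrays[0].shape
        for f, a in zip(fields(self), arrays):
            if a.ndim != 1 or a.shape != n:
                raise ValueError(f"{f.name} must be a length-A vector")
            if np.any(a <= 0):
                raise ValueError(f"{f.name} must be strictly positive")
            setattr(self, f.name, a)

    @classmethod
    def uniform(cls, n_ensembles: int, value: float = 1.0) -> "PriorHyperparameters":
        """Flat priors: symmetric Dirichlet and uniform betas (default 1)."""
        v = np.full(n_ensembles, float(value))
        return cls(*(v.copy() for _ in _FAMILIES))

    @property
    def n_ensembles(self) -> int:
        return self.alpha_n.shape[0]

    def as_tuple(self):
        return tuple(getattr(self, name) for name in _FAMILIES)


@dataclass
class SufficientStatistics:
    """Tilde-valued statistics of (t, omega, s), one value per ensemble.

    ``alpha_n[mu]`` is the total membership weight of ensemble ``mu``;
    ``alpha_p`` / ``beta_p`` the accumulated activity / inactivity of the
    ensemble over time; the four lambda families weigh neuron activity by
    membership and by ensemble (in)activity.  For one-hot ``t`` and binary
    ``omega``, ``s`` they reduce to the integer co-occurrence counts of the
    hard-clustering baseline.
    """

    alpha_n: np.ndarray
    alpha_p: np.ndarray
    beta_p: np.ndarray
    alpha_lam1: np.ndarray
    beta_lam1: np.ndarray
    alpha_lam0: np.ndarray
    beta_lam0: np.ndarray

    @property
    def n_ensembles(self) -> int:
        return self.alpha_n.shape[0]

    def as_tuple(self):
        return tuple(getattr(self, name) for name in _FAMILIES)


def _check_dims(t: np.ndarray, omega: np.ndarray, s: np.ndarray) -> None:
    A, N = t.shape
    M, A2 = omega.shape
    N2, M2 = s.shape
    if A != A2:
        raise ValueError(
            f"ensemble axis mismatch: t has A={A}, omega has A={A2}"
        )
    if N != N2:
        raise ValueError(f"neuron axis mismatch: t has N={N}, s has N={N2}")
    if M != M2:
        raise ValueError(f"time axis mismatch: omega has M={M}, s has M={M2}")


def compute_sufficient_stats(t, omega, s) -> SufficientStatistics:
    """Evaluate the seven tilde statistics of the marginalized likelihood.

    Parameters
    ----------
    t : ndarray of shape (A, N)
        Membership weights, columns on the simplex.
    omega : ndarray of shape (M, A)
        Ensemble activity in [0, 1].
    s : ndarray of shape (N, M)
        Neuronal activity in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    omega = np.asarray(omega, dtype=float)
    s = np.asarray(s, dtype=float)
    _check_dims(t, omega, s)
    M = omega.shape[0]

    alpha_n = t.sum(axis=1)                       # sum_i t_mu_i
    alpha_p = omega.sum(axis=0)                   # sum_k omega_k_mu
    beta_p = M - alpha_p

    ts = t @ s                                    # (A, M): sum_i t_mu_i s_ik
    t1s = alpha_n[:, None] - ts                   # sum_i t_mu_i (1 - s_ik)
    alpha_lam1 = np.einsum("am,ma->a", ts, omega)
    beta_lam1 = np.einsum("am,ma->a", t1s, omega)
    alpha_lam0 = ts.sum(axis=1) - alpha_lam1
    beta_lam0 = t1s.sum(axis=1) - beta_lam1
    return SufficientStatistics(
        alpha_n, alpha_p, beta_p,
        alpha_lam1, beta_lam1,
        np.maximum(alpha_lam0, 0.0), np.maximum(beta_lam0, 0.0),
    )


def log_multivariate_beta(x) -> float:
    """log B(x_1, ..., x_A) = sum_mu log Gamma(x_mu) - log Gamma(sum_mu x_mu).

    For a length-2 vector this is the ordinary log beta function; for a
    length-1 vector it equals 0 (B(x) = Gamma(x)/Gamma(x) = 1).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("multivariate beta requires strictly positive arguments")
    return float(gammaln(x).sum() - gammaln(x.sum()))


def log_beta(a, b):
    """Elementwise log B(a, b) through log-gamma (vectorized)."""
    return gammaln(a) + gammaln(b) - gammaln(a + b)


def log_marginal_joint(stats: SufficientStatistics,
                       prior: PriorHyperparameters) -> float:
    """Log joint probability of (t, omega, s), parameters integrated out.

    Up to an additive constant independent of (t, omega): the log multivariate
    beta of ``alpha_n + tilde(alpha_n)`` plus, per ensemble, log beta terms
    for the p, lambda_1 and lambda_0 families.  Only differences of this
    quantity are ever exponentiated (Metropolis–Hastings ratios), so the
    constant never matters.
    """
    if stats.n_ensembles != prior.n_ensembles:
        raise ValueError(
            f"length mismatch: stats has A={stats.n_ensembles}, "
            f"prior has A={prior.n_ensembles}"
        )
    an, ap, bp, a1, b1, a0, b0 = prior.as_tuple()
    tan, tap, tbp, ta1, tb1, ta0, tb0 = stats.as_tuple()
    out = log_multivariate_beta(an + tan)
    out += log_beta(ap + tap, bp + tbp).sum()
    out += log_beta(a1 + ta1, b1 + tb1).sum()
    out += log_beta(a0 + ta0, b0 + tb0).sum()
    if not np.isfinite(out):
        raise ValueError("non-finite log joint probability")
    return float(out)


def posterior_hyperparameters(prior: PriorHyperparameters,
                              stats: SufficientStatistics) -> PriorHyperparameters:
    """Conjugate update: hat = prior + tilde, elementwise for all families."""
    if stats.n_ensembles != prior.n_ensembles:
        raise ValueError(
            f"length mismatch: stats has A={stats.n_ensembles}, "
            f"prior has A={prior.n_ensembles}"
        )
    return PriorHyperparameters(
        *(p + t for p, t in zip(prior.as_tuple(), stats.as_tuple()))
    )
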