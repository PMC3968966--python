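"""Kullback-Leibler dissimilarities between per-trajectory HMMs.

The pairwise dissimilarity between two fitted models is the symmetrized KL
divergence between the probability densities they place on trajectory space.
The trajectory-space integral is intractable, so three estimators are
provided:

``empirical``
    Each model's likelihood column over the *observed* trajectory set is
    normalized (log-sum-exp normalizer ``Z``) into a discrete distribution
    ``P~_lambda`` over the N observed trajectories; the divergence is the
    ordinary discrete KL between those distributions.  This is the default:
    it uses all the data while only requiring the N x N likelihood matrix.
``one_point``
    The classical single-point approximation built from the four
    self/cross likelihoods of the pair.
``monte_carlo``
    Sample-average of the log-likelihood ratio over trajectories drawn from
    the first model (with covariate paths resampled from the observed data,
    since covariates are exogenous).

All arithmetic is in log space; values are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .hmm import HMMParameters, forward_log_likelihood, sample_trajectory
from .schema import Trajectory

__all__ = [
    "LikelihoodMatrix",
    "DistanceMatrix",
    "MonteCarloKL",
    "likelihood_matrix",
    "empirical_kl",
    "one_point_kl",
    "monte_carlo_kl",
    "symmetrized_distance_matrix",
    "monte_carlo_distance_matrix",
    "effective_sample_sizes",
]


@dataclass(frozen=True)
class LikelihoodMatrix:
    """``loglik[i, j] = log P(T_i | lambda_j)`` in fixed dataset order."""

    loglik: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        ll = np.asarray(self.loglik, dtype=float)
        object.__setattr__(self, "loglik", ll)
        if ll.ndim != 2 or ll.shape[0] != ll.shape[1]:
            raise ValueError("log-likelihood matrix must be square")
        if len(self.subject_ids) != ll.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if not np.isfinite(ll).all():
            raise ValueError("log-likelihood matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.loglik.shape[0]

    def normalized_log_columns(self) -> np.ndarray:
        """Columns turned into log discrete distributions over the N
        observed trajectories (log P~)."""
        return self.loglik - logsumexp(self.loglik, axis=0, keepdims=True)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric, zero-diagonal matrix of pairwise model dissimilarities."""

    values: np.ndarray
    method: str
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        D = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", D)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MonteCarloKL:
    estimate: float
    std_error: float
    n_draws: int


def likelihood_matrix(
    models: list[HMMParameters], trajectories: list[Trajectory]
) -> LikelihoodMatrix:
    """Evaluate every trajectory under every fitted model (N^2 forward passes)."""
    if len(models) != len(trajectories):
        raise ValueError(
            f"{len(models)} models but {len(trajectories)} trajectories"
        )
    N = len(models)
    ll = np.empty((N, N))
    for j, model in enumerate(models):
        for i, traj in enumerate(trajectories):
            ll[i, j] = forward_log_likelihood(model, traj)
    return LikelihoodMatrix(
        loglik=ll, subject_ids=tuple(t.subject_id for t in trajectories)
    )


def empirical_kl(loglik: LikelihoodMatrix, a: int, b: int) -> float:
    """Directed KL between the normalized likelihood columns of models a and b."""
    N = loglik.n
    if not (0 <= a < N and 0 <= b < N):
        raise IndexError("model index out of range")
    if N == 1:
        return 0.0
    la = loglik.loglik[:, a] - logsumexp(loglik.loglik[:, a])
    lb = loglik.loglik[:, b] - logsumexp(loglik.loglik[:, b])
    return float(np.sum(np.exp(la) * (la - lb)))


def one_point_kl(loglik: LikelihoodMatrix, a: int, b: int) -> float:
    """Symmetrized single-point KL approximation from the four pair entries.

    May be negative for pathological fits; reported as-is.
    """
    ll = loglik.loglik
    return 0.5 * ((ll[a, a] - ll[a, b]) + (ll[b, b] - ll[b, a]))


def symmetrized_distance_matrix(
    loglik: LikelihoodMatrix, method: str = "empirical"
) -> DistanceMatrix:
    """``D[i, j] = (KL(i; j) + KL(j; i)) / 2`` for the chosen estimator."""
    N = loglik.n
    if method == "empirical":
        Lc = loglik.normalized_log_columns()  # (N, N), column = log P~
        P = np.exp(Lc)
        self_terms = np.sum(P * Lc, axis=0)  # (N,)
        KL = self_terms[:, None] - P.T @ Lc  # KL[a, b]
        D = 0.5 * (KL + KL.T)
        # exact non-negativity can be lost to rounding only at ~1e-15 scale
        D = np.maximum(D, 0.0)
    elif method == "one_point":
        ll = loglik.loglik
        diag = np.diag(ll)
        KL = diag[:, None] - ll.T  # KL[a, b] = ll[a,a] - ll[a,b]
        D = 0.5 * (KL + KL.T)
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(values=D, method=method, subject_ids=loglik.subject_ids)


def monte_carlo_kl(
    model_a: HMMParameters,
    model_b: HMMParameters,
    covariate_source: list[np.ndarray],
    n: int = 2000,
    seed: int = 0,
) -> MonteCarloKL:
    """Monte-Carlo estimate of the directed KL from model a to model b.

    Trajectories are sampled from ``model_a``; because covariates are
    exogenous conditioning inputs, each draw reuses a covariate path sampled
    uniformly from ``covariate_source`` (typically the observed dataset's
    covariate paths).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not covariate_source:
        raise ValueError("covariate_source must not be empty")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n)
    for i in range(n):
        cov = covariate_source[int(rng.integers(len(covariate_source)))]
        traj = sample_trajectory(model_a, cov, seed=rng)
        ratios[i] = forward_log_likelihood(model_a, traj) - forward_log_likelihood(
            model_b, traj
        )
    se = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return MonteCarloKL(estimate=float(ratios.mean()), std_error=se, n_draws=n)


def monte_carlo_distance_matrix(
    models: list[HMMParameters],
    trajectories: list[Trajectory],
    n: int = 500,
    seed: int = 0,
) -> DistanceMatrix:
    """Symmetrized Monte-Carlo KL distance matrix (expensive; mostly for
    comparisons against the empirical estimator)."""
    N = len(models)
    cov_source = [t.covariates for t in trajectories]
    ss = np.random.SeedSequence(seed)
    D = np.zeros((N, N))
    for a in range(N):
        for b in range(a + 1, N):
            s1, s2 = ss.spawn(2)
            kab = monte_carlo_kl(models[a], models[b], cov_source, n,
                                 seed=np.random.default_rng(s1))
            kba = monte_carlo_kl(models[b], models[a], cov_source, n,
                                 seed=np.random.default_rng(s2))
            D[a, b] = D[b, a] = 0.5 * (kab.estimate + kba.estimate)
    return DistanceMatrix(
        values=D, method="monte_carlo",
        subject_ids=tuple(t.subject_id for t in trajectories),
    )


def effective_sample_sizes(loglik: LikelihoodMatrix) -> np.ndarray:
    """Diagnostic: effective sample size ``1 / sum_i P~(T_i)^2`` per column.

    Short trajectories carry larger likelihoods and can dominate the
    empirical distributions; a column ESS near 1 warns that one trajectory
    dominates that model's discrete distribution.
    """
    P = np.exp(loglik.normalized_log_columns())
    return 1.0 / np.sum(P**2, axis=0)
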