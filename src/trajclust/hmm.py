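"""Covariate-aware hidden Markov models with multinomial emissions.

Each trajectory is embedded in its own HMM: a finite hidden-state chain whose
transition probabilities (and optionally emission probabilities) follow
multinomial-logit links in dummy-encoded categorical covariates.  Observation
channels are contemporaneously conditionally independent given the hidden
state, each with a per-state multinomial distribution.

All likelihood arithmetic is carried out in log space with log-sum-exp; no
probability-space scaling variant exists.  Parameters are estimated by
maximum likelihood via EM (Baum-Welch) with multiple seeded restarts; with
covariates enabled the M-step performs a posterior-weighted multinomial-logit
maximization by damped Newton ascent, accepted only when it does not decrease
the expected complete-data log-likelihood (a generalized EM step, so the
likelihood trace is monotone).

Conventions
-----------
* Softmax identifiability: in every logit row the reference cell (hidden
  state 0 for transitions, category 0 for emissions and the initial
  distribution) is pinned to zero.
* The transition *into* time ``t`` is conditioned on the covariate row at
  time ``t`` (the destination time).  The sampler uses the same convention.
* The abstract time step carries no units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import log_softmax, logsumexp, softmax

from .schema import DatasetSchema, Trajectory, TrajectoryError

__all__ = [
    "HMMParameters",
    "EMConfig",
    "FitResult",
    "OverfitError",
    "transition_matrix_at",
    "emission_log_prob_at",
    "forward_log_likelihood",
    "forward_backward_posteriors",
    "fit_em",
    "sample_trajectory",
    "n_free_parameters",
]


class OverfitError(ValueError):
    """Requested state count implies more parameters than the guard allows."""


# =====================================================================
# parameter container
# =====================================================================


@dataclass
class HMMParameters:
    """Parameters of one covariate-aware HMM.

    Attributes
    ----------
    schema
        The dataset schema the model is defined over.
    n_states
        Number of hidden states ``S``.
    initial_logits
        Length-``S`` vector; softmax gives the initial state distribution.
        Element 0 is the reference (zero).
    transition_weights
        ``(S, S, 1+p)`` multinomial-logit weights: origin state, destination
        state, regressor (intercept + p dummy covariates).  Destination 0 is
        the reference (all-zero slice).
    emission_weights
        One ``(S, C_k, 1+p)`` tensor per observation channel; category 0 is
        the reference.
    """

    schema: DatasetSchema
    n_states: int
    initial_logits: np.ndarray
    transition_weights: np.ndarray
    emission_weights: tuple[np.ndarray, ...]
    use_covariates_in_transitions: bool = True
    use_covariates_in_emissions: bool = False

    def __post_init__(self):
        S, P = self.n_states, self.schema.design_dim
        self.initial_logits = np.asarray(self.initial_logits, dtype=float).reshape(S)
        self.transition_weights = np.asarray(
            self.transition_weights, dtype=float
        ).reshape(S, S, P)
        ew = []
        for k, card in enumerate(self.schema.observation_cardinalities):
            ew.append(np.asarray(self.emission_weights[k], dtype=float).reshape(S, card, P))
        self.emission_weights = tuple(ew)

    def initial_distribution(self) -> np.ndarray:
        return softmax(self.initial_logits)

    def copy(self) -> "HMMParameters":
        return replace(
            self,
            initial_logits=self.initial_logits.copy(),
            transition_weights=self.transition_weights.copy(),
            emission_weights=tuple(w.copy() for w in self.emission_weights),
        )


def uniform_parameters(
    schema: DatasetSchema,
    n_states: int,
    use_covariates_in_transitions: bool = True,
    use_covariates_in_emissions: bool = False,
) -> HMMParameters:
    """All-zero-logit (uniform) parameters — a convenient starting point."""
    P = schema.design_dim
    return HMMParameters(
        schema=schema,
        n_states=n_states,
        initial_logits=np.zeros(n_states),
        transition_weights=np.zeros((n_states, n_states, P)),
        emission_weights=tuple(
            np.zeros((n_states, c, P)) for c in schema.observation_cardinalities
        ),
        use_covariates_in_transitions=use_covariates_in_transitions,
        use_covariates_in_emissions=use_covariates_in_emissions,
    )


def n_free_parameters(
    schema: DatasetSchema,
    n_states: int,
    use_covariates_in_transitions: bool = True,
    use_covariates_in_emissions: bool = False,
) -> int:
    """Count of free (non-reference) parameters of the model."""
    S = n_states
    p = schema.design_dim - 1
    n = S - 1
    if S > 1:
        n += S * (S - 1) * (1 + (p if use_covariates_in_transitions else 0))
    for c in schema.observation_cardinalities:
        n += S * (c - 1) * (1 + (p if use_covariates_in_emissions else 0))
    return n


# =====================================================================
# pointwise probability queries
# =====================================================================


def transition_matrix_at(params: HMMParameters, covariate_row: np.ndarray) -> np.ndarray:
    """Row-stochastic ``S x S`` transition matrix at one encoded covariate row.

    ``covariate_row`` is the dummy-encoded regressor vector (intercept first)
    as produced by :meth:`DatasetSchema.encode_covariate_row`.
    """
    x = np.asarray(covariate_row, dtype=float).ravel()
    if x.shape[0] != params.schema.design_dim:
        raise ValueError(
            f"covariate_row has length {x.shape[0]}, model expects "
            f"{params.schema.design_dim}"
        )
    logits = params.transition_weights @ x  # (S, S)
    return softmax(logits, axis=1)


def emission_log_prob_at(
    params: HMMParameters,
    state: int,
    covariate_row: np.ndarray,
    observation_row: np.ndarray,
) -> float:
    """Log emission probability of one observation row given a hidden state.

    Channels are conditionally independent given the state, so the result is
    the sum of per-channel log multinomial probabilities.
    """
    x = np.asarray(covariate_row, dtype=float).ravel()
    if x.shape[0] != params.schema.design_dim:
        raise ValueError("covariate_row dimension mismatch")
    obs = np.asarray(observation_row, dtype=np.int64).ravel()
    if obs.shape[0] != params.schema.n_observation_channels:
        raise TrajectoryError("observation_row has wrong number of channels")
    total = 0.0
    for k, card in enumerate(params.schema.observation_cardinalities):
        if not 0 <= obs[k] < card:
            raise TrajectoryError(
                f"category index {obs[k]} out of range for channel "
                f"{params.schema.observation_names[k]!r}"
            )
        logits = params.emission_weights[k][state] @ x  # (C_k,)
        total += float(log_softmax(logits)[obs[k]])
    return total


# =====================================================================
# log-space machinery shared by likelihood evaluation and EM
# =====================================================================


def _design(params: HMMParameters, traj: Trajectory) -> np.ndarray:
    traj.validate(params.schema)
    return params.schema.encode_covariates(traj.covariates)  # (L, 1+p)


def _log_transition_tensor(params: HMMParameters, X: np.ndarray) -> np.ndarray:
    """``(L, S, S)`` log transition matrices; entry ``[t]`` governs the move
    into time ``t`` (entry ``[0]`` is unused)."""
    if params.use_covariates_in_transitions:
        logits = np.einsum("sdp,lp->lsd", params.transition_weights, X)
    else:
        logits = np.broadcast_to(
            params.transition_weights[:, :, 0], (X.shape[0],) + (params.n_states,) * 2
        )
    return log_softmax(logits, axis=2)


def _log_emission_matrix(
    params: HMMParameters, X: np.ndarray, observations: np.ndarray
) -> np.ndarray:
    """``(L, S)`` log probability of the observed row at each time and state."""
    L = X.shape[0]
    B = np.zeros((L, params.n_states))
    for k in range(params.schema.n_observation_channels):
        if params.use_covariates_in_emissions:
            logits = np.einsum("scp,lp->lsc", params.emission_weights[k], X)
        else:
            logits = np.broadcast_to(
                params.emission_weights[k][:, :, 0], (L,) + params.emission_weights[k].shape[:2]
            )
        lp = log_softmax(logits, axis=2)  # (L, S, C_k)
        B += lp[np.arange(L), :, observations[:, k]]
    return B


def _forward_backward(log_pi, logA, logB):
    """Log-space forward/backward passes.

    Returns ``(log_alpha, log_beta, log_likelihood)`` with
    ``alpha[t, s] = log P(y_0..y_t, z_t = s)``.
    """
    L, S = logB.shape
    log_alpha = np.empty((L, S))
    log_alpha[0] = log_pi + logB[0]
    # inline log-sum-exp (max-subtract) keeps the sequential loops cheap
    for t in range(1, L):
        prev = log_alpha[t - 1]
        m = prev.max()
        with np.errstate(divide="ignore"):
            log_alpha[t] = m + np.log(np.exp(prev - m) @ np.exp(logA[t])) + logB[t]
    last = log_alpha[-1]
    m = last.max()
    ll = float(m + np.log(np.exp(last - m).sum()))
    log_beta = np.zeros((L, S))
    for t in range(L - 2, -1, -1):
        nxt = logB[t + 1] + log_beta[t + 1]
        m = nxt.max()
        with np.errstate(divide="ignore"):
            log_beta[t] = m + np.log(np.exp(logA[t + 1]) @ np.exp(nxt - m))
    return log_alpha, log_beta, ll


def forward_log_likelihood(params: HMMParameters, traj: Trajectory) -> float:
    """``log P(T | lambda)`` by the forward algorithm (log-sum-exp scaled)."""
    X = _design(params, traj)
    logB = _log_emission_matrix(params, X, traj.observations)
    log_pi = log_softmax(params.initial_logits)
    if params.n_states == 1:
        return float(logB.sum())
    logA = _log_transition_tensor(params, X)
    _, _, ll = _forward_backward(log_pi, logA, logB)
    return ll


def forward_backward_posteriors(params: HMMParameters, traj: Trajectory):
    """Per-time state posteriors ``gamma`` and pairwise posteriors ``xi``.

    Returns ``(gamma, xi)`` where ``gamma`` is ``(L, S)`` and ``xi`` is
    ``(L-1, S, S)`` with ``xi[t, i, j] = P(z_t = i, z_{t+1} = j | T)``.
    """
    X = _design(params, traj)
    logB = _log_emission_matrix(params, X, traj.observations)
    log_pi = log_softmax(params.initial_logits)
    L, S = logB.shape
    if S == 1:
        return np.ones((L, 1)), np.ones((max(L - 1, 0), 1, 1))
    logA = _log_transition_tensor(params, X)
    log_alpha, log_beta, ll = _forward_backward(log_pi, logA, logB)
    gamma = np.exp(log_alpha + log_beta - ll)
    xi = np.exp(
        log_alpha[:-1, :, None]
        + logA[1:]
        + (logB[1:] + log_beta[1:])[:, None, :]
        - ll
    )
    return gamma, xi


# =====================================================================
# EM fitting
# =====================================================================


@dataclass
class EMConfig:
    """Fitting options for :func:`fit_em`.

    ``tol`` is the relative log-likelihood improvement below which EM stops;
    ``overfit_guard`` bounds the free-parameter count at
    ``overfit_guard * L * d`` (d = number of observation channels).
    """

    n_restarts: int = 5
    tol: float = 1e-6
    max_iter: int = 200
    init_jitter: float = 0.3
    newton_steps: int = 2
    prob_floor: float = 1e-2
    covariate_ridge: float = 1.0
    overfit_guard: float = 5.0
    use_covariates_in_transitions: bool = True
    use_covariates_in_emissions: bool = False


@dataclass
class FitResult:
    params: HMMParameters
    log_likelihood_trace: np.ndarray
    converged: bool
    n_restarts_used: int
    seed: int

    @property
    def log_likelihood(self) -> float:
        return float(self.log_likelihood_trace[-1])


def _floored_simplex_mle(w: np.ndarray, floor: float) -> np.ndarray:
    """Exact maximizer of ``sum_c w_c log p_c`` over the floor-truncated
    simplex ``{p : p_c >= floor, sum p = 1}`` (water-filling KKT solution).

    Using the exact constrained maximizer (rather than floor-and-renormalize)
    preserves the EM ascent guarantee when the floor binds.
    """
    w = np.asarray(w, dtype=float)
    C = w.shape[-1]
    if floor * C >= 1.0:
        raise ValueError("floor too large for the number of categories")
    total = w.sum()
    if total <= 0:
        return np.full(C, 1.0 / C)
    p = w / total
    clamped = np.zeros(C, dtype=bool)
    for _ in range(C):
        below = p < floor
        new_clamped = clamped | below
        if new_clamped.all():
            return np.full(C, 1.0 / C)
        if (new_clamped == clamped).all():
            break
        clamped = new_clamped
        free_mass = 1.0 - floor * clamped.sum()
        w_free = np.where(clamped, 0.0, w)
        p = np.where(clamped, floor, w_free / w_free.sum() * free_mass)
    return p


def _floored_log_ratio(p: np.ndarray, floor: float) -> np.ndarray:
    """Constrained-MLE probabilities along the last axis, returned as
    reference-pinned logits ``log p_c - log p_0``."""
    p = np.asarray(p, dtype=float)
    out = np.apply_along_axis(_floored_simplex_mle, -1, p, floor)
    lp = np.log(out)
    return lp - lp[..., :1]


def _weighted_mnlogit_objective(V: np.ndarray, X: np.ndarray, W: np.ndarray) -> float:
    # V: (C-1, P) free logit rows (category 0 is the reference)
    logits = np.concatenate([np.zeros((X.shape[0], 1)), X @ V.T], axis=1)
    return float(np.sum(W * log_softmax(logits, axis=1)))


def _weighted_mnlogit_newton(
    X: np.ndarray,
    W: np.ndarray,
    V: np.ndarray,
    steps: int,
    smooth: float = 0.0,
    ridge: float = 0.0,
) -> np.ndarray:
    """A few damped-Newton ascent steps on the posterior-weighted multinomial
    logit log-likelihood.  Concave objective; a step is accepted only if it
    does not decrease the objective, so the caller's EM stays monotone.

    ``smooth`` adds a uniform pseudo-weight per (time, category) cell — the
    multinomial-logit analogue of the probability floor used by the
    closed-form M-steps.  It keeps every category supported at every design
    row, so the optimum stays finite even for separable single-trajectory
    posteriors.  ``ridge`` is an L2 penalty on the covariate (non-intercept)
    columns only: with a handful of transitions per subject, unpenalized
    covariate coefficients are barely estimable, and regularization is the
    standard control for that overfitting.

    Acceptance gates on the raw (unsmoothed, unpenalized) objective never
    decreasing, which preserves the EM likelihood-ascent property; smoothing
    and ridge shape the search direction and stopping point.
    """
    T, P = X.shape
    C = W.shape[1]
    if C < 2 or T == 0:
        return V
    W_raw = W
    if smooth > 0.0:
        W = W + smooth
    rowsum = W.sum(axis=1)  # (T,)
    if rowsum.sum() <= 0:
        return V
    def penalty(v):
        return 0.5 * ridge * float(np.sum(v[:, 1:] ** 2)) if ridge > 0.0 else 0.0

    f = _weighted_mnlogit_objective(V, X, W) - penalty(V)
    f_raw = _weighted_mnlogit_objective(V, X, W_raw)
    dim = (C - 1) * P
    ridge_diag = np.zeros(dim)
    if ridge > 0.0:
        ridge_diag = np.tile(np.r_[0.0, np.full(P - 1, ridge)], C - 1)
    for _ in range(steps):
        logits = np.concatenate([np.zeros((T, 1)), X @ V.T], axis=1)
        pr = softmax(logits, axis=1)[:, 1:]  # (T, C-1)
        grad = (W[:, 1:] - rowsum[:, None] * pr).T @ X  # (C-1, P)
        if ridge > 0.0:
            grad[:, 1:] -= ridge * V[:, 1:]
        # Hessian of -f: block (c, d) = sum_t rowsum_t (diag(pr) - pr pr^T) x x^T
        wpr = rowsum[:, None] * pr
        diag_blocks = np.einsum("tc,tp,tq->cpq", wpr, X, X)
        cross = np.einsum("tc,td,tp,tq->cdpq", wpr, pr, X, X)
        H = -cross
        idx = np.arange(C - 1)
        H[idx, idx] += diag_blocks
        Hm = H.transpose(0, 2, 1, 3).reshape(dim, dim)
        Hm = Hm + np.diag(ridge_diag) + 1e-8 * (np.trace(Hm) / dim + 1.0) * np.eye(dim)
        try:
            delta = np.linalg.solve(Hm, grad.reshape(dim)).reshape(C - 1, P)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        accepted = False
        while step > 1e-4:
            Vn = V + step * delta
            fn = _weighted_mnlogit_objective(Vn, X, W) - penalty(Vn)
            fn_raw = _weighted_mnlogit_objective(Vn, X, W_raw)
            # the raw (unsmoothed) objective must not decrease either, so the
            # EM likelihood trace stays monotone under smoothing
            if fn >= f - 1e-12 and fn_raw >= f_raw - 1e-12:
                if fn <= f + 1e-12:
                    return V
                V, f, f_raw, accepted = Vn, fn, fn_raw, True
                break
            step /= 2.0
        if not accepted:
            break
    return V


def _m_step(params: HMMParameters, X, obs, gamma, xi, cfg: EMConfig) -> None:
    S = params.n_states
    # initial distribution
    params.initial_logits = _floored_log_ratio(gamma[0], cfg.prob_floor)
    # transitions
    if S > 1:
        if cfg.use_covariates_in_transitions and X.shape[1] > 1:
            for s in range(S):
                V = _weighted_mnlogit_newton(
                    X[1:], xi[:, s, :], params.transition_weights[s, 1:, :].copy(),
                    cfg.newton_steps, smooth=cfg.prob_floor,
                    ridge=cfg.covariate_ridge,
                )
                params.transition_weights[s, 1:, :] = V
                params.transition_weights[s, 0, :] = 0.0
        else:
            counts = xi.sum(axis=0)  # (S, S)
            counts = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
            params.transition_weights[:, :, 0] = _floored_log_ratio(
                counts, cfg.prob_floor
            )
            params.transition_weights[:, :, 1:] = 0.0
    # emissions
    for k, card in enumerate(params.schema.observation_cardinalities):
        onehot = np.zeros((obs.shape[0], card))
        onehot[np.arange(obs.shape[0]), obs[:, k]] = 1.0
        if cfg.use_covariates_in_emissions and X.shape[1] > 1:
            for s in range(S):
                V = _weighted_mnlogit_newton(
                    X, gamma[:, s : s + 1] * onehot,
                    params.emission_weights[k][s, 1:, :].copy(), cfg.newton_steps,
                    smooth=cfg.prob_floor, ridge=cfg.covariate_ridge,
                )
                params.emission_weights[k][s, 1:, :] = V
                params.emission_weights[k][s, 0, :] = 0.0
        else:
            counts = gamma.T @ onehot  # (S, C)
            counts = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1e-300)
            params.emission_weights[k][:, :, 0] = _floored_log_ratio(
                counts, cfg.prob_floor
            )
            params.emission_weights[k][:, :, 1:] = 0.0


def _init_params(
    schema: DatasetSchema, S: int, cfg: EMConfig, rng: np.random.Generator
) -> HMMParameters:
    # uniform + small seeded jitter on the intercepts; covariate weights start at 0
    P = schema.design_dim
    params = uniform_parameters(
        schema, S, cfg.use_covariates_in_transitions, cfg.use_covariates_in_emissions
    )
    params.initial_logits = cfg.init_jitter * rng.standard_normal(S)
    params.initial_logits[0] = 0.0
    if S > 1:
        params.transition_weights[:, 1:, 0] = cfg.init_jitter * rng.standard_normal(
            (S, S - 1)
        )
    ew = []
    for c in schema.observation_cardinalities:
        w = np.zeros((S, c, P))
        w[:, 1:, 0] = cfg.init_jitter * rng.standard_normal((S, c - 1))
        ew.append(w)
    params.emission_weights = tuple(ew)
    return params


def _segment_init(
    schema: DatasetSchema,
    S: int,
    cfg: EMConfig,
    rng: np.random.Generator,
    observations: np.ndarray,
) -> HMMParameters:
    """Initialize states from a random contiguous segmentation of the series.

    Health trajectories are broadly progressive, so seeding each state's
    emissions with the category frequencies of one time segment (plus a
    sticky, forward-leaning transition guess) starts EM near the phase
    structure instead of at an uninformative symmetric point.  Segment
    proportions are redrawn per restart from a Dirichlet.
    """
    L = observations.shape[0]
    P = schema.design_dim
    params = uniform_parameters(
        schema, S, cfg.use_covariates_in_transitions, cfg.use_covariates_in_emissions
    )
    params.initial_logits = np.full(S, -2.0) + 0.1 * rng.standard_normal(S)
    params.initial_logits[0] = 0.0
    if S > 1:
        A = np.full((S, S), 0.02 / max(S - 2, 1))
        for s in range(S):
            A[s, s] = 0.78
            if s + 1 < S:
                A[s, s + 1] = 0.20
            A[s] /= A[s].sum()
        params.transition_weights[:, :, 0] = np.log(A) - np.log(A[:, :1])
    bounds = np.clip(
        np.round(np.cumsum(rng.dirichlet(np.full(S, 3.0))) * L).astype(int), 1, L
    )
    bounds[-1] = L
    ew = []
    for k, card in enumerate(schema.observation_cardinalities):
        w = np.zeros((S, card, P))
        start = 0
        for s, bound in enumerate(bounds):
            seg = observations[start : max(bound, start + 1), k]
            freq = np.bincount(seg, minlength=card).astype(float) + 0.5
            freq /= freq.sum()
            w[s, :, 0] = np.log(freq) - np.log(freq[0])
            start = bound
        ew.append(w)
    params.emission_weights = tuple(ew)
    return params


def _em_single(params: HMMParameters, X, obs, cfg: EMConfig):
    log_pi = None
    trace = []
    prev = -np.inf
    converged = False
    S = params.n_states
    for _ in range(cfg.max_iter):
        logB = _log_emission_matrix(params, X, obs)
        log_pi = log_softmax(params.initial_logits)
        if S == 1:
            ll = float(logB.sum())
            gamma = np.ones((X.shape[0], 1))
            xi = np.ones((X.shape[0] - 1, 1, 1))
        else:
            logA = _log_transition_tensor(params, X)
            log_alpha, log_beta, ll = _forward_backward(log_pi, logA, logB)
            gamma = np.exp(log_alpha + log_beta - ll)
            xi = np.exp(
                log_alpha[:-1, :, None]
                + logA[1:]
                + (logB[1:] + log_beta[1:])[:, None, :]
                - ll
            )
        trace.append(ll)
        if np.isfinite(prev) and (ll - prev) <= cfg.tol * abs(prev):
            converged = True
            break
        prev = ll
        _m_step(params, X, obs, gamma, xi, cfg)
    else:
        # record the likelihood of the final parameters
        logB = _log_emission_matrix(params, X, obs)
        if S == 1:
            trace.append(float(logB.sum()))
        else:
            logA = _log_transition_tensor(params, X)
            _, _, ll = _forward_backward(log_softmax(params.initial_logits), logA, logB)
            trace.append(ll)
    return params, np.asarray(trace), converged


def fit_em(
    traj: Trajectory,
    schema: DatasetSchema,
    n_states: int,
    config: EMConfig | None = None,
    seed: int = 0,
) -> FitResult:
    """Fit one HMM to one trajectory by EM with seeded restarts.

    The best (highest final log-likelihood) restart is returned.  Raises
    :class:`OverfitError` when the free-parameter count exceeds
    ``config.overfit_guard * L * d``.
    """
    cfg = config or EMConfig()
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    traj.validate(schema)
    if n_states >= 2 and traj.length < 2:
        raise TrajectoryError("need L >= 2 to fit a multi-state model")
    n_par = n_free_parameters(
        schema, n_states, cfg.use_covariates_in_transitions,
        cfg.use_covariates_in_emissions,
    )
    budget = cfg.overfit_guard * traj.length * schema.n_observation_channels
    if n_par > budget:
        raise OverfitError(
            f"{n_par} free parameters exceed the overfitting guard "
            f"({cfg.overfit_guard} x L x d = {budget:.0f}); reduce the state count"
        )
    X = schema.encode_covariates(traj.covariates)
    obs = traj.observations
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_restarts)
    best = None
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        # multi-state restarts are seeded from random time segmentations;
        # the single-state model has no phases to seed
        if n_states == 1:
            params = _init_params(schema, n_states, cfg, rng)
        else:
            params = _segment_init(schema, n_states, cfg, rng, obs)
        params, trace, converged = _em_single(params, X, obs, cfg)
        if best is None or trace[-1] > best[1][-1]:
            best = (params, trace, converged)
    params, trace, converged = best
    return FitResult(
        params=params,
        log_likelihood_trace=trace,
        converged=converged,
        n_restarts_used=cfg.n_restarts,
        seed=seed,
    )


# =====================================================================
# sampling
# =====================================================================


def sample_trajectory(
    params: HMMParameters,
    covariates: np.ndarray,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sample",
) -> Trajectory:
    """Draw one trajectory from the generative process.

    The covariate path is supplied externally (covariates condition the model
    but are not emitted by it).  Reproducible given a seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covariates = np.asarray(covariates, dtype=np.int64)
    if covariates.ndim == 1:
        covariates = covariates.reshape(-1, params.schema.n_covariate_channels or 1)
    if params.schema.n_covariate_channels == 0:
        covariates = covariates.reshape(covariates.shape[0], 0)
    L = covariates.shape[0]
    if L < 1:
        raise TrajectoryError("covariate path must have length >= 1")
    X = params.schema.encode_covariates(covariates)
    S = params.n_states
    d = params.schema.n_observation_channels
    obs = np.zeros((L, d), dtype=np.int64)
    state = int(rng.choice(S, p=params.initial_distribution()))
    for t in range(L):
        if t > 0:
            probs = softmax(params.transition_weights[state] @ X[t])
            state = int(rng.choice(S, p=probs))
        for k in range(d):
            p = softmax(params.emission_weights[k][state] @ X[t])
            obs[t, k] = int(rng.choice(p.shape[0], p=p))
    return Trajectory(subject_id=subject_id, observations=obs, covariates=covariates)
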