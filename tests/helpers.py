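"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
textbook formulas) and shares no code with the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import softmax

from trajclust.hmm import HMMParameters, uniform_parameters
from trajclust.schema import DatasetSchema, Trajectory


def brute_force_log_likelihood(params: HMMParameters, traj: Trajectory) -> float:
    """Sum P(path, observations) over all S^L hidden-state paths."""
    X = params.schema.encode_covariates(traj.covariates)
    S, L = params.n_states, traj.length
    pi = softmax(params.initial_logits)
    total = 0.0
    for path in itertools.product(range(S), repeat=L):
        p = pi[path[0]]
        for t in range(L):
            if t > 0:
                A = softmax(params.transition_weights[path[t - 1]] @ X[t])
                p *= A[path[t]]
            p *= np.exp(_emission_prob(params, path[t], X[t], traj.observations[t]))
        total += p
    return float(np.log(total))


def _emission_prob(params, state, x, obs_row) -> float:
    lp = 0.0
    for k in range(params.schema.n_observation_channels):
        probs = softmax(params.emission_weights[k][state] @ x)
        lp += np.log(probs[obs_row[k]])
    return lp


def brute_force_posteriors(params: HMMParameters, traj: Trajectory):
    """State and pairwise posteriors by enumerating all paths."""
    X = params.schema.encode_covariates(traj.covariates)
    S, L = params.n_states, traj.length
    pi = softmax(params.initial_logits)
    gamma = np.zeros((L, S))
    xi = np.zeros((max(L - 1, 0), S, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=L):
        p = pi[path[0]]
        for t in range(L):
            if t > 0:
                A = softmax(params.transition_weights[path[t - 1]] @ X[t])
                p *= A[path[t]]
            p *= np.exp(_emission_prob(params, path[t], X[t], traj.observations[t]))
        total += p
        for t in range(L):
            gamma[t, path[t]] += p
        for t in range(L - 1):
            xi[t, path[t], path[t + 1]] += p
    return gamma / total, xi / total


def random_model(
    schema: DatasetSchema,
    n_states: int,
    rng: np.random.Generator,
    scale: float = 1.0,
    covariates_in_emissions: bool = False,
) -> HMMParameters:
    """Random reference-pinned parameters for oracle comparisons."""
    params = uniform_parameters(
        schema,
        n_states,
        use_covariates_in_transitions=True,
        use_covariates_in_emissions=covariates_in_emissions,
    )
    P = schema.design_dim
    params.initial_logits = scale * rng.normal(size=n_states)
    params.initial_logits[0] = 0.0
    w = scale * rng.normal(size=(n_states, n_states, P))
    w[:, 0, :] = 0.0
    params.transition_weights = w
    ew = []
    for c in schema.observation_cardinalities:
        e = scale * rng.normal(size=(n_states, c, P))
        e[:, 0, :] = 0.0
        if not covariates_in_emissions:
            e[:, :, 1:] = 0.0
        ew.append(e)
    params.emission_weights = tuple(ew)
    return params


def model_from_tables(
    schema: DatasetSchema,
    initial: np.ndarray,
    transition: np.ndarray,
    emissions: list[np.ndarray],
) -> HMMParameters:
    """Build a covariate-free model from plain probability tables."""
    S = len(initial)
    params = uniform_parameters(schema, S, use_covariates_in_transitions=False)
    initial = np.asarray(initial, dtype=float)
    params.initial_logits = np.log(initial) - np.log(initial[0])
    A = np.asarray(transition, dtype=float)
    params.transition_weights[:, :, 0] = np.log(A) - np.log(A[:, :1])
    ew = []
    for k, E in enumerate(emissions):
        E = np.asarray(E, dtype=float)
        w = np.zeros((S, E.shape[1], schema.design_dim))
        w[:, :, 0] = np.log(E) - np.log(E[:, :1])
        ew.append(w)
    params.emission_weights = tuple(ew)
    return params


def enumerate_observation_space(schema: DatasetSchema, length: int):
    """All possible observation tables of the given length (small channels)."""
    cards = schema.observation_cardinalities
    per_step = list(itertools.product(*[range(c) for c in cards]))
    for combo in itertools.product(per_step, repeat=length):
        yield np.asarray(combo, dtype=np.int64)


def exact_kl_between_models(model_a, model_b, covariates, length) -> float:
    """Exact trajectory-space KL by enumerating every observation sequence."""
    from trajclust.hmm import forward_log_likelihood

    kl = 0.0
    for obs in enumerate_observation_space(model_a.schema, length):
        traj = Trajectory("enum", obs, covariates)
        la = forward_log_likelihood(model_a, traj)
        lb = forward_log_likelihood(model_b, traj)
        kl += np.exp(la) * (la - lb)
    return float(kl)


def silhouette_reference(D: np.ndarray, labels: np.ndarray) -> float:
    """Textbook silhouette: s(i) = (b - a) / max(a, b); singletons 0."""
    n = D.shape[0]
    vals = []
    for i in range(n):
        own = np.flatnonzero((labels == labels[i]) & (np.arange(n) != i))
        if own.size == 0:
            vals.append(0.0)
            continue
        a = D[i, own].mean()
        b = min(
            D[i, labels == k].mean() for k in np.unique(labels) if k != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def dunn_reference(D: np.ndarray, labels: np.ndarray) -> float:
    clusters = [np.flatnonzero(labels == k) for k in np.unique(labels)]
    sep = min(
        D[i, j]
        for a, b in itertools.combinations(range(len(clusters)), 2)
        for i in clusters[a]
        for j in clusters[b]
    )
    diam = max(
        (D[i, j] for c in clusters for i in c for j in c if i != j), default=0.0
    )
    return float(sep / diam)


def davies_bouldin_reference(D, labels, medoids) -> float:
    uniq = np.unique(labels)
    K = uniq.size
    S = [D[labels == k, medoids[i]].mean() for i, k in enumerate(uniq)]
    total = 0.0
    for i in range(K):
        total += max(
            (S[i] + S[j]) / D[medoids[i], medoids[j]] for j in range(K) if j != i
        )
    return float(total / K)


def exhaustive_pam_cost(D: np.ndarray, K: int) -> float:
    """Global optimum of the PAM objective by trying every medoid subset."""
    n = D.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), K):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return float(best)
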