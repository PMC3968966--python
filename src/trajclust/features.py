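"""Interpretive trajectory features, cluster profiles, and hidden-state
selection.

Clusters of health trajectories are interpreted through a small vector of
features per subject: the fraction of the trajectory spent with each chronic
condition, and the fraction of the pre-onset / post-onset windows spent in
each risk-factor category.  The *pre-onset window* is the part of the
trajectory strictly before the earliest event onset (whichever condition
comes first); the *post-onset window* starts at the latest first-onset among
the event channels (i.e., once every condition has appeared) and includes
the onset step itself.  Windows of length zero, and subjects for whom the
relevant onsets never occur, produce missing feature values which are
excluded from cluster means rather than imputed.

The number of hidden states is chosen by the profile-decorrelation
criterion: for each candidate state count, fit per-trajectory HMMs, build
the empirical symmetrized KL distance matrix, pick the cluster count by the
Dunn index, and compute the mean pairwise Pearson correlation between the
cluster feature profiles.  The state count whose profiles are least
correlated wins — distinct, interpretable profiles indicate that the
embedding resolved genuinely different dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import distance as _distance
from . import hmm as _hmm
from .schema import DatasetSchema, Trajectory

__all__ = [
    "FeatureProfile",
    "StateSelectionResult",
    "compute_trajectory_features",
    "feature_names",
    "compute_feature_matrix",
    "cluster_feature_profiles",
    "average_profile_correlation",
    "select_num_hidden_states",
]


def _event_indices(schema: DatasetSchema) -> list[int]:
    return [schema.observation_names.index(e) for e in schema.event_channels]


def _state_channels(schema: DatasetSchema):
    """Channels profiled over the pre-/post-onset windows: covariates plus
    any non-event observation channels."""
    chans = [("cov", j, name, cats) for j, (name, cats) in enumerate(schema.covariate_channels)]
    for k, (name, cats) in enumerate(schema.observation_channels):
        if name not in schema.event_channels:
            chans.append(("obs", k, name, cats))
    return chans


def feature_names(schema: DatasetSchema) -> list[str]:
    """Ordered feature names for :func:`compute_trajectory_features`.

    The reference (first) category of every profiled channel is suppressed,
    mirroring the redundancy of mutually exclusive categories.
    """
    if not schema.event_channels:
        # no onsets to anchor windows on: whole-trajectory category fractions
        return [
            f"fraction_{chan}={c}"
            for _, _, chan, cats in _state_channels(schema)
            for c in cats[1:]
        ]
    names = [f"time_with_{schema.observation_names[k]}" for k in _event_indices(schema)]
    for _, _, chan, cats in _state_channels(schema):
        names.extend(f"{chan}={c}_before_first_onset" for c in cats[1:])
    for _, _, chan, cats in _state_channels(schema):
        names.extend(f"{chan}={c}_after_last_onset" for c in cats[1:])
    return names


def compute_trajectory_features(traj: Trajectory, schema: DatasetSchema) -> np.ndarray:
    """Feature vector for one subject; undefined entries are NaN."""
    traj.validate(schema)
    ev = _event_indices(schema)
    if not ev:
        warnings.warn(
            "schema has no event channels; onset-window features skipped",
            stacklevel=2,
        )
        vals = []
        for kind, j, _, cats in _state_channels(schema):
            col = traj.covariates[:, j] if kind == "cov" else traj.observations[:, j]
            vals.extend(float((col == c).mean()) for c in range(1, len(cats)))
        return np.asarray(vals)
    L = traj.length
    values: list[float] = []
    onsets = []
    for k in ev:
        present = traj.observations[:, k] == 1
        values.append(float(present.mean()))
        onsets.append(int(np.argmax(present)) if present.any() else None)
    # pre-onset window: strictly before the earliest onset over all events
    observed = [o for o in onsets if o is not None]
    pre = np.arange(min(observed)) if (ev and observed) else None
    if pre is not None and pre.size == 0:
        pre = None
    # post-onset window: at or after the latest first-onset, defined only
    # when every event channel has onset
    post = None
    if ev and all(o is not None for o in onsets):
        post = np.arange(max(onsets), L)
    for window in (pre, post):
        for kind, j, _, cats in _state_channels(schema):
            col = traj.covariates[:, j] if kind == "cov" else traj.observations[:, j]
            for c in range(1, len(cats)):
                if window is None:
                    values.append(np.nan)
                else:
                    values.append(float((col[window] == c).mean()))
    return np.asarray(values)


def compute_feature_matrix(
    trajectories: list[Trajectory],
    schema: DatasetSchema,
    min_support: float = 0.0,
) -> pd.DataFrame:
    """Per-subject feature table (subjects x features).

    ``min_support`` drops window-fraction features for categories observed in
    fewer than that fraction of subject-steps (rare categories make noisy,
    uninformative profile entries).
    """
    rows = [compute_trajectory_features(t, schema) for t in trajectories]
    df = pd.DataFrame(
        rows,
        index=[t.subject_id for t in trajectories],
        columns=feature_names(schema),
    )
    if min_support > 0.0:
        drop = []
        for kind, j, chan, cats in _state_channels(schema):
            cols = np.concatenate(
                [t.covariates[:, j] if kind == "cov" else t.observations[:, j]
                 for t in trajectories]
            )
            for c in range(1, len(cats)):
                if (cols == c).mean() < min_support:
                    drop.extend(
                        [f"{chan}={cats[c]}_before_first_onset",
                         f"{chan}={cats[c]}_after_last_onset"]
                    )
        df = df.drop(columns=[c for c in drop if c in df.columns])
    return df


@dataclass
class FeatureProfile:
    """Per-subject features plus per-cluster mean profiles."""

    feature_names: list[str]
    per_subject: pd.DataFrame
    per_cluster: pd.DataFrame


def cluster_feature_profiles(per_subject: pd.DataFrame, labels) -> FeatureProfile:
    """Cluster-mean profiles over subjects with each feature defined."""
    labels = np.asarray(labels)
    if labels.shape[0] != per_subject.shape[0]:
        raise ValueError("labels length does not match the feature table")
    per_cluster = per_subject.groupby(labels).mean()  # pandas skips NaN
    per_cluster.index.name = "cluster"
    return FeatureProfile(
        feature_names=list(per_subject.columns),
        per_subject=per_subject,
        per_cluster=per_cluster,
    )


def average_profile_correlation(profile: FeatureProfile, min_features: int = 3) -> float:
    """Mean pairwise Pearson correlation between the K cluster profiles.

    Each pair is correlated over its jointly defined (non-missing) features;
    a zero-variance profile or too few shared features raises an error.
    """
    P = profile.per_cluster.to_numpy(dtype=float)
    K = P.shape[0]
    if K < 2:
        raise ValueError("need at least two cluster profiles")
    cors = []
    for a in range(K):
        for b in range(a + 1, K):
            mask = np.isfinite(P[a]) & np.isfinite(P[b])
            if mask.sum() < min_features:
                raise ValueError(
                    f"profiles {a} and {b} share only {int(mask.sum())} defined features"
                )
            x, y = P[a, mask], P[b, mask]
            if x.std() == 0.0 or y.std() == 0.0:
                raise ValueError(
                    f"zero-variance profile in pair ({a}, {b}): correlation undefined"
                )
            cors.append(float(np.corrcoef(x, y)[0, 1]))
    return float(np.mean(cors))


@dataclass
class StatePipelineDetail:
    """Intermediate artifacts of one candidate state count."""

    n_states: int
    fits: list[_hmm.FitResult]
    loglik: _distance.LikelihoodMatrix
    dist: _distance.DistanceMatrix
    selected_k: int
    index_table: pd.DataFrame
    clustering: _cluster.ClusteringResult
    profile: FeatureProfile
    avg_correlation: float


@dataclass
class StateSelectionResult:
    best_s: int
    table: pd.DataFrame
    details: dict[int, StatePipelineDetail] = field(repr=False, default_factory=dict)


def select_num_hidden_states(
    trajectories: list[Trajectory],
    schema: DatasetSchema,
    s_range,
    k_range=range(2, 11),
    em_config: _hmm.EMConfig | None = None,
    distance_method: str = "empirical",
    pam_restarts: int = 5,
    min_support: float = 0.0,
    seed: int = 0,
) -> StateSelectionResult:
    """Run the full pipeline for each candidate state count and pick the one
    whose cluster feature profiles are least correlated.

    Returns the winning state count, a table mirroring the per-S summary
    (selected K and average profile correlation), and the per-S intermediate
    artifacts for reuse.
    """
    s_range = sorted(set(int(s) for s in s_range))
    if not s_range:
        raise ValueError("empty state range")
    em_config = em_config or _hmm.EMConfig()
    feats = compute_feature_matrix(trajectories, schema, min_support=min_support)
    ss = np.random.SeedSequence(seed)
    rows = []
    details: dict[int, StatePipelineDetail] = {}
    for s, child in zip(s_range, ss.spawn(len(s_range))):
        fit_seeds = child.generate_state(len(trajectories) + 1) % (2**31)
        fits = [
            _hmm.fit_em(t, schema, s, config=em_config, seed=int(fs))
            for t, fs in zip(trajectories, fit_seeds)
        ]
        models = [f.params for f in fits]
        lm = _distance.likelihood_matrix(models, trajectories)
        dist = _distance.symmetrized_distance_matrix(lm, method=distance_method)
        best_k, table, results = _cluster.select_num_clusters(
            dist, k_range, n_restarts=pam_restarts, seed=int(fit_seeds[-1])
        )
        clustering = results[best_k]
        profile = cluster_feature_profiles(feats, clustering.labels)
        corr = average_profile_correlation(profile)
        details[s] = StatePipelineDetail(
            n_states=s, fits=fits, loglik=lm, dist=dist, selected_k=best_k,
            index_table=table, clustering=clustering, profile=profile,
            avg_correlation=corr,
        )
        rows.append(
            {"n_states": s, "selected_k": best_k, "avg_profile_correlation": corr}
        )
    table = pd.DataFrame(rows).set_index("n_states")
    corrs = table["avg_profile_correlation"].to_numpy()
    # exact ties arise when two state counts induce the very same partition
    # (identical profiles); the criterion is then indifferent and parsimony
    # prefers the smaller state count
    best_s = s_range[int(np.argmin(corrs))]
    return StateSelectionResult(best_s=best_s, table=table, details=details)
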