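"""Seeded synthetic benchmark: known-structure health-trajectory datasets.

The generator emulates the validation logic of the clustering pipeline:
sample trajectories from a small population of known covariate-HMMs ("cluster
centers"), run the pipeline, and check that the known component structure and
state count are recovered.

Each component is a 3-state left-to-right progression model over the default
health schema (healthy -> component-specific first-disease phase ->
all-diseases phase, with effectively absorbing disease channels).  The four
default archetypes differ in which disease onsets first (heart / diabetes /
stroke / heart+diabetes together), in progression speed, and in their
post-onset risk-factor drift (weight loss vs gain, smoking cessation) — the
same axes along which real trajectory clusters are distinguishable.  The
sampled population is restricted, by rejection, to subjects whose full
sequential progression is observed inside the window: a subject who never
onsets, is already sick at baseline, or develops everything in one step
carries no ordering signal and is unclassifiable by construction.

A scalar ``separation`` blends every component's parameters (and drift
pattern) toward the population mean: 0 makes all components identical (null
control), 1 uses the archetypes as specified.  Covariate paths (BMI class,
smoking status) follow shared exogenous Markov chains, modulated post-onset
by the per-component feedback drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import softmax
from sklearn.metrics import adjusted_rand_score

from .hmm import HMMParameters, sample_trajectory
from .schema import DatasetSchema, Trajectory, default_health_schema

__all__ = [
    "MarkovChainSpec",
    "BenchmarkConfig",
    "ConfusionResult",
    "make_hmm_population",
    "sample_covariate_path",
    "sample_dataset",
    "confusion_matrix",
]


@dataclass(frozen=True)
class MarkovChainSpec:
    """First-order Markov chain over one categorical covariate channel."""

    initial: tuple[float, ...]
    transition: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        p0 = np.asarray(self.initial, dtype=float)
        P = np.asarray(self.transition, dtype=float)
        if not np.isclose(p0.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if P.shape != (p0.size, p0.size) or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be square and row-stochastic")


def _default_covariate_chains() -> dict[str, MarkovChainSpec]:
    return {
        "bmi": MarkovChainSpec(
            initial=(0.02, 0.38, 0.35, 0.25),
            transition=(
                (0.85, 0.15, 0.00, 0.00),
                (0.01, 0.88, 0.11, 0.00),
                (0.00, 0.08, 0.84, 0.08),
                (0.00, 0.00, 0.10, 0.90),
            ),
        ),
        "smoking": MarkovChainSpec(
            initial=(0.50, 0.30, 0.20),
            transition=(
                (0.97, 0.02, 0.01),
                (0.01, 0.89, 0.10),
                (0.03, 0.07, 0.90),
            ),
        ),
    }


@dataclass
class BenchmarkConfig:
    """Study conditions of the synthetic validation experiment.

    Defaults: four 3-state components, 30 subjects each, trajectory lengths
    uniform on 10..20, separation 1 (archetypes as specified).
    """

    n_components: int = 4
    states_per_component: int = 3
    subjects_per_component: int = 30
    length_range: tuple[int, int] = (10, 20)
    separation: float = 1.0
    # post-onset risk-factor drift strength (0 disables the feedback hook)
    risk_feedback: float = 0.3
    # emulate cohorts restricted to subjects who develop every condition
    require_all_onsets: bool = True
    covariate_chains: dict[str, MarkovChainSpec] = field(
        default_factory=_default_covariate_chains
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length_range")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# archetype definitions: rows = hidden state, columns = destination state /
# disease channel.  The middle phase (state 1) carries each component's
# distinguishing disease pattern; archetypes also differ in progression
# speed.  The chain is left-to-right (chronic conditions do not remit;
# back-rates are numerically tiny rather than exactly zero so every logit
# stays finite) and direct healthy -> advanced jumps are rare, so nearly
# every subject expresses the middle phase.  P(present | state) of 0.999
# keeps the disease channels effectively absorbing.
_ARCH_TRANSITIONS = [
    # heart-first, slow pre-onset phase
    ((0.72, 0.278, 0.002), (1e-8, 0.74, 0.26), (1e-8, 1e-8, 1.0)),
    # diabetes-first
    ((0.62, 0.378, 0.002), (1e-8, 0.72, 0.28), (1e-8, 1e-8, 1.0)),
    # stroke-first
    ((0.67, 0.328, 0.002), (1e-8, 0.73, 0.27), (1e-8, 1e-8, 1.0)),
    # heart + diabetes together, stroke last; fast onset, long middle phase
    ((0.50, 0.498, 0.002), (1e-8, 0.80, 0.20), (1e-8, 1e-8, 1.0)),
]
_ARCH_EMISSIONS = [
    # P(disease present | state) per channel (heart, diabetes, stroke)
    ((0.001, 0.001, 0.001), (0.999, 0.001, 0.001), (0.999, 0.999, 0.999)),
    ((0.001, 0.001, 0.001), (0.001, 0.999, 0.001), (0.999, 0.999, 0.999)),
    ((0.001, 0.001, 0.001), (0.001, 0.001, 0.999), (0.999, 0.999, 0.999)),
    ((0.001, 0.001, 0.001), (0.999, 0.999, 0.001), (0.999, 0.999, 0.999)),
]
_ARCH_INITIAL = [
    (0.95, 0.04, 0.01),
    (0.95, 0.04, 0.01),
    (0.95, 0.04, 0.01),
    (0.95, 0.04, 0.01),
]
# post-onset risk-factor drift per component (scaled by config.risk_feedback):
# bmi direction (-1 weight loss, +1 weight gain, 0 none) and per-step
# probability multiplier for smokers quitting — emulating the
# cluster-specific weight-change and smoking-cessation patterns that make
# cluster feature profiles distinguishable in real cohorts
_ARCH_FEEDBACK = [
    {"bmi": -1.0, "quit": 0.1},   # heart-first: weight loss, little quitting
    {"bmi": +1.0, "quit": 0.6},   # diabetes-first: weight gain, some quitting
    {"bmi": 0.0, "quit": 1.0},    # stroke-first: strong quitting
    {"bmi": -1.0, "quit": 1.0},   # heart+diabetes: weight loss and quitting
]

# shared covariate effects on the single-step progression logits (per dummy
# regressor: bmi normal/overweight/obese, smoking smoking/quit)
_PROGRESSION_EFFECTS = {
    "bmi=normal": 0.1,
    "bmi=overweight": 0.35,
    "bmi=obese": 0.6,
    "smoking=smoking": 0.5,
    "smoking=quit_smoking": 0.2,
}


def make_hmm_population(config: BenchmarkConfig) -> list[HMMParameters]:
    """Construct the component-center HMMs.

    Components are deterministic archetypes (cycled if ``n_components`` > 4)
    blended toward their mean by ``separation`` in logit space.
    """
    schema = default_health_schema()
    S = config.states_per_component
    P = schema.design_dim
    if S != 3:
        raise ValueError("the archetype population is defined for 3-state components")
    design_names = schema.design_column_names()
    comps = []
    for c in range(config.n_components):
        a = c % len(_ARCH_TRANSITIONS)
        trans = np.zeros((S, S, P))
        A = np.asarray(_ARCH_TRANSITIONS[a])
        trans[:, :, 0] = np.log(A) - np.log(A[:, :1])
        for j, name in enumerate(design_names):
            eff = _PROGRESSION_EFFECTS.get(name)
            if eff is None:
                continue
            for s in range(S - 1):
                trans[s, s + 1, j] = eff
        emis = []
        E = np.asarray(_ARCH_EMISSIONS[a])
        for k in range(schema.n_observation_channels):
            w = np.zeros((S, 2, P))
            for s in range(S):
                w[s, 1, 0] = _logit(E[s, k])
            emis.append(w)
        pi = np.asarray(_ARCH_INITIAL[a])
        init = np.log(pi) - np.log(pi[0])
        comps.append(
            HMMParameters(
                schema=schema,
                n_states=S,
                initial_logits=init,
                transition_weights=trans,
                emission_weights=tuple(emis),
                use_covariates_in_transitions=True,
                use_covariates_in_emissions=False,
            )
        )
    # blend toward the population mean by the separation dial
    sep = config.separation
    mean_init = np.mean([p.initial_logits for p in comps], axis=0)
    mean_trans = np.mean([p.transition_weights for p in comps], axis=0)
    mean_emis = [
        np.mean([p.emission_weights[k] for p in comps], axis=0)
        for k in range(schema.n_observation_channels)
    ]
    for p in comps:
        p.initial_logits = mean_init + sep * (p.initial_logits - mean_init)
        p.transition_weights = mean_trans + sep * (p.transition_weights - mean_trans)
        p.emission_weights = tuple(
            mean_emis[k] + sep * (p.emission_weights[k] - mean_emis[k])
            for k in range(schema.n_observation_channels)
        )
    return comps


def sample_covariate_path(
    chains: dict[str, MarkovChainSpec],
    schema: DatasetSchema,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample an ``(L, q)`` covariate table from the per-channel chains."""
    path = np.zeros((length, schema.n_covariate_channels), dtype=np.int64)
    for j, name in enumerate(schema.covariate_names):
        spec = chains[name]
        p0 = np.asarray(spec.initial)
        P = np.asarray(spec.transition)
        state = int(rng.choice(p0.size, p=p0))
        path[0, j] = state
        for t in range(1, length):
            state = int(rng.choice(p0.size, p=P[state]))
            path[t, j] = state
    return path


def _sample_with_feedback(
    params: HMMParameters,
    chains: dict[str, MarkovChainSpec],
    length: int,
    feedback: float,
    drift: dict[str, float],
    rng: np.random.Generator,
    subject_id: str,
) -> Trajectory:
    """Joint stepwise sampler with post-onset risk-factor drift.

    Once any disease is present, the BMI class drifts one category per step
    in the component's direction with probability ``feedback * |bmi|`` and
    current smokers quit with probability ``feedback * quit``.
    """
    schema = params.schema
    cov = np.zeros((length, schema.n_covariate_channels), dtype=np.int64)
    obs = np.zeros((length, schema.n_observation_channels), dtype=np.int64)
    chain_arrays = {
        name: (np.asarray(c.initial), np.asarray(c.transition))
        for name, c in chains.items()
    }
    bmi_j = schema.covariate_names.index("bmi")
    smk_j = schema.covariate_names.index("smoking")
    n_bmi = schema.covariate_cardinalities[bmi_j]
    state = None
    diseased = False
    for t in range(length):
        for j, name in enumerate(schema.covariate_names):
            p0, P = chain_arrays[name]
            cov[t, j] = (
                rng.choice(p0.size, p=p0) if t == 0 else rng.choice(p0.size, p=P[cov[t - 1, j]])
            )
        if diseased and feedback > 0.0:
            b = drift.get("bmi", 0.0)
            if b < 0 and cov[t, bmi_j] > 1 and rng.random() < feedback * -b:
                cov[t, bmi_j] -= 1
            elif b > 0 and cov[t, bmi_j] < n_bmi - 1 and rng.random() < feedback * b:
                cov[t, bmi_j] += 1
            if cov[t, smk_j] == 1 and rng.random() < feedback * drift.get("quit", 0.0):
                cov[t, smk_j] = 2
        x = schema.encode_covariate_row(cov[t])
        if t == 0:
            state = int(rng.choice(params.n_states, p=params.initial_distribution()))
        else:
            probs = softmax(params.transition_weights[state] @ x)
            state = int(rng.choice(params.n_states, p=probs))
        for k in range(schema.n_observation_channels):
            p = softmax(params.emission_weights[k][state] @ x)
            obs[t, k] = int(rng.choice(p.shape[0], p=p))
        if obs[t].any():
            diseased = True
    return Trajectory(subject_id=subject_id, observations=obs, covariates=cov)


def sample_dataset(
    population: list[HMMParameters], config: BenchmarkConfig
) -> tuple[list[Trajectory], np.ndarray]:
    """Sample the benchmark dataset: ``subjects_per_component`` trajectories
    per component, lengths uniform on the configured range.

    Returns ``(trajectories, true_labels)``; covariate paths are stored
    inside each trajectory.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    schema = population[0].schema
    lmin, lmax = config.length_range
    trajectories: list[Trajectory] = []
    labels: list[int] = []
    ev = [schema.observation_names.index(e) for e in schema.event_channels]
    # the separation dial also blends the per-component feedback patterns, so
    # separation 0 leaves no component structure anywhere
    n = len(population)
    mean_drift = {
        key: float(np.mean([_ARCH_FEEDBACK[i % len(_ARCH_FEEDBACK)][key] for i in range(n)]))
        for key in ("bmi", "quit")
    }
    drifts = [
        {
            key: mean_drift[key]
            + config.separation
            * (_ARCH_FEEDBACK[i % len(_ARCH_FEEDBACK)][key] - mean_drift[key])
            for key in ("bmi", "quit")
        }
        for i in range(n)
    ]
    for c, params in enumerate(population):
        for s in range(config.subjects_per_component):
            L = int(rng.integers(lmin, lmax + 1))
            sid = f"c{c}_s{s}"
            for _ in range(1000):
                if config.risk_feedback > 0.0:
                    traj = _sample_with_feedback(
                        params, config.covariate_chains, L, config.risk_feedback,
                        drifts[c], rng, sid,
                    )
                else:
                    cov = sample_covariate_path(config.covariate_chains, schema, L, rng)
                    traj = sample_trajectory(params, cov, seed=rng, subject_id=sid)
                # population definition: the full sequential progression is
                # observed inside the window — every condition absent at
                # baseline, developed persistently (still present at the
                # end), onset no later than two steps before the end, and
                # the first and last onsets at least two steps apart
                # (simultaneous onsets carry no ordering signal, like
                # never-onsetting subjects)
                if not config.require_all_onsets:
                    break
                if all(
                    traj.observations[0, k] == 0
                    and traj.observations[-1, k] == 1
                    and (traj.observations[1:, k] == 1).any()
                    for k in ev
                ):
                    onsets = [
                        int(np.argmax(traj.observations[:, k] == 1)) for k in ev
                    ]
                    if max(onsets) - min(onsets) >= 2 and max(onsets) <= L - 3:
                        break
            else:
                raise RuntimeError(
                    "could not sample a trajectory with every condition onsetting; "
                    "progression rates too slow for the configured lengths"
                )
            trajectories.append(traj)
            labels.append(c)
    return trajectories, np.asarray(labels)


@dataclass
class ConfusionResult:
    """Hungarian-matched confusion matrix plus agreement scores."""

    table: pd.DataFrame
    accuracy: float
    ari: float
    mapping: dict[int, int]


def confusion_matrix(true_labels, predicted_labels) -> ConfusionResult:
    """Confusion matrix (rows = actual, columns = predicted) with predicted
    clusters relabeled by the accuracy-maximizing Hungarian assignment;
    reports best-matching accuracy and the adjusted Rand index."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    t_vals, t_inv = np.unique(true_labels, return_inverse=True)
    p_vals, p_inv = np.unique(predicted_labels, return_inverse=True)
    cont = np.zeros((t_vals.size, p_vals.size), dtype=np.int64)
    np.add.at(cont, (t_inv, p_inv), 1)
    # pad to square so every predicted cluster gets a column assignment
    K = max(t_vals.size, p_vals.size)
    padded = np.zeros((K, K), dtype=np.int64)
    padded[: t_vals.size, : p_vals.size] = cont
    row, col = linear_sum_assignment(-padded)
    order = [int(c) for _, c in sorted(zip(row, col))][: t_vals.size]
    # columns not matched to any actual class go last
    extra = [c for c in range(p_vals.size) if c not in order]
    col_order = [c for c in order if c < p_vals.size] + extra
    matched = cont[:, col_order]
    accuracy = float(padded[row, col].sum()) / float(true_labels.size)
    ari = float(adjusted_rand_score(true_labels, predicted_labels))
    table = pd.DataFrame(
        matched,
        index=[f"actual_{v}" for v in t_vals],
        columns=[f"predicted_{p_vals[c]}" for c in col_order],
    )
    mapping = {int(p_vals[c]): int(t_vals[i]) for i, c in enumerate(order) if c < p_vals.size}
    return ConfusionResult(table=table, accuracy=accuracy, ari=ari, mapping=mapping)
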