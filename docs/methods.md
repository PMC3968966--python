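# Methods

`trajclust` clusters multivariate categorical time series — health
trajectories — by embedding each series in a generative model and measuring
distances between the models rather than between the raw sequences.  This
note records the statistical model, the estimators, the numerical choices,
and what the synthetic benchmark does and does not establish.

## The embedding model

Each subject `i` contributes a trajectory `T_i`: aligned categorical series
over `d` observation channels (here binary chronic-disease indicators) and
`q` categorical covariate channels (BMI class, smoking status), of length
`L_i` (lengths may differ across subjects).  `T_i` is embedded in its own
hidden Markov model `λ_i` with `S` hidden states:

* initial state distribution `π = softmax(α)`;
* transition probabilities `P(z_t = s' | z_{t-1} = s, x_t) =
  softmax_{s'}(W_{s s'} · x_t)`, where `x_t` is the dummy-encoded covariate
  row at the destination time (intercept + one indicator per non-reference
  category);
* per-channel multinomial emissions, contemporaneously conditionally
  independent given the state: `P(y_t | z_t, x_t) = ∏_k
  softmax_c(E_{k, z_t c} · x_t)[y_{t k}]`.

For identifiability one reference cell per softmax row (state 0, category 0)
is pinned to zero.  Covariates enter transitions by default; emission
covariates are supported but off by default, since per-subject fits rarely
support the extra parameters.  The time step is abstract and units never
enter any computation.

`λ_i` is estimated by maximizing `P(T_i | λ_i)` with EM.  The E-step is the
standard forward–backward recursion, run entirely in log space with
log-sum-exp scaling.  The M-step:

* initial distribution and, when covariates are disabled,
  transition/emission tables have closed forms: posterior-weighted category
  frequencies, maximized over the *floor-truncated simplex*
  `{p : p_c ≥ ε, Σ p = 1}` (water-filling KKT solution).  The floor
  default is `ε = 0.01`: a single trajectory cannot estimate small
  probabilities, and an unfloored fit assigns vanishing mass to every
  symbol it did not happen to contain, which later turns model-to-model
  distances into outlier-dominated noise.  Using the exact constrained
  maximizer (not floor-and-renormalize) preserves the EM ascent guarantee.
* with covariates, transition rows (and optionally emissions) are
  posterior-weighted multinomial-logit fits, maximized by a few damped
  Newton steps per EM iteration (generalized EM).  Two stabilizers address
  the severe overparameterization of per-subject fits: a smoothing
  pseudo-weight of `ε` per (time, category) cell — the logit analogue of
  the probability floor — and an L2 ridge (default 1.0) on the covariate
  columns only.  Newton steps are accepted only if the *unpenalized*
  expected complete-data log-likelihood does not decrease, so the observed
  log-likelihood trace is monotone to machine precision regardless of the
  regularizers.

Restarts (default 5) are seeded from random contiguous segmentations of the
trajectory: segment proportions drawn from a Dirichlet, each state's
emissions initialized at its segment's category frequencies, transitions at
a sticky forward-leaning guess.  Health trajectories are broadly
progressive, and symmetric "uniform plus jitter" starts collapse the phase
structure often enough to produce degenerate fits; segment seeding is the
standard remedy for left-to-right-ish sequences.  The single-state model
uses a jittered uniform start (it has no phases).  Convergence: relative
log-likelihood improvement below `1e-6`, at most 200 iterations.  An
overfitting guard refuses fits whose free-parameter count exceeds
`5 · L · d`.

## Distances between trajectories

The dissimilarity between trajectories is the symmetrized Kullback–Leibler
divergence between their fitted models.  The trajectory-space KL integral is
intractable, so the package implements three estimators (all in nats):

* **empirical** (default): each model's likelihood column over the observed
  trajectory set `{P(T_1|λ), …, P(T_N|λ)}` is normalized (log-sum-exp) into
  a discrete distribution `P̃_λ` over the N observed trajectories, and the
  divergence is the ordinary discrete KL `Σ_i P̃_a(T_i) log[P̃_a(T_i) /
  P̃_b(T_i)]`.  It uses all the data but needs only the N×N likelihood
  matrix.  Trajectory lengths vary, so short trajectories (larger
  likelihoods) weigh more in `P̃`; this is inherent to the estimator and is
  left uncorrected, but `effective_sample_sizes` reports the ESS
  `1/Σ_i P̃(T_i)²` of each column as a diagnostic.
* **one-point**: `½[(ll_aa − ll_ab) + (ll_bb − ll_ba)]` from the four
  self/cross likelihoods; can be negative for pathological fits and is
  reported as-is.
* **Monte-Carlo**: mean log-likelihood ratio over trajectories sampled from
  the first model, with a standard error.  Covariates are exogenous, so
  each draw reuses a covariate path sampled uniformly from the observed
  dataset's paths — the sampling distribution of covariates is otherwise
  undefined.

The symmetrized empirical distance matrix is symmetric, has zero diagonal
and non-negative entries, but need not satisfy the triangle inequality.

## Clustering and model selection

PAM (Partitioning Around Medoids) runs from the deterministic greedy BUILD
seeding followed by best-improvement SWAP, plus seeded random restarts
(default 5); the lowest total cost wins and assignment ties break toward
the lowest medoid index.  The number of clusters is chosen by the Dunn
index (single-linkage separation over complete diameter), computed for each
K in the candidate range alongside the medoid-based Davies–Bouldin index
and the silhouette; ties break toward smaller K.  DB uses medoids in place
of centroids because only a dissimilarity matrix exists.  Classical
(Torgerson) MDS with negative eigenvalues clamped to zero provides
3-D coordinates for visualization.

Interpretation features per subject: fraction of the trajectory spent with
each condition; fractions of the pre-onset window (strictly before the
earliest onset) and of the post-onset window (at or after the latest first
onset, defined only when every condition onsets) spent in each non-reference
category of each risk-factor channel.  Empty windows yield missing values,
excluded from cluster means rather than imputed.  The number of hidden
states is selected by running the full pipeline for each candidate S and
choosing the S whose cluster mean-feature profiles have the lowest average
pairwise Pearson correlation — distinct profiles indicate the embedding
resolved genuinely different dynamics; ties break toward smaller S.

## The synthetic benchmark

No real cohort is distributed, so validation uses a seeded generator
producing datasets with known structure: four 3-state left-to-right
progression components (healthy → component-specific first-disease phase →
all-diseases phase) over the default schema.  Components differ in which
condition onsets first (heart / diabetes / stroke / heart + diabetes
together), in progression speed, and in their post-onset risk-factor drift
(weight loss vs gain, smoking-cessation propensity — the feedback hook,
strength 0.3 by default).  Emissions are near-deterministic given the state
(`P(present) = 0.999` in disease phases) and back-transitions are
numerically zero, so the disease channels are effectively absorbing.
Covariate paths follow shared first-order Markov chains (BMI persistent
with adjacent-class moves; smoking with quit and small relapse rates);
obesity and smoking add to the single-step progression logits.  A scalar
`separation` blends all component parameters (and drift patterns) toward
their mean: 0 yields an exchangeable null population, 1 the archetypes as
specified.

The sampled population is defined as subjects whose full sequential
progression is observed in-window: every condition absent at baseline,
developed persistently (still present at the end) no later than two steps
before the end, and first-to-last onset at least two steps apart.
Trajectories violating these (never-onsetting, already-sick-at-baseline,
simultaneous-onset) carry no ordering signal and are unclassifiable by
construction; rejection sampling enforces the definition.  Defaults: 30
subjects per component, lengths uniform on 10–20, seed-reproducible.

What passing the benchmark shows: the pipeline recovers cluster structure
and the generating state count when trajectories truly come from distinct
HMM components of this kind.  What it does not show: performance on real
cohorts, where emission noise is larger, components are not exact HMMs,
lengths may be informative (e.g. truncation at death), and covariates feed
back on disease far more richly.  The null control (separation 0) verifies
that the pipeline does not hallucinate structure: the adjusted Rand index
against the meaningless generator labels stays near zero.

## Problem sizes and determinism

The packaged validation experiment uses 4 × 30 subjects and S ∈ {2, 3, 4};
the null control uses 4 × 15 subjects over five seeds.  These sizes keep
the full suite to a few minutes while leaving the conclusions unchanged at
larger N (the estimators only improve with more subjects per component).
Every random draw — generator, EM restarts, PAM restarts, Monte-Carlo KL —
flows from explicit integer seeds through `numpy` `SeedSequence` spawning,
so every result in the test suite, the examples, and the acceptance script
is bit-reproducible.

## Known limitations

* Per-trajectory HMMs are only meaningful for trajectories long enough to
  visit their states; the overfitting guard is a crude control, and very
  short series (L < ~8 with three channels) should use fewer states.
* The empirical KL estimator inherits a length bias through `P̃`; datasets
  mixing very short and very long trajectories should check the ESS
  diagnostic.
* The Dunn index is a min/max statistic: a single anomalous trajectory can
  change the selected K.  The index table (with DB and silhouette) is
  always reported so that selection can be inspected rather than trusted
  blindly.
* Hidden-state selection by profile decorrelation requires features that
  can differ across clusters; if cluster structure is unrelated to every
  profiled feature, the criterion is uninformative.
* The margins of the state-selection criterion are intrinsically small:
  when an under- or over-parameterized embedding happens to induce (nearly)
  the same partition as the best one, the average profile correlations
  differ at the 0.01 level or tie exactly.  Exact ties are resolved by
  parsimony (the smaller state count).  The full per-S table is returned so
  that a thin margin is visible rather than hidden behind the argmin.
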