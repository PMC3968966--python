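"""Dataset schema and trajectory containers for categorical longitudinal data.

A dataset is a collection of per-subject multivariate categorical time series
("trajectories").  Each trajectory carries two aligned tables: *observations*
(the channels the hidden Markov model emits, e.g. disease indicators) and
*covariates* (exogenous categorical channels that modulate the model's
transition and, optionally, emission probabilities, e.g. BMI class or smoking
status).  The :class:`DatasetSchema` records channel names, ordered category
inventories and which observation channels are binary disease/event
indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SchemaError(ValueError):
    """Raised when a schema definition is internally inconsistent."""


class TrajectoryError(ValueError):
    """Raised when trajectory data violates its schema."""


Channel = tuple[str, tuple[str, ...]]


def _as_channels(channels) -> tuple[Channel, ...]:
    return tuple((str(name), tuple(str(c) for c in cats)) for name, cats in channels)


@dataclass(frozen=True)
class DatasetSchema:
    """Names, category inventories, and roles of all channels.

    Parameters
    ----------
    observation_channels
        Ordered ``(name, categories)`` pairs for the channels the HMM emits.
    covariate_channels
        Ordered ``(name, categories)`` pairs for exogenous conditioning
        channels.  May be empty.
    event_channels
        Names of observation channels that are binary event indicators with
        category order ``(absent, present)``.  Used for onset-based feature
        construction.
    """

    observation_channels: tuple[Channel, ...]
    covariate_channels: tuple[Channel, ...] = ()
    event_channels: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "observation_channels", _as_channels(self.observation_channels)
        )
        object.__setattr__(
            self, "covariate_channels", _as_channels(self.covariate_channels)
        )
        object.__setattr__(
            self, "event_channels", tuple(str(n) for n in self.event_channels)
        )
        names = [n for n, _ in self.observation_channels] + [
            n for n, _ in self.covariate_channels
        ]
        if len(set(names)) != len(names):
            raise SchemaError("channel names must be unique across all channels")
        if not self.observation_channels:
            raise SchemaError("at least one observation channel is required")
        for name, cats in self.observation_channels + self.covariate_channels:
            if len(cats) < 2:
                raise SchemaError(f"channel {name!r} needs >=2 categories")
            if len(set(cats)) != len(cats):
                raise SchemaError(f"channel {name!r} has duplicate categories")
        obs_names = {n for n, _ in self.observation_channels}
        for ev in self.event_channels:
            if ev not in obs_names:
                raise SchemaError(f"event channel {ev!r} is not an observation channel")
            cats = dict(self.observation_channels)[ev]
            if len(cats) != 2:
                raise SchemaError(f"event channel {ev!r} must be binary")

    # ------------------------------------------------------------------ views
    @property
    def observation_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.observation_channels)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.covariate_channels)

    @property
    def observation_cardinalities(self) -> tuple[int, ...]:
        return tuple(len(c) for _, c in self.observation_channels)

    @property
    def covariate_cardinalities(self) -> tuple[int, ...]:
        return tuple(len(c) for _, c in self.covariate_channels)

    @property
    def n_observation_channels(self) -> int:
        return len(self.observation_channels)

    @property
    def n_covariate_channels(self) -> int:
        return len(self.covariate_channels)

    @property
    def design_dim(self) -> int:
        """Length of the encoded covariate regressor row (intercept + dummies).

        Each categorical covariate with ``C`` categories contributes ``C - 1``
        dummy regressors (first category is the reference).
        """
        return 1 + sum(c - 1 for c in self.covariate_cardinalities)

    # -------------------------------------------------------------- encoding
    def encode_covariates(self, covariates: np.ndarray) -> np.ndarray:
        """Dummy-encode an ``(L, q)`` integer covariate table to ``(L, 1+p)``.

        Column 0 is the intercept; each covariate contributes one 0/1 column
        per non-reference category, in schema order.
        """
        covariates = np.asarray(covariates)
        if covariates.ndim == 1:
            covariates = covariates[None, :]
        L = covariates.shape[0]
        q = self.n_covariate_channels
        if covariates.shape[1] != q:
            raise TrajectoryError(
                f"expected {q} covariate columns, got {covariates.shape[1]}"
            )
        X = np.zeros((L, self.design_dim))
        X[:, 0] = 1.0
        col = 1
        for j, card in enumerate(self.covariate_cardinalities):
            vals = covariates[:, j]
            if (vals < 0).any() or (vals >= card).any():
                raise TrajectoryError(
                    f"covariate {self.covariate_names[j]!r} index out of range"
                )
            for c in range(1, card):
                X[:, col] = vals == c
                col += 1
        return X

    def encode_covariate_row(self, row) -> np.ndarray:
        """Encode a single length-``q`` covariate category row to ``(1+p,)``."""
        return self.encode_covariates(np.asarray(row)[None, :])[0]

    def design_column_names(self) -> list[str]:
        names = ["intercept"]
        for (name, cats) in self.covariate_channels:
            names.extend(f"{name}={c}" for c in cats[1:])
        return names


@dataclass(frozen=True)
class Trajectory:
    """One subject's aligned categorical observation and covariate series.

    ``observations`` is an ``(L, d)`` integer array of category indices (one
    column per observation channel); ``covariates`` is ``(L, q)``.  The time
    index is implicitly ``0..L-1`` with no gaps.
    """

    subject_id: str
    observations: np.ndarray
    covariates: np.ndarray = field(default=None)

    def __post_init__(self):
        obs = np.atleast_2d(np.asarray(self.observations, dtype=np.int64))
        object.__setattr__(self, "observations", obs)
        cov = self.covariates
        if cov is None:
            cov = np.zeros((obs.shape[0], 0), dtype=np.int64)
        cov = np.asarray(cov, dtype=np.int64)
        if cov.ndim == 1:
            cov = cov.reshape(obs.shape[0], -1)
        object.__setattr__(self, "covariates", cov)
        if obs.shape[0] < 1:
            raise TrajectoryError(f"subject {self.subject_id!r}: length must be >= 1")
        if cov.shape[0] != obs.shape[0]:
            raise TrajectoryError(
                f"subject {self.subject_id!r}: observation and covariate "
                "tables differ in length"
            )

    @property
    def length(self) -> int:
        return self.observations.shape[0]

    def validate(self, schema: DatasetSchema) -> None:
        """Check category indices and column counts against *schema*."""
        if self.observations.shape[1] != schema.n_observation_channels:
            raise TrajectoryError(
                f"subject {self.subject_id!r}: expected "
                f"{schema.n_observation_channels} observation columns, got "
                f"{self.observations.shape[1]}"
            )
        if self.covariates.shape[1] != schema.n_covariate_channels:
            raise TrajectoryError(
                f"subject {self.subject_id!r}: expected "
                f"{schema.n_covariate_channels} covariate columns, got "
                f"{self.covariates.shape[1]}"
            )
        for k, card in enumerate(schema.observation_cardinalities):
            col = self.observations[:, k]
            if (col < 0).any() or (col >= card).any():
                raise TrajectoryError(
                    f"subject {self.subject_id!r}: observation channel "
                    f"{schema.observation_names[k]!r} index out of range"
                )
        for k, card in enumerate(schema.covariate_cardinalities):
            col = self.covariates[:, k]
            if (col < 0).any() or (col >= card).any():
                raise TrajectoryError(
                    f"subject {self.subject_id!r}: covariate channel "
                    f"{schema.covariate_names[k]!r} index out of range"
                )


def default_health_schema() -> DatasetSchema:
    """Schema of the reference health-trajectory dataset shape.

    Three binary chronic-disease indicators (heart disease, diabetes, stroke),
    all flagged as event channels, plus a 4-category BMI class and a
    3-category smoking-status covariate.
    """
    return DatasetSchema(
        observation_channels=(
            ("heart_disease", ("absent", "present")),
            ("diabetes", ("absent", "present")),
            ("stroke", ("absent", "present")),
        ),
        covariate_channels=(
            ("bmi", ("underweight", "normal", "overweight", "obese")),
            ("smoking", ("not_smoking", "smoking", "quit_smoking")),
        ),
        event_channels=("heart_disease", "diabetes", "stroke"),
    )
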