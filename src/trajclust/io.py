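"""Reading and writing the pipeline's plain-text formats.

Trajectories travel as long-format CSV (one row per subject-time step,
category values as labels); likelihood and distance matrices as square CSV
with the subject ids as header row and index column, full double precision.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, LikelihoodMatrix
from .schema import DatasetSchema, Trajectory, TrajectoryError

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "trajectories_to_frame",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_likelihood_matrix",
    "read_likelihood_matrix",
    "schema_to_dict",
    "schema_from_dict",
]

def trajectories_to_frame(
    trajectories: list[Trajectory], schema: DatasetSchema
) -> pd.DataFrame:
    rows = []
    for traj in trajectories:
        traj.validate(schema)
        for t in range(traj.length):
            row = {"subject_id": traj.subject_id, "t": t}
            for k, (name, cats) in enumerate(schema.observation_channels):
                row[name] = cats[traj.observations[t, k]]
            for j, (name, cats) in enumerate(schema.covariate_channels):
                row[name] = cats[traj.covariates[t, j]]
            rows.append(row)
    return pd.DataFrame(rows)


def write_trajectories(
    trajectories: list[Trajectory], schema: DatasetSchema, path
) -> None:
    trajectories_to_frame(trajectories, schema).to_csv(path, index=False)


def read_trajectories(path, schema: DatasetSchema) -> list[Trajectory]:
    """Parse a long-format trajectory CSV, validating time contiguity and
    category labels.  Errors name the offending subject and row."""
    df = pd.read_csv(path, dtype=str)
    required = ["subject_id", "t"] + list(schema.observation_names) + list(
        schema.covariate_names
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryError(f"missing columns: {missing}")
    df["t"] = df["t"].astype(int)
    obs_maps = [
        {c: i for i, c in enumerate(cats)} for _, cats in schema.observation_channels
    ]
    cov_maps = [
        {c: i for i, c in enumerate(cats)} for _, cats in schema.covariate_channels
    ]
    out: list[Trajectory] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("t")
        tvals = grp["t"].to_numpy()
        expected = np.arange(len(tvals))
        if not np.array_equal(tvals, expected):
            raise TrajectoryError(
                f"subject {sid!r}: time index must be contiguous from 0, got "
                f"{tvals.tolist()}"
            )
        obs = np.zeros((len(grp), schema.n_observation_channels), dtype=np.int64)
        cov = np.zeros((len(grp), schema.n_covariate_channels), dtype=np.int64)
        for k, name in enumerate(schema.observation_names):
            for r, (ridx, v) in enumerate(zip(grp.index, grp[name])):
                if v not in obs_maps[k]:
                    raise TrajectoryError(
                        f"subject {sid!r}, row {ridx}: unknown category {v!r} "
                        f"for channel {name!r}"
                    )
                obs[r, k] = obs_maps[k][v]
        for j, name in enumerate(schema.covariate_names):
            for r, (ridx, v) in enumerate(zip(grp.index, grp[name])):
                if v not in cov_maps[j]:
                    raise TrajectoryError(
                        f"subject {sid!r}, row {ridx}: unknown category {v!r} "
                        f"for channel {name!r}"
                    )
                cov[r, j] = cov_maps[j][v]
        traj = Trajectory(subject_id=str(sid), observations=obs, covariates=cov)
        traj.validate(schema)
        out.append(traj)
    return out


def _write_square(values: np.ndarray, subject_ids, path) -> None:
    # pandas' default float repr is shortest-round-trip: full precision
    pd.DataFrame(values, index=list(subject_ids), columns=list(subject_ids)).to_csv(path)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    _write_square(dist.values, dist.subject_ids, path)


def read_distance_matrix(path, method: str = "empirical") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return DistanceMatrix(
        values=df.to_numpy(dtype=float),
        method=method,
        subject_ids=tuple(str(c) for c in df.columns),
    )


def write_likelihood_matrix(lm: LikelihoodMatrix, path) -> None:
    _write_square(lm.loglik, lm.subject_ids, path)


def read_likelihood_matrix(path) -> LikelihoodMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return LikelihoodMatrix(
        loglik=df.to_numpy(dtype=float),
        subject_ids=tuple(str(c) for c in df.columns),
    )


def schema_to_dict(schema: DatasetSchema) -> dict:
    return {
        "observation_channels": [
            {"name": n, "categories": list(c)} for n, c in schema.observation_channels
        ],
        "covariate_channels": [
            {"name": n, "categories": list(c)} for n, c in schema.covariate_channels
        ],
        "event_channels": list(schema.event_channels),
    }


def schema_from_dict(d: dict) -> DatasetSchema:
    return DatasetSchema(
        observation_channels=tuple(
            (ch["name"], tuple(ch["categories"])) for ch in d["observation_channels"]
        ),
        covariate_channels=tuple(
            (ch["name"], tuple(ch["categories"]))
            for ch in d.get("covariate_channels", [])
        ),
        event_channels=tuple(d.get("event_channels", [])),
    )
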