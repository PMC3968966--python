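"""Static plots: cluster feature-profile lines and MDS scatter."""

from __future__ import annotations

import numpy as np

from .features import FeatureProfile

__all__ = ["plot_cluster_profiles", "plot_mds"]


def plot_cluster_profiles(profile: FeatureProfile, ax=None, path=None):
    """Line plot of per-cluster mean feature profiles.

    Feature names run along the x axis; one colored line per cluster.
    Returns the matplotlib axes; writes a PNG when *path* is given.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.7 * len(profile.feature_names)), 4))
    x = np.arange(len(profile.per_cluster.columns))
    for cluster, row in profile.per_cluster.iterrows():
        ax.plot(x, row.to_numpy(), marker="o", label=f"cluster {cluster}")
    ax.set_xticks(x)
    ax.set_xticklabels(profile.per_cluster.columns, rotation=60, ha="right")
    ax.set_ylabel("cluster mean feature value")
    ax.legend()
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=120)
    return ax


def plot_mds(coordinates: np.ndarray, labels=None, ax=None, path=None):
    """2-D scatter of (the first two) MDS coordinates, colored by cluster."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    coordinates = np.asarray(coordinates)
    if coordinates.ndim != 2 or coordinates.shape[1] < 2:
        raise ValueError("need at least two embedding dimensions")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(
        coordinates[:, 0],
        coordinates[:, 1],
        c=None if labels is None else np.asarray(labels),
        cmap="tab10",
        s=25,
    )
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.figure.tight_layout()
    if path is not None:
        ax.figure.savefig(path, dpi=120)
    return ax
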