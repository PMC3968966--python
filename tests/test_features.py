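"""Tests for trajectory features, cluster profiles, and state selection."""

import numpy as np
import pandas as pd
import pytest

from trajclust.features import (
    FeatureProfile,
    average_profile_correlation,
    cluster_feature_profiles,
    compute_feature_matrix,
    compute_trajectory_features,
    feature_names,
)
from trajclust.schema import DatasetSchema, Trajectory, default_health_schema


def _health_traj(rows, cov_rows, sid="s"):
    return Trajectory(sid, np.asarray(rows), np.asarray(cov_rows))


@pytest.fixture
def schema():
    return default_health_schema()


class TestTrajectoryFeatures:
    def test_time_with_condition(self, schema):
        # condition 0 present at steps 4..9 of 10 -> 0.6
        obs = np.zeros((10, 3), dtype=int)
        obs[4:, 0] = 1
        obs[5:, 1] = 1
        obs[6:, 2] = 1
        cov = np.zeros((10, 2), dtype=int)
        vals = compute_trajectory_features(_health_traj(obs, cov), schema)
        names = feature_names(schema)
        assert vals[names.index("time_with_heart_disease")] == pytest.approx(0.6)
        assert vals[names.index("time_with_diabetes")] == pytest.approx(0.5)

    def test_pre_onset_window_fractions(self, schema):
        # BMI normal for both pre-onset steps; first onset at step 2
        obs = np.zeros((4, 3), dtype=int)
        obs[2:, :] = 1
        cov = np.array([[1, 0], [1, 0], [2, 0], [3, 0]])
        vals = compute_trajectory_features(_health_traj(obs, cov), schema)
        names = feature_names(schema)
        assert vals[names.index("bmi=normal_before_first_onset")] == pytest.approx(1.0)
        assert vals[names.index("bmi=overweight_before_first_onset")] == pytest.approx(0.0)

    def test_missing_when_condition_never_onsets(self, schema):
        obs = np.zeros((6, 3), dtype=int)
        obs[2:, 0] = 1
        obs[3:, 1] = 1  # stroke never onsets
        cov = np.zeros((6, 2), dtype=int)
        vals = compute_trajectory_features(_health_traj(obs, cov), schema)
        names = feature_names(schema)
        after = [v for n, v in zip(names, vals) if n.endswith("after_last_onset")]
        assert all(np.isnan(after))
        before = vals[names.index("bmi=normal_before_first_onset")]
        assert not np.isnan(before)

    def test_zero_length_pre_window_missing(self, schema):
        obs = np.ones((5, 3), dtype=int)  # onset at step 0
        cov = np.zeros((5, 2), dtype=int)
        vals = compute_trajectory_features(_health_traj(obs, cov), schema)
        names = feature_names(schema)
        before = [v for n, v in zip(names, vals) if n.endswith("before_first_onset")]
        assert all(np.isnan(before))

    def test_window_fractions_sum_to_one_with_reference(self, schema):
        rng = np.random.default_rng(0)
        obs = np.zeros((8, 3), dtype=int)
        obs[3:, :] = 1
        cov = np.column_stack([rng.integers(0, 4, 8), rng.integers(0, 3, 8)])
        vals = compute_trajectory_features(_health_traj(obs, cov), schema)
        names = feature_names(schema)
        # non-reference BMI fractions + (unreported) reference = 1
        pre_bmi = sum(
            vals[names.index(f"bmi={c}_before_first_onset")]
            for c in ("normal", "overweight", "obese")
        )
        ref = np.mean(cov[:3, 0] == 0)
        assert pre_bmi + ref == pytest.approx(1.0)

    def test_no_event_channels_warns(self):
        plain = DatasetSchema(observation_channels=(("x", ("a", "b")),))
        traj = Trajectory("s", np.zeros((3, 1), dtype=int))
        with pytest.warns(UserWarning):
            vals = compute_trajectory_features(traj, plain)
        assert vals.size == 0 or not np.isnan(vals).all()


class TestClusterProfiles:
    def test_mean_profile(self):
        df = pd.DataFrame([[0.2, 0.4], [0.6, 0.8]], columns=["f1", "f2"])
        prof = cluster_feature_profiles(df, [0, 0])
        assert np.allclose(prof.per_cluster.loc[0], [0.4, 0.6])

    def test_missing_excluded_from_means(self):
        df = pd.DataFrame(
            [[0.2, np.nan], [0.6, 0.5], [1.0, np.nan]], columns=["f1", "f2"]
        )
        prof = cluster_feature_profiles(df, [0, 0, 0])
        assert prof.per_cluster.loc[0, "f1"] == pytest.approx(0.6)
        assert prof.per_cluster.loc[0, "f2"] == pytest.approx(0.5)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((10, 4)))
        labels = rng.integers(0, 2, 10)
        p1 = cluster_feature_profiles(df, labels).per_cluster
        perm = rng.permutation(10)
        p2 = cluster_feature_profiles(df.iloc[perm], labels[perm]).per_cluster
        assert np.allclose(p1.to_numpy(), p2.to_numpy())


class TestProfileCorrelation:
    def _profile(self, rows):
        df = pd.DataFrame(rows)
        return FeatureProfile(
            feature_names=list(df.columns),
            per_subject=df,
            per_cluster=df,
        )

    def test_anti_linear_profiles(self):
        prof = self._profile([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert average_profile_correlation(prof) == pytest.approx(-1.0)

    def test_identical_profiles(self):
        prof = self._profile([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert average_profile_correlation(prof) == pytest.approx(1.0)

    def test_three_cluster_hand_computation(self):
        rows = np.array(
            [[0.1, 0.5, 0.9, 0.3], [0.2, 0.4, 0.8, 0.1], [0.9, 0.2, 0.1, 0.7]]
        )
        prof = self._profile(rows)
        ref = np.mean(
            [
                np.corrcoef(rows[a], rows[b])[0, 1]
                for a, b in [(0, 1), (0, 2), (1, 2)]
            ]
        )
        assert average_profile_correlation(prof) == pytest.approx(ref, abs=1e-12)

    def test_affine_feature_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        rows = rng.random((3, 5))
        prof = self._profile(rows)
        scaled = rows.copy()
        scaled[:, 2] = 10.0 * scaled[:, 2] - 4.0  # same feature across clusters
        prof2 = self._profile(scaled)
        # correlation is NOT invariant feature-wise in general; it is
        # invariant when the whole profile is rescaled
        prof3 = self._profile(2.5 * rows + 1.0)
        assert average_profile_correlation(prof) == pytest.approx(
            average_profile_correlation(prof3), abs=1e-12
        )

    def test_zero_variance_signalled(self):
        prof = self._profile([[1.0, 1.0, 1.0], [0.1, 0.5, 0.9]])
        with pytest.raises(ValueError, match="zero-variance"):
            average_profile_correlation(prof)

    def test_too_few_shared_features(self):
        prof = self._profile(
            [[1.0, np.nan, 3.0, np.nan], [2.0, 1.0, np.nan, np.nan]]
        )
        with pytest.raises(ValueError, match="defined features"):
            average_profile_correlation(prof)


def test_feature_matrix_min_support_drops_rare_categories(schema):
    rng = np.random.default_rng(3)
    trajs = []
    for i in range(6):
        obs = np.zeros((8, 3), dtype=int)
        obs[3:, :] = 1
        cov = np.column_stack(
            [rng.integers(1, 4, 8), rng.integers(0, 2, 8)]
        )  # BMI never underweight, smoking never quit
        trajs.append(Trajectory(f"s{i}", obs, cov))
    df = compute_feature_matrix(trajs, schema, min_support=0.05)
    assert not any("quit_smoking" in c for c in df.columns)
    assert any("bmi=normal" in c for c in df.columns)


def test_profile_and_mds_plots_render(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    import pandas as pd

    from trajclust.cluster import classical_mds
    from trajclust.features import FeatureProfile
    from trajclust.plots import plot_cluster_profiles, plot_mds

    df = pd.DataFrame(
        [[0.1, 0.5, 0.9], [0.8, 0.4, 0.2]], columns=["f1", "f2", "f3"]
    )
    prof = FeatureProfile(feature_names=list(df.columns), per_subject=df, per_cluster=df)
    plot_cluster_profiles(prof, path=tmp_path / "profiles.png")
    pts = np.array([0.0, 1.0, 3.0, 7.0])
    D = np.abs(pts[:, None] - pts[None, :])
    coords = classical_mds(D, dims=2)
    plot_mds(coords, labels=[0, 0, 1, 1], path=tmp_path / "mds.png")
    assert (tmp_path / "profiles.png").stat().st_size > 0
    assert (tmp_path / "mds.png").stat().st_size > 0
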