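"""QSep, marker summaries and PCA coordinates."""

import numpy as np
import pandas as pd
import pytest

from dialop import SpatialDataset, ValidationError, marker_profile_summary, pca_map, qsep


def dataset_from_blocks(blocks, labels=None):
    """Stack per-class coordinate blocks into a marker-annotated dataset."""
    rows, markers = [], {}
    for cls, block in blocks.items():
        for i, row in enumerate(np.atleast_2d(block)):
            name = f"{cls}{i}"
            rows.append(pd.Series(row, name=name))
            markers[name] = cls
    profiles = pd.DataFrame(rows)
    profiles.columns = [f"rep1_frac{j + 1:02d}" for j in range(profiles.shape[1])]
    if labels is not None:
        markers = {k: v for k, v in markers.items() if k in labels}
    return SpatialDataset(profiles, pd.Series(markers))


def brute_force_qsep(dataset):
    """Independent double-loop computation of the raw QSep matrix."""
    markers = dataset.markers
    classes = sorted(markers.unique())
    raw = pd.DataFrame(0.0, index=classes, columns=classes)
    for ci in classes:
        for cj in classes:
            xi = dataset.profiles.loc[markers.index[markers == ci]].to_numpy()
            xj = dataset.profiles.loc[markers.index[markers == cj]].to_numpy()
            dists = []
            for a in range(len(xi)):
                for b in range(len(xj)):
                    if ci == cj and a == b:
                        continue
                    dists.append(np.linalg.norm(xi[a] - xj[b]))
            raw.loc[ci, cj] = np.mean(dists)
    return raw


class TestQsep:
    def test_two_cluster_hand_computation(self):
        ds = dataset_from_blocks(
            {"A": [(0, 0), (0, 1)], "B": [(10, 0), (10, 1)]}
        )
        report = qsep(ds)
        cross = (10 + np.sqrt(101) + np.sqrt(101) + 10) / 4
        assert report.raw.loc["A", "A"] == pytest.approx(1.0)
        assert report.raw.loc["A", "B"] == pytest.approx(cross)
        assert report.normalized.loc["A", "B"] == pytest.approx(cross)
        assert np.allclose(np.diag(report.normalized), 1.0)

    def test_coincident_clusters_show_no_separation(self):
        rng = np.random.default_rng(0)
        report = qsep(
            dataset_from_blocks(
                {"A": rng.normal(0, 1, (40, 3)), "B": rng.normal(0, 1, (40, 3))}
            )
        )
        # clusters drawn from the same distribution: between ~ within
        assert report.normalized.loc["A", "B"] == pytest.approx(1.0, abs=0.1)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(12)
        blocks = {
            cls: rng.normal(loc, 1.0, (7, 5))
            for cls, loc in [("A", 0), ("B", 3), ("C", -2), ("D", 6)]
        }
        ds = dataset_from_blocks(blocks)
        report = qsep(ds)
        brute = brute_force_qsep(ds)
        assert np.allclose(report.raw.to_numpy(), brute.to_numpy())
        assert np.allclose(
            report.normalized.to_numpy(),
            brute.to_numpy() / np.diag(brute)[:, None],
        )

    def test_scale_invariance_of_normalized_matrix(self):
        rng = np.random.default_rng(4)
        blocks = {"A": rng.normal(0, 1, (5, 4)), "B": rng.normal(5, 1, (5, 4))}
        ds = dataset_from_blocks(blocks)
        scaled = SpatialDataset(ds.profiles * 37.5, ds.markers)
        r1, r2 = qsep(ds), qsep(scaled)
        assert np.allclose(r2.raw.to_numpy(), 37.5 * r1.raw.to_numpy())
        assert np.allclose(r2.normalized.to_numpy(), r1.normalized.to_numpy())

    def test_singleton_cluster_is_named(self):
        ds = dataset_from_blocks({"A": [(0, 0), (0, 1)], "lonely": [(5, 5)]})
        with pytest.raises(ValidationError, match="lonely"):
            qsep(ds)

    def test_separation_grows_with_centroid_distance(self):
        rng = np.random.default_rng(9)
        spread = rng.normal(0, 0.5, (6, 4))
        values = []
        for shift in (2.0, 4.0, 8.0):
            ds = dataset_from_blocks({"A": spread, "B": spread + shift})
            values.append(qsep(ds).normalized.loc["A", "B"])
        assert values[0] < values[1] < values[2]


class TestMarkerSummary:
    def test_median_and_se_hand_values(self):
        ds = dataset_from_blocks({"A": [[0.1], [0.2], [0.9]]})
        medians, se = marker_profile_summary(ds)
        assert medians.loc["A"].iloc[0] == pytest.approx(0.2)
        expected_se = np.std([0.1, 0.2, 0.9], ddof=1) / np.sqrt(3)
        assert se.loc["A"].iloc[0] == pytest.approx(expected_se)

    def test_single_member_class_has_zero_se(self):
        ds = dataset_from_blocks({"A": [[0.3, 0.7]]})
        medians, se = marker_profile_summary(ds)
        assert medians.loc["A"].tolist() == [0.3, 0.7]
        assert (se.loc["A"] == 0.0).all()


@pytest.fixture(scope="module")
def dataset():
    rng = np.random.default_rng(21)
    profiles = pd.DataFrame(
        rng.lognormal(0, 0.5, (60, 5)), index=[f"p{i}" for i in range(60)]
    )
    profiles.columns = [f"rep1_frac{j + 1:02d}" for j in range(5)]
    return SpatialDataset(profiles)


class TestPcaMap:
    def test_zero_trim_flags_nothing(self, dataset):
        result = pca_map(dataset, trim_frac=0.0)
        assert not result.outliers.any()

    def test_trim_flags_extreme_tails_only(self, dataset):
        result = pca_map(dataset, trim_frac=0.02)  # ceil(60*0.02) = 2 per tail
        assert result.outliers.sum() <= 8
        pc1 = result.coords["PC1"].sort_values()
        assert result.outliers[pc1.index[0]] and result.outliers[pc1.index[-1]]
        assert len(result.coords) == len(dataset.profiles)  # never deleted

    def test_two_column_dataset_fully_explained(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(rng.random((30, 2)), columns=["rep1_frac01", "rep1_frac02"])
        profiles.index = [f"p{i}" for i in range(30)]
        result = pca_map(SpatialDataset(profiles))
        assert result.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_sign_convention_makes_runs_identical(self, dataset):
        a = pca_map(dataset)
        b = pca_map(dataset)
        pd.testing.assert_frame_equal(a.coords, b.coords)
        assert np.allclose(a.explained_variance_ratio, b.explained_variance_ratio)

    def test_full_rank_reconstruction(self, dataset):
        from sklearn.decomposition import PCA

        x = dataset.profiles.to_numpy()
        model = PCA(n_components=min(x.shape), svd_solver="full")
        coords = model.fit_transform(x)
        back = model.inverse_transform(coords)
        assert np.abs(back - x).max() < 1e-8
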