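"""LC/MS feature-table bookkeeping: filtering, zones, matrices, PCA, k-means."""

import numpy as np
import pandas as pd
import pytest

from osmactools.lcms_profiles import (
    LOG_FLOOR,
    Peak,
    PeakTable,
    ProfileMatrix,
    ZoneConfig,
    build_profile_matrix,
    filter_noise,
    kmeans_profiles,
    pca_profiles,
    read_peak_tables,
    write_peak_tables,
    zone_summary,
)
from osmactools.synthetic_data import ConditionSpec, gen_peak_tables


def table(sample, specs):
    """specs: iterable of (feature_id, rt, area)."""
    return PeakTable(sample, [Peak(f, rt, a) for f, rt, a in specs])


class TestNoiseFilter:
    def test_sub_threshold_peak_removed(self):
        t = table("s", [("a", 10, 99.0), ("b", 20, 0.5)])
        out = filter_noise(t)
        assert [p.feature_id for p in out.peaks] == ["a"]

    def test_all_above_threshold_unchanged(self):
        t = table("s", [("a", 10, 60.0), ("b", 20, 40.0)])
        assert filter_noise(t) == t

    def test_exactly_one_percent_kept(self):
        t = table("s", [("a", 10, 99.0), ("b", 20, 1.0)])
        out = filter_noise(t)
        assert [p.feature_id for p in out.peaks] == ["a", "b"]

    def test_relative_areas_use_prefilter_total(self):
        # three tiny peaks at 0.9% each: all removed even though after
        # removing one the survivors would clear 1% of the reduced total
        t = table("s", [("big", 10, 97.3), ("x", 20, 0.9), ("y", 30, 0.9), ("z", 40, 0.9)])
        out = filter_noise(t)
        assert [p.feature_id for p in out.peaks] == ["big"]

    def test_empty_table_warns(self):
        with pytest.warns(UserWarning):
            out = filter_noise(PeakTable("s", []))
        assert out.peaks == ()


class TestZones:
    def test_one_peak_per_zone(self):
        t = table("s", [("a", 10, 1.0), ("b", 25, 2.0), ("c", 45, 3.0)])
        df = zone_summary(t)
        assert df.loc["high_polarity", "n_peaks"] == 1
        assert df.loc["middle_polarity", "n_peaks"] == 1
        assert df.loc["low_polarity", "n_peaks"] == 1
        assert df.loc["pre_gradient", "n_peaks"] == 0

    def test_boundary_assigned_upward(self):
        df = zone_summary(table("s", [("a", 21.0, 1.0)]))
        assert df.loc["middle_polarity", "n_peaks"] == 1

    def test_pre_gradient_bucket(self):
        df = zone_summary(table("s", [("a", 5.0, 2.0)]))
        assert df.loc["pre_gradient", "total_area"] == 2.0

    def test_empty_table_all_zero(self):
        df = zone_summary(PeakTable("s", []))
        assert (df["n_peaks"] == 0).all()
        assert (df["total_area"] == 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_of_counts_and_areas(self, seed):
        rng = np.random.default_rng(seed)
        t = table(
            "s",
            [
                (f"f{i}", float(rng.uniform(0, 60)), float(rng.uniform(0, 100)))
                for i in range(40)
            ],
        )
        df = zone_summary(t)
        assert df["n_peaks"].sum() == len(t.peaks)
        assert df["total_area"].sum() == pytest.approx(t.total_area)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ZoneConfig(boundaries=(9.0, 9.0, 39.0))


class TestProfileMatrix:
    def test_single_peak_is_unit_cell(self):
        pm = build_profile_matrix([table("s", [("a", 10, 42.0)])])
        assert np.allclose(pm.relative_areas.values, [[1.0]])
        assert np.allclose(pm.log10().values, [[0.0]])

    def test_equal_split_and_log(self):
        pm = build_profile_matrix([table("s", [("a", 10, 5.0), ("b", 20, 5.0)])])
        assert np.allclose(pm.relative_areas.values, [[0.5, 0.5]])
        assert np.allclose(pm.log10().values, [[-0.30103, -0.30103]], atol=1e-5)

    def test_absent_feature_sits_at_floor(self):
        pm = build_profile_matrix(
            [table("A", [("x", 10, 1.0), ("y", 20, 1.0)]), table("B", [("x", 10, 3.0)])]
        )
        assert pm.relative_areas.loc["B", "y"] == 0.0
        assert pm.log10().loc["B", "y"] == LOG_FLOOR

    def test_rows_sum_to_one(self):
        tables = gen_peak_tables(ConditionSpec(seed=4))
        pm = build_profile_matrix(tables)
        assert pm.relative_areas.sum(axis=1).values == pytest.approx(
            np.ones(len(tables))
        )

    def test_unlabeled_peaks_matched_by_rt(self):
        a = PeakTable("A", [Peak("", 10.00, 5.0, mz=300.0)])
        b = PeakTable("B", [Peak("", 10.05, 7.0, mz=300.001)])
        pm = build_profile_matrix([a, b], align_tolerance=(0.2, 10.0))
        assert pm.relative_areas.shape == (2, 1)
        assert (pm.relative_areas.values == 1.0).all()

    def test_unlabeled_peaks_outside_tolerance_split(self):
        a = PeakTable("A", [Peak("", 10.0, 5.0)])
        b = PeakTable("B", [Peak("", 11.0, 7.0)])
        pm = build_profile_matrix([a, b], align_tolerance=(0.2, 10.0))
        assert pm.relative_areas.shape == (2, 2)


class TestPCA:
    def test_rank_one_matrix_explained_by_single_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        data = pd.DataFrame(np.outer([1.0, 2.0, 3.0], base))
        scores, evr = pca_profiles(data, n_components=2)
        assert evr[0] == pytest.approx(1.0)
        assert evr[1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_samples_coincide(self):
        data = pd.DataFrame(
            [[1.0, 0.0, 2.0], [1.0, 0.0, 2.0], [0.0, 3.0, 1.0], [2.0, 1.0, 0.0]]
        )
        scores, _ = pca_profiles(data, n_components=2)
        assert scores.iloc[0].values == pytest.approx(scores.iloc[1].values)

    def test_explained_variance_matches_eigendecomposition(self):
        """Oracle: eigenvalues of the sample covariance of 2-factor data."""
        rng = np.random.default_rng(0)
        n, p = 40, 8
        factors = rng.normal(size=(n, 2))
        loadings = rng.normal(size=(2, p)) * [[3.0], [1.5]]
        data = pd.DataFrame(factors @ loadings + 0.05 * rng.normal(size=(n, p)))
        _, evr = pca_profiles(data, n_components=4)
        cov = np.cov(data.to_numpy(), rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig / eig.sum()
        assert evr == pytest.approx(expected[:4], rel=1e-8)
        assert np.all(np.diff(evr) <= 1e-12)  # non-increasing

    def test_translation_invariance_of_scores(self):
        data = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 5)))
        shifted = data + 7.5
        s1, _ = pca_profiles(data, n_components=2)
        s2, _ = pca_profiles(shifted, n_components=2)
        assert np.allclose(np.abs(s1.values), np.abs(s2.values), atol=1e-9)

    def test_too_many_components_rejected(self):
        data = pd.DataFrame(np.zeros((3, 5)))
        with pytest.raises(ValueError):
            pca_profiles(data, n_components=3)


class TestKMeans:
    def test_single_cluster(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        assert (kmeans_profiles(X, k=1) == 0).all()

    def test_separated_clouds_partitioned_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.1, size=(4, 2))
        b = rng.normal(50.0, 0.1, size=(3, 2))
        labels = kmeans_profiles(np.vstack([a, b]), k=2, seed=0)
        assert labels.tolist() == [0, 0, 0, 0, 1, 1, 1]

    def test_outlier_condition_forms_singleton(self):
        """Five OSMAC-like profiles where one condition carries extra
        exclusive features and a global intensity boost: k=2 isolates it."""
        tables = gen_peak_tables(ConditionSpec(seed=10))
        pm = build_profile_matrix(tables)
        labels = kmeans_profiles(pm, k=2, seed=0)
        outlier_idx = pm.samples.index("PvFe")
        assert labels[outlier_idx] == 1
        assert (labels == 1).sum() == 1

    def test_fixed_seed_reproducible(self):
        X = np.random.default_rng(3).normal(size=(8, 4))
        l1 = kmeans_profiles(X, k=3, seed=17)
        l2 = kmeans_profiles(X, k=3, seed=17)
        assert (l1 == l2).all()

    def test_invalid_k_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans_profiles(X, k=0)
        with pytest.raises(ValueError):
            kmeans_profiles(X, k=4)


def test_peak_table_csv_roundtrip(tmp_path):
    tables = gen_peak_tables(ConditionSpec(seed=6))
    path = tmp_path / "peaks.csv"
    write_peak_tables(tables, path)
    back = read_peak_tables(path)
    assert [t.sample_id for t in back] == [t.sample_id for t in tables]
    for t1, t2 in zip(tables, back):
        assert [p.feature_id for p in t1.peaks] == [p.feature_id for p in t2.peaks]
        assert [p.area for p in t1.peaks] == pytest.approx([p.area for p in t2.peaks])
        assert [p.mz for p in t1.peaks] == pytest.approx([p.mz for p in t2.peaks])


def test_duplicate_feature_ids_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        PeakTable("s", [Peak("a", 1.0, 1.0), Peak("a", 2.0, 2.0)])
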