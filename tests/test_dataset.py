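import numpy as np
import pandas as pd
import pytest

from msikit.dataset import (
    ChunkPlan,
    attach_pixel_annotations,
    mean_spectrum,
    process_in_chunks,
    roi_from_rectangles,
    subset_pixels,
    summarize_feature,
)
from msikit.phantom import generate_centroid_phantom

from conftest import make_dataset


class TestAnnotations:
    def test_full_table_annotates_every_pixel(self, random_dataset):
        ds = random_dataset
        table = ds.pixels[["run", "x", "y"]].copy()
        table["region"] = "A"
        out = attach_pixel_annotations(ds, table)
        assert out.pixels["region"].notna().all()
        assert len(out.pixels) == ds.n_pixels

    def test_partial_table_then_filter_keeps_annotated_only(self, random_dataset):
        # annotate a subset tumor/stroma, filter to the annotated spectra
        ds = random_dataset
        table = ds.pixels[["run", "x", "y"]].iloc[:50].copy()
        table["tissue"] = ["tumor"] * 30 + ["stroma"] * 20
        out = attach_pixel_annotations(ds, table)
        assert out.pixels["tissue"].isna().sum() == ds.n_pixels - 50
        sub = subset_pixels(out, "tissue in ['tumor', 'stroma']")
        assert sub.n_pixels == 50
        assert set(sub.pixels["tissue"]) == {"tumor", "stroma"}

    def test_duplicate_key_raises_and_names_it(self, random_dataset):
        table = random_dataset.pixels[["run", "x", "y"]].iloc[[0, 0]].copy()
        table["v"] = [1, 2]
        with pytest.raises(ValueError, match=r"duplicate \(run,x,y\)"):
            attach_pixel_annotations(random_dataset, table)

    def test_pixel_order_unchanged(self, random_dataset):
        table = random_dataset.pixels[["run", "x", "y"]].iloc[::-1].copy()
        table["v"] = np.arange(len(table))
        out = attach_pixel_annotations(random_dataset, table)
        pd.testing.assert_frame_equal(
            out.pixels[["run", "x", "y"]], random_dataset.pixels[["run", "x", "y"]]
        )


class TestSubset:
    def test_always_true_is_identity(self, random_dataset):
        out = subset_pixels(random_dataset, "x >= 0")
        assert out.n_pixels == random_dataset.n_pixels
        np.testing.assert_array_equal(
            out.intensity_matrix(), random_dataset.intensity_matrix()
        )

    def test_region_subset_count_matches_ground_truth(self):
        # 10x10 grid; region A planted on 40 pixels; count by direct scan
        ds, lab = generate_centroid_phantom(
            {"A": 40, "B": 60}, {"A": {500.0: 5.0}, "B": {500.0: 1.0}},
            width=10, seed=3,
        )
        ds.pixels["region"] = lab.to_numpy()
        expected = int((lab == "A").sum())
        out = subset_pixels(ds, "region == 'A'")
        assert out.n_pixels == expected == 40

    def test_unknown_column_raises(self, random_dataset):
        with pytest.raises(ValueError, match="unknown column"):
            subset_pixels(random_dataset, "nope == 1")

    def test_empty_result_is_empty_dataset(self, random_dataset):
        out = subset_pixels(random_dataset, "x > 10000")
        assert out.n_pixels == 0

    def test_subset_composition_equals_conjunction(self, random_dataset):
        a = subset_pixels(subset_pixels(random_dataset, "x < 10"), "y < 5")
        b = subset_pixels(random_dataset, "(x < 10) & (y < 5)")
        pd.testing.assert_frame_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())

    def test_features_unchanged_and_order_preserved(self, random_dataset):
        out = subset_pixels(random_dataset, "x % 2 == 0")
        pd.testing.assert_frame_equal(out.features, random_dataset.features)
        assert out.pixels["x"].tolist() == sorted(
            out.pixels["x"].tolist(), key=lambda _: 0
        )  # original row order retained
        assert (out.pixels["x"] % 2 == 0).all()


class TestRoi:
    def test_single_rectangle_covers_grid(self, random_dataset):
        col = roi_from_rectangles(
            random_dataset, [("run0", (0, 19), (0, 9), "all")])
        assert (col == "all").all()

    def test_two_disjoint_rectangles_counts(self):
        ds = make_dataset(np.ones((3, 36)), width=6)
        col = roi_from_rectangles(ds, [
            ("run0", (0, 2), (0, 3), "L"),  # 3 x 4 = 12 pixels
            ("run0", (3, 5), (4, 5), "R"),  # 3 x 2 = 6 ... plus 2 more rows
            ("run0", (3, 5), (2, 3), "R"),
        ])
        # brute-force point-in-rectangle scan
        px = ds.pixels
        exp_l = ((px.x <= 2) & (px.y <= 3)).sum()
        exp_r = ((px.x >= 3) & (px.y >= 2) & (px.y <= 5)).sum()
        assert (col == "L").sum() == exp_l == 12
        assert (col == "R").sum() == exp_r == 12
        assert col.isna().sum() == 36 - 24

    def test_overlapping_rectangles_different_labels_raise(self, random_dataset):
        with pytest.raises(ValueError, match="overlapping"):
            roi_from_rectangles(random_dataset, [
                ("run0", (0, 5), (0, 5), "a"),
                ("run0", (4, 8), (4, 8), "b"),
            ])


class TestChunking:
    def test_tic_sum_invariant_to_chunk_size(self, random_dataset):
        vals = [
            process_in_chunks(random_dataset, lambda s: s.sum(), np.add,
                              ChunkPlan(chunk_size=c))
            for c in (1, 13, None)
        ]
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)
        assert vals[0] == pytest.approx(vals[2], rel=1e-12)

    def test_mean_spectrum_workers_invariant(self, random_dataset):
        m1 = mean_spectrum(random_dataset, ChunkPlan(chunk_size=17, workers=1))
        m2 = mean_spectrum(random_dataset, ChunkPlan(chunk_size=17, workers=2))
        np.testing.assert_allclose(m1, m2, rtol=1e-12)
        # single-pass dense oracle
        oracle = random_dataset.intensity_matrix().mean(axis=1)
        np.testing.assert_allclose(m1, oracle, rtol=1e-10)

    def test_map_error_names_pixel(self, random_dataset):
        def bad(s, _n=iter(range(10**6))):
            raise ValueError("boom")

        calls = {"i": -1}

        def bad(s):
            calls["i"] += 1
            if calls["i"] == 7:
                raise ValueError("boom")
            return 0.0

        with pytest.raises(RuntimeError, match="pixel 7"):
            process_in_chunks(random_dataset, bad, np.add, ChunkPlan(chunk_size=4))

    def test_chunked_pipeline_matches_dense(self, random_dataset):
        dense = random_dataset.intensity_matrix()
        for c in (1, 7, 64, None):
            m = mean_spectrum(random_dataset, ChunkPlan(chunk_size=c))
            np.testing.assert_allclose(m, dense.mean(axis=1), rtol=1e-10)


class TestMeanSpectrum:
    def test_identical_spectra(self):
        s = np.array([1.0, 5.0, 2.0])
        ds = make_dataset(np.tile(s[:, None], (1, 8)))
        np.testing.assert_array_equal(mean_spectrum(ds), s)

    def test_two_spectra(self):
        ds = make_dataset(np.array([[1.0, 3.0], [3.0, 5.0]]))
        np.testing.assert_array_equal(mean_spectrum(ds), [2.0, 4.0])


class TestSummarizeFeature:
    def test_single_group_equals_overall_mean(self, random_dataset):
        ds = random_dataset
        ds.pixels["g"] = "one"
        out = summarize_feature(ds, ds.mz[3], 10.0, "g")
        assert out["value"].iloc[0] == pytest.approx(
            ds.intensity_matrix()[3].mean())

    def test_planted_group_means_recovered(self):
        ds, lab = generate_centroid_phantom(
            {"lo": 50, "hi": 50},
            {"lo": {1347.7: 1.0}, "hi": {1347.7: 5.0}},
            noise_sd=0.01, seed=5,
        )
        ds.pixels["grp"] = lab.to_numpy()
        out = summarize_feature(ds, 1347.7, 100.0, "grp")
        got = dict(zip(out["grp"], out["value"]))
        assert got["lo"] == pytest.approx(1.0, abs=0.01)
        assert got["hi"] == pytest.approx(5.0, abs=0.01)

    def test_query_resolves_to_nearest_feature(self):
        ds = make_dataset(np.ones((3, 4)), mz=[1347.2, 1347.65, 1350.0])
        out = summarize_feature(ds, 1347.7, 200.0, "run")
        assert out["mz"].iloc[0] == 1347.65

    def test_no_feature_in_tolerance_reports_nearest(self):
        ds = make_dataset(np.ones((2, 4)), mz=[100.0, 200.0])
        with pytest.raises(ValueError, match="nearest is 200"):
            summarize_feature(ds, 199.0, 10.0, "run")


def test_provenance_grows_by_one_per_op(random_dataset):
    ds = random_dataset
    n0 = len(ds.provenance)
    ds1 = subset_pixels(ds, "x < 15")
    table = ds1.pixels[["run", "x", "y"]].copy()
    table["c"] = 1
    ds2 = attach_pixel_annotations(ds1, table)
    assert len(ds1.provenance) == n0 + 1
    assert len(ds2.provenance) == n0 + 2
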