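import numpy as np
import pandas as pd
import pytest

from grainscape import (PointPattern, SpatialModel, flag_touching,
                        generate_point_pattern, nn_distances,
                        theoretical_vs_observed)


def pattern_from_coords(coords, patch="exposed", window=(100.0, 100.0), **cols):
    df = pd.DataFrame({"x_um": [c[0] for c in coords],
                       "y_um": [c[1] for c in coords],
                       "patch": patch, **cols})
    return PointPattern(df, window)


class TestNNDistances:
    def test_square_lattice_spacing(self):
        xs, ys = np.meshgrid(np.arange(5, 100, 5.0), np.arange(5, 100, 5.0))
        pat = pattern_from_coords(list(zip(xs.ravel(), ys.ravel())))
        res = nn_distances(pat, exclude_touching=False)
        assert res.loc["exposed", "mean_nn_um"] == pytest.approx(5.0)
        assert res.loc["exposed", "sd_nn_um"] == pytest.approx(0.0)

    def test_two_points_three_four_five(self):
        pat = pattern_from_coords([(0, 0), (3, 4)])
        res = nn_distances(pat, exclude_touching=False)
        assert res.loc["exposed", "mean_nn_um"] == pytest.approx(5.0)
        assert res.loc["exposed", "min_um"] == res.loc["exposed", "max_um"] == 5.0

    def test_classes_summarized_separately(self):
        df = pd.DataFrame({
            "x_um": [0, 10, 50, 51], "y_um": [0, 0, 50, 50],
            "patch": ["exposed", "exposed", "protected", "protected"],
        })
        res = nn_distances(PointPattern(df, (100, 100)), exclude_touching=False)
        assert res.loc["exposed", "mean_nn_um"] == pytest.approx(10.0)
        assert res.loc["protected", "mean_nn_um"] == pytest.approx(1.0)

    def test_single_point_class_reports_null_stats(self):
        df = pd.DataFrame({"x_um": [1, 2, 3], "y_um": [1, 2, 3],
                           "patch": ["exposed", "protected", "protected"]})
        res = nn_distances(PointPattern(df, (10, 10)), exclude_touching=False)
        assert res.loc["exposed", "n_cells"] == 1
        assert np.isnan(res.loc["exposed", "mean_nn_um"])

    def test_excluding_touching_never_decreases_mean(self):
        # planted touching pair at distance 0.2 amid well-spaced points
        coords = [(10, 10), (10.2, 10), (30, 30), (60, 60), (90, 20)]
        pat = pattern_from_coords(coords)
        with_touch = nn_distances(pat, exclude_touching=False)
        without = nn_distances(pat, exclude_touching=True, touching_radius_um=1.0)
        assert (without.loc["exposed", "mean_nn_um"]
                >= with_touch.loc["exposed", "mean_nn_um"])
        assert without.loc["exposed", "n_cells"] == 3

    def test_explicit_touching_flags_respected(self):
        pat = pattern_from_coords([(0, 0), (3, 4), (50, 50)],
                                  touching=[True, False, False])
        res = nn_distances(pat, exclude_touching=True)
        assert res.loc["exposed", "n_cells"] == 2

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(10, 40, size=(30, 2))
        base = pattern_from_coords([tuple(c) for c in coords])
        shifted = pattern_from_coords([tuple(c + 25.0) for c in coords])
        a = nn_distances(base, exclude_touching=False)
        b = nn_distances(shifted, exclude_touching=False)
        pd.testing.assert_frame_equal(a, b)

    def test_distances_bounded_by_window_diagonal(self):
        rng = np.random.default_rng(15)
        coords = rng.uniform(0, 100, size=(40, 2))
        res = nn_distances(pattern_from_coords([tuple(c) for c in coords]),
                           exclude_touching=False)
        assert res.loc["exposed", "max_um"] <= np.hypot(100, 100)


class TestTheoreticalComparison:
    def test_lattice_and_poisson_spacings(self):
        res = nn_distances(pattern_from_coords([(0, 0), (3, 4)]), exclude_touching=False)
        cmp = theoretical_vs_observed(0.09, res)
        assert cmp["lattice_spacing_um"] == pytest.approx(3.333, abs=5e-3)
        assert cmp["poisson_mean_nn_um"] == pytest.approx(1.667, abs=5e-3)

    def test_unit_density(self):
        res = nn_distances(pattern_from_coords([(0, 0), (3, 4)]), exclude_touching=False)
        cmp = theoretical_vs_observed(1.0, res)
        assert cmp["lattice_spacing_um"] == 1.0
        assert cmp["poisson_mean_nn_um"] == 0.5


class TestGenerator:
    def test_zero_exposed_intensity_all_protected(self):
        model = SpatialModel(exposed_intensity=0.0, protected_intensity=0.5,
                             protected_patch_fraction=0.3, window=(80, 80), seed=4)
        pat = generate_point_pattern(model)
        assert pat.n_points > 0
        assert set(pat.points["patch"]) == {"protected"}

    def test_poisson_count_within_three_sigma(self):
        lam, w = 0.09, 1000.0
        model = SpatialModel(window=(w, w), exposed_intensity=lam,
                             protected_intensity=0.0, protected_patch_fraction=0.0,
                             cluster_scale=0.0, seed=10)
        pat = generate_point_pattern(model)
        mean = lam * w * w
        assert abs(pat.n_points - mean) < 3 * np.sqrt(mean)

    def test_seeded_determinism(self):
        a = generate_point_pattern(SpatialModel(seed=21))
        b = generate_point_pattern(SpatialModel(seed=21))
        pd.testing.assert_frame_equal(a.points, b.points)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            SpatialModel(exposed_intensity=-0.1)

    def test_touching_flags_mark_close_pairs(self):
        pat = pattern_from_coords([(5, 5), (5.3, 5), (20, 20)])
        flags = flag_touching(pat, radius_um=1.0)
        assert flags.tolist() == [True, True, False]

    def test_clustered_pattern_denser_neighborhoods(self):
        # Thomas clustering shortens NN distances at fixed intensity
        kw = dict(window=(300.0, 300.0), exposed_intensity=0.05,
                  protected_intensity=0.0, protected_patch_fraction=0.0, seed=2)
        homog = generate_point_pattern(SpatialModel(cluster_scale=0.0, **kw))
        clust = generate_point_pattern(SpatialModel(cluster_scale=2.0, **kw))
        nn_h = nn_distances(homog, exclude_touching=False).loc["exposed", "mean_nn_um"]
        nn_c = nn_distances(clust, exclude_touching=False).loc["exposed", "mean_nn_um"]
        assert nn_c < nn_h
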