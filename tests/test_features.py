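"""The 36 heatmap statistics: band logic, worked examples, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_heatmap
from pdacwsi.features import (BANDS, FEATURE_NAMES, N_FEATURES, band_of,
                              extract_features, features_to_frame)

probability_grids = st.lists(
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=5),
    min_size=2, max_size=5).filter(lambda g: len({len(r) for r in g}) == 1)


class TestBandOf:
    def test_top_band_is_strict(self):
        assert band_of(0.9995) == 0           # P > 0.999
        assert band_of(0.999) == 1            # boundary belongs below: 0.99 < P <= 0.999
        assert band_of(1.0) == 0

    @pytest.mark.parametrize("p,idx", [
        (0.995, 1), (0.96, 2), (0.92, 3), (0.85, 4),
        (0.75, 5), (0.65, 6), (0.55, 7),
        (0.99, 2), (0.95, 3), (0.9, 4), (0.8, 5), (0.7, 6), (0.6, 7),
    ])
    def test_band_membership_and_boundaries(self, p, idx):
        assert band_of(p) == idx

    def test_below_half_has_no_band(self):
        assert band_of(0.5) is None
        assert band_of(0.2) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            band_of(1.2)
        with pytest.raises(ValueError):
            band_of(-0.1)

    def test_bands_partition_upper_half(self):
        assert BANDS[0][1] == 1.0 and BANDS[-1][0] == 0.5
        for (lo1, _), (_, hi2) in zip(BANDS, BANDS[1:]):
            assert lo1 == hi2  # adjacent, disjoint


class TestExtractFeatures:
    def test_degenerate_all_tumor_heatmap(self):
        hm = make_heatmap(np.ones((3, 3)))
        f = extract_features(hm).as_series()
        assert f["tumor_mean"] == 1.0
        assert f["tumor_variance"] == 0.0
        assert f["tumor_sum"] == 9.0
        assert f["np_tumor_gt0.999"] == 9.0
        assert sum(f[k] for k in f.index
                   if k.startswith("np_tumor") and k != "np_tumor_gt0.999") == 0
        assert f["argmax_mean_class"] == 1.0 and f["majority_class"] == 1.0

    def test_worked_2x2_example(self):
        """Hand-computed statistics of p_tumor = {0.1, 0.4, 0.6, 0.95}."""
        hm = make_heatmap([[0.1, 0.4], [0.6, 0.95]])
        f = extract_features(hm).as_series()
        assert np.isclose(f["tumor_mean"], 0.5125)
        assert np.isclose(f["tumor_min"], 0.1)
        assert np.isclose(f["tumor_max"], 0.95)
        assert np.isclose(f["tumor_range"], 0.85)
        assert np.isclose(f["tumor_sum"], 2.05)
        assert np.isclose(f["tumor_median"], 0.5)
        assert f["np_tumor_gt0.9"] == 1.0   # 0.95 in (0.9, 0.95]
        assert f["np_tumor_gt0.5"] == 1.0   # 0.6 in (0.5, 0.6]
        assert f["np_normal_gt0.8"] == 1.0  # p_normal 0.9 in (0.8, 0.9]
        assert f["np_normal_gt0.5"] == 1.0  # p_normal 0.6
        # 2 vs 2 patches -> tie resolved toward tumor
        assert f["majority_class"] == 1.0

    def test_vector_length_and_names(self):
        hm = make_heatmap(np.random.default_rng(0).random((4, 4)))
        vec = extract_features(hm)
        assert vec.values.shape == (N_FEATURES,)
        assert len(FEATURE_NAMES) == 36

    def test_mode_rounding_and_tie_rule(self):
        # rounded to 2 dp: {0.10: x2, 0.20: x2, 0.35: x1} -> tie 0.1 vs 0.2 -> smallest
        hm = make_heatmap([[0.101, 0.099], [0.2, 0.204], [0.35, 0.35]])
        f = extract_features(hm).as_series()
        assert f["tumor_mode"] == pytest.approx(0.1)

    def test_background_cells_excluded_by_default(self):
        bg = np.array([[False, True], [True, True]])
        hm = make_heatmap([[0.9, 0.0], [0.0, 0.0]], background=bg)
        f = extract_features(hm).as_series()
        assert f["tumor_mean"] == pytest.approx(0.9)
        f_all = extract_features(hm, include_background=True).as_series()
        assert f_all["tumor_mean"] == pytest.approx(0.225)

    def test_all_background_fails_explicitly(self):
        hm = make_heatmap([[0.5]], background=np.array([[True]]))
        with pytest.raises(ValueError, match="no counted cells"):
            extract_features(hm)

    def test_variance_std_range_consistency(self):
        hm = make_heatmap(np.random.default_rng(1).random((5, 5)))
        f = extract_features(hm).as_series()
        for cls in ("normal", "tumor"):
            assert np.isclose(f[f"{cls}_variance"], f[f"{cls}_std"] ** 2)
            assert np.isclose(f[f"{cls}_range"], f[f"{cls}_max"] - f[f"{cls}_min"])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(probability_grids)
def test_normal_tumor_statistics_linkage(grid):
    """p_normal = 1 - p_tumor links the two blocks: mean_n = 1 - mean_t,
    var_n = var_t, range_n = range_t, sum_n = n - sum_t."""
    hm = make_heatmap(grid)
    f = extract_features(hm).as_series()
    n = np.asarray(grid).size
    assert np.isclose(f["normal_mean"], 1 - f["tumor_mean"])
    assert np.isclose(f["normal_variance"], f["tumor_variance"], atol=1e-12)
    assert np.isclose(f["normal_range"], f["tumor_range"])
    assert np.isclose(f["normal_sum"], n - f["tumor_sum"])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(probability_grids)
def test_band_counts_match_brute_force_oracle(grid):
    hm = make_heatmap(grid)
    f = extract_features(hm).as_series()
    cells = hm.grid.reshape(-1, 2)
    for b, (lo, hi) in enumerate(BANDS):
        for ci, cls in enumerate(("normal", "tumor")):
            expected = sum(1 for cell in cells if lo < cell[ci] <= hi)
            assert f[f"np_{cls}_gt{lo}"] == expected


@settings(max_examples=20, deadline=None, derandomize=True)
@given(probability_grids, st.randoms(use_true_random=False))
def test_permutation_invariance(grid, rnd):
    hm = make_heatmap(grid)
    flat = hm.grid.reshape(-1, 2)
    idx = list(range(len(flat)))
    rnd.shuffle(idx)
    shuffled = make_heatmap(flat[idx, 1].reshape(np.asarray(grid).shape))
    a = extract_features(hm).values
    b = extract_features(shuffled).values
    assert np.allclose(a, b)


def test_each_cell_hits_at_most_one_band_pair():
    rng = np.random.default_rng(2)
    p = rng.random((6, 6))
    hm = make_heatmap(p)
    f = extract_features(hm).as_series()
    total_band_counts = sum(f[k] for k in f.index if k.startswith("np_"))
    # every cell contributes via exactly one class unless both probs == 0.5
    exact_half = np.sum(p == 0.5)
    assert total_band_counts == p.size - exact_half


def test_features_frame_layout():
    hms = [make_heatmap(np.random.default_rng(i).random((3, 3)),
                        slide_id=f"s{i}") for i in range(3)]
    df = features_to_frame([extract_features(h) for h in hms])
    assert list(df.columns) == ["slide_id"] + list(FEATURE_NAMES)
    assert df.shape == (3, 37)
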