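import numpy as np
import pandas as pd
import pytest

import vibands as vb
from vibands.core import SampleSet
from vibands.optimizer import (GridConfig, MetricMap, compare_criteria,
                               count_configs, enumerate_configs, evaluate_config,
                               evaluate_map, evaluate_map_scalar, select_optimal)

TOY_GRID = GridConfig(start=460, stop=810, step=50)  # 8 wavelengths


class TestEnumeration:
    def test_default_grid_cardinality(self):
        counts = count_configs(GridConfig())
        assert counts["wavelengths"] == 501
        assert counts["per_bandwidth_pair"] == 501 * 500 == 250_500

    def test_three_wavelengths_give_six_ordered_pairs(self):
        grid = GridConfig(start=500, stop=700, step=100)
        pairs = list(enumerate_configs(grid, 10, 10))
        assert len(pairs) == 6
        assert pairs[0] == (500.0, 10, 600.0, 10)  # row-major, diagonal skipped
        assert all(p[0] != p[2] for p in pairs)

    def test_step_five_count(self):
        counts = count_configs(GridConfig(step=5))
        assert counts["per_bandwidth_pair"] == 101 * 100 == 10_100

    def test_enumeration_matches_count_and_bandwidth_pairing(self):
        grid = GridConfig(start=450, stop=500, step=10,
                          bandwidths=(1, 5), pair_bandwidths="equal")
        assert count_configs(grid)["bandwidth_pairs"] == 2
        full = GridConfig(start=450, stop=500, step=10, bandwidths=(1, 5))
        assert count_configs(full)["bandwidth_pairs"] == 4
        assert len(list(enumerate_configs(grid, 1, 1))) == \
            count_configs(grid)["per_bandwidth_pair"]


class TestMapEvaluation:
    @pytest.mark.parametrize("formula", ["NDVI", "SR", "DI", "SAVI", "mSR",
                                         "mNDI", "TVI"])
    def test_vectorized_map_equals_scalar_oracle(self, noiseless_set, formula):
        fast = evaluate_map(noiseless_set, "chl", formula, 10, 30, TOY_GRID)
        slow = evaluate_map_scalar(noiseless_set, "chl", formula, 10, 30,
                                   TOY_GRID)
        np.testing.assert_array_equal(fast.valid, slow.valid)
        for attr in ("r2", "rmse", "re_percent"):
            a, b = getattr(fast, attr), getattr(slow, attr)
            np.testing.assert_allclose(a[fast.valid], b[slow.valid],
                                       atol=1e-10, rtol=0)

    def test_identical_pigment_values_mask_every_cell(self, noiseless_set):
        pig = noiseless_set.pigments.copy()
        pig["chl_mg_per_l"] = 5.0
        degenerate = SampleSet(noiseless_set.wavelengths,
                               noiseless_set.reflectance, pig)
        m = evaluate_map(degenerate, "chl", "NDVI", 10, 10, TOY_GRID)
        assert not m.valid.any()

    def test_di_map_symmetric_in_r2_under_band_swap(self, noiseless_set):
        # DI(a, b) = -DI(b, a); the log-linear fit flips b's sign but
        # prediction quality is unchanged
        m = evaluate_map(noiseless_set, "chl", "DI", 10, 10, TOY_GRID)
        ok = m.valid & m.valid.T
        np.testing.assert_allclose(m.r2[ok], m.r2.T[ok], atol=1e-9)

    def test_diagonal_masked_and_determinism(self, noiseless_set):
        a = evaluate_map(noiseless_set, "car", "NDVI", 10, 10, TOY_GRID)
        b = evaluate_map(noiseless_set, "car", "NDVI", 10, 10, TOY_GRID)
        assert not a.valid.diagonal().any()
        np.testing.assert_array_equal(
            np.where(a.valid, a.r2, -1), np.where(b.valid, b.r2, -1))

    def test_map_dataframe_round_trip(self, noiseless_set, tmp_path):
        m = evaluate_map(noiseless_set, "chl", "NDVI", 10, 10, TOY_GRID)
        path = tmp_path / "map.csv"
        m.write_csv(path)
        df = pd.read_csv(path)
        assert len(df) == m.lambda1.size ** 2
        assert df["valid"].sum() == m.valid.sum()

    def test_too_few_samples_rejected(self, noiseless_set):
        small = SampleSet(noiseless_set.wavelengths,
                          noiseless_set.reflectance[:2],
                          noiseless_set.pigments.iloc[:2])
        with pytest.raises(ValueError):
            evaluate_map(small, "chl", "NDVI", 10, 10, TOY_GRID)


class TestSelection:
    def _map_from(self, r2, rmse, formula="NDVI"):
        k = r2.shape[0]
        axis = 500.0 + 10.0 * np.arange(k)
        valid = np.isfinite(r2)
        return MetricMap(axis, axis, r2, rmse, np.zeros_like(r2),
                         np.full(r2.shape, 10), valid, formula, 10, 10, "chl")

    def test_single_unmasked_cell_returned(self, noiseless_set):
        m = evaluate_map(noiseless_set, "chl", "NDVI", 10, 10, TOY_GRID)
        keep = (2, 5)
        m.valid[:] = False
        m.valid[keep] = True
        results, best = select_optimal([m], noiseless_set, "chl")
        assert (best.lambda1, best.lambda2) == (m.lambda1[2], m.lambda2[5])

    def test_r2_tie_broken_by_lower_rmse(self, noiseless_set):
        r2 = np.full((3, 3), np.nan)
        rmse = np.full((3, 3), np.nan)
        r2[0, 1] = r2[1, 0] = 0.9
        rmse[0, 1], rmse[1, 0] = 1.0, 0.5
        m = self._map_from(r2, rmse)
        from vibands.optimizer import _best_cell
        _, _, l1, l2 = _best_cell(m, "r2")
        assert (l1, l2) == (m.lambda1[1], m.lambda2[0])

    def test_all_masked_rejected(self, noiseless_set):
        r2 = np.full((3, 3), np.nan)
        m = self._map_from(r2, r2.copy())
        with pytest.raises(ValueError):
            select_optimal([m], noiseless_set, "chl")

    def test_selected_optimum_recomputed_through_scalar_path(self, noiseless_set):
        m = evaluate_map(noiseless_set, "chl", "NDVI", 10, 10, TOY_GRID)
        _, best = select_optimal([m], noiseless_set, "chl")
        redo = evaluate_config(noiseless_set, "chl", "NDVI", best.lambda1,
                               10, best.lambda2, 10)
        assert redo.metrics.r2 == best.metrics.r2
        assert redo.model.a == best.model.a

    def test_criterion_comparison_reports_displacements(self, noiseless_set):
        maps = [evaluate_map(noiseless_set, "chl", f, 10, 10, TOY_GRID)
                for f in ("NDVI", "SR")]
        report = compare_criteria(maps, noiseless_set, "chl")
        assert set(report["formula"]) == {"NDVI", "SR"}
        assert (report["max_lambda_shift_nm"] >= 0).all()


def test_end_to_end_search_finds_the_informative_red_region(low_noise_set):
    grid = GridConfig(step=5, bandwidths=(10,), formulas=("NDVI", "SR"))
    maps = [evaluate_map(low_noise_set, "chl", f, 10, 10, grid)
            for f in grid.formulas]
    _, best = select_optimal(maps, low_noise_set, "chl")
    assert best.metrics.r2 >= 0.8
    assert (600 <= best.lambda1 <= 740) or (600 <= best.lambda2 <= 740)
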