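import numpy as np
import pytest

import vibands as vb
from vibands.optimizer import GridConfig, evaluate_map, select_optimal
from vibands.sensitivity import (bandwidth_profile, formula_comparison,
                                 shift_profile)


@pytest.fixture(scope="module")
def reference(low_noise_set):
    """Exhaustive-search optimum on a 5 nm grid (NDVI, 10 nm channels)."""
    grid = GridConfig(step=5, bandwidths=(10,), formulas=("NDVI",))
    maps = [evaluate_map(low_noise_set, "chl", "NDVI", 10, 10, grid)]
    _, best = select_optimal(maps, low_noise_set, "chl")
    return best


class TestShiftProfile:
    def test_zero_offset_embeds_reference_exactly(self, low_noise_set, reference):
        prof = shift_profile(low_noise_set, "chl", reference,
                             max_shift=10, step=5)
        i0 = int(np.where(prof.offsets == 0)[0][0])
        assert prof.r2[i0] == reference.metrics.r2
        assert prof.rmse[i0] == reference.metrics.rmse

    def test_argmax_dominance_over_on_grid_offsets(self, low_noise_set, reference):
        # offsets that are multiples of the search step stay on the
        # searched grid, so no shifted configuration can beat the optimum
        prof = shift_profile(low_noise_set, "chl", reference,
                             max_shift=20, step=5)
        i0 = int(np.where(prof.offsets == 0)[0][0])
        assert np.all(prof.r2 <= prof.r2[i0] + 1e-12)

    def test_max_deviation_grows_with_the_probed_range(self, low_noise_set,
                                                       reference):
        wide = shift_profile(low_noise_set, "chl", reference,
                             max_shift=20, step=5)
        narrow = shift_profile(low_noise_set, "chl", reference,
                               max_shift=5, step=5)
        assert wide.max_deviation_percent.max() >= \
            narrow.max_deviation_percent.max()

    def test_out_of_range_offsets_dropped_with_note(self, low_noise_set,
                                                    reference):
        huge = shift_profile(low_noise_set, "chl", reference,
                             max_shift=600, step=100)
        assert huge.dropped_offsets
        lo, hi = low_noise_set.wavelengths[0], low_noise_set.wavelengths[-1]
        for d in huge.offsets:
            assert lo <= reference.lambda1 + d <= hi
            assert lo <= reference.lambda2 + d <= hi

    def test_per_channel_mode_contains_the_joint_diagonal(self, low_noise_set,
                                                          reference):
        joint = shift_profile(low_noise_set, "chl", reference,
                              max_shift=5, step=5)
        grid2d = shift_profile(low_noise_set, "chl", reference,
                               max_shift=5, step=5, mode="per-channel")
        for i, d in enumerate(grid2d.offsets):
            j = int(np.where(joint.offsets == d)[0][0])
            assert grid2d.r2[i, i] == joint.r2[j]

    def test_repeated_runs_identical(self, low_noise_set, reference):
        a = shift_profile(low_noise_set, "chl", reference, max_shift=10, step=5)
        b = shift_profile(low_noise_set, "chl", reference, max_shift=10, step=5)
        np.testing.assert_array_equal(a.r2, b.r2)
        np.testing.assert_array_equal(a.max_deviation_percent,
                                      b.max_deviation_percent)

    def test_frozen_model_mode_skips_recalibration(self, low_noise_set,
                                                   reference):
        prof = shift_profile(low_noise_set, "chl", reference, max_shift=10,
                             step=5, refit=False)
        i0 = int(np.where(prof.offsets == 0)[0][0])
        assert prof.r2[i0] == reference.metrics.r2
        # away from the reference a frozen calibration cannot beat re-fitting
        refit = shift_profile(low_noise_set, "chl", reference, max_shift=10,
                              step=5)
        assert np.all(prof.r2 <= refit.r2 + 1e-12)


class TestBandwidthProfile:
    def test_reference_bandwidth_reproduces_reference_metrics(
            self, low_noise_set, reference):
        prof = bandwidth_profile(low_noise_set, "chl", reference)
        idx = prof.bandwidth_pairs.index((reference.dl1, reference.dl2))
        assert prof.r2[idx] == reference.metrics.r2
        assert prof.rmse[idx] == reference.metrics.rmse

    def test_unequal_reference_pair_appended(self, low_noise_set):
        ref = vb.evaluate_config(low_noise_set, "chl", "NDVI",
                                 680.0, 30.0, 750.0, 1.0)
        prof = bandwidth_profile(low_noise_set, "chl", ref,
                                 bandwidths=(5.0, 10.0))
        assert (30.0, 1.0) in prof.bandwidth_pairs
        idx = prof.bandwidth_pairs.index((30.0, 1.0))
        assert prof.r2[idx] == ref.metrics.r2

    def test_per_channel_mode_covers_the_product(self, low_noise_set, reference):
        prof = bandwidth_profile(low_noise_set, "chl", reference,
                                 bandwidths=(5.0, 10.0), mode="per-channel")
        assert set(prof.bandwidth_pairs) >= {(5.0, 5.0), (5.0, 10.0),
                                             (10.0, 5.0), (10.0, 10.0)}

    def test_wide_channels_are_more_stable_on_narrow_feature_data(self):
        # a leaf model whose only chl feature is ~10 nm wide (FWHM)
        narrow = vb.LeafSpectrumModel(
            components=(vb.synthetic.AbsorptionComponent("chl", 670.0, 4.25,
                                                         0.30),),
            mult_noise_sd=0.01, add_noise_sd=0.002)
        samples = vb.generate_sample_set(n=50, model=narrow, seed=13)
        ref = vb.evaluate_config(samples, "chl", "NDVI", 670.0, 1.0, 800.0, 1.0)
        prof = bandwidth_profile(samples, "chl", ref,
                                 bandwidths=(1, 5, 10, 20, 30, 50))
        steps = np.diff(prof.stability[:6])
        assert np.sum(steps <= 0) >= 4


class TestFormulaComparison:
    def test_reference_formula_reproduces_reference_metrics(
            self, low_noise_set, reference):
        comp = formula_comparison(low_noise_set, "chl", reference.lambda1,
                                  reference.dl1, reference.lambda2,
                                  reference.dl2)
        row = comp.summary.set_index("formula").loc[reference.formula]
        assert row["r2"] == reference.metrics.r2
        assert row["rmse"] == reference.metrics.rmse

    def test_mean_per_sample_error_equals_aggregate_re(self, low_noise_set,
                                                       reference):
        comp = formula_comparison(low_noise_set, "chl", reference.lambda1,
                                  reference.dl1, reference.lambda2,
                                  reference.dl2)
        for _, row in comp.summary.iterrows():
            per_sample = comp.per_sample_errors[row["formula"]]
            assert per_sample.mean() == pytest.approx(row["re_percent"],
                                                      rel=1e-12)

    def test_formula_choice_spreads_prediction_quality(self, low_noise_set,
                                                       reference):
        comp = formula_comparison(low_noise_set, "chl", reference.lambda1,
                                  reference.dl1, reference.lambda2,
                                  reference.dl2)
        r2 = comp.summary["r2"]
        assert r2.max() - r2.min() >= 0.2
        assert comp.summary.loc[comp.summary["rank"] == 1, "r2"].iloc[0] == \
            r2.max()
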