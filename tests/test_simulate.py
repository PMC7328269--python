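import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methbatch import (
    SpikeSpec,
    assign_groups,
    build_layout,
    calibrate_effect_shift,
    emulate_parameter_profile,
    generate_null_betas,
    inject_batch_effects,
    spike_group_effects,
)
from methbatch.params import CpGParameterProfile
from methbatch.simulate import BETA_EPS


def _profile_from_arrays(mean, sd):
    n = len(mean)
    return CpGParameterProfile(
        table=pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(n)],
                "mean_beta": mean,
                "sd_beta": sd,
                "design_type": "II",
            }
        )
    )


class TestGenerateNullBetas:
    def test_law_of_large_numbers(self):
        prof = _profile_from_arrays([0.5], [0.01])
        layout = assign_groups(build_layout(10_000), "random", seed=1)
        betas = generate_null_betas(prof, layout, seed=2)
        assert abs(betas.values.mean() - 0.5) < 4 * 0.01 / np.sqrt(10_000)

    def test_deterministic(self, small_profile, layout48_random):
        a = generate_null_betas(small_profile, layout48_random, seed=3)
        b = generate_null_betas(small_profile, layout48_random, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_clamped_to_open_unit_interval(self):
        prof = _profile_from_arrays([0.999, 0.001], [0.05, 0.05])
        layout = assign_groups(build_layout(200), "random", seed=1)
        betas = generate_null_betas(prof, layout, seed=4)
        assert betas.values.max() <= 1 - BETA_EPS
        assert betas.values.min() >= BETA_EPS

    def test_null_pvalues_are_uniform(self):
        prof = emulate_parameter_profile(10_000, seed=5)
        layout = assign_groups(build_layout(48), "random", seed=6)
        betas = generate_null_betas(prof, layout, seed=7)
        g = layout.group_indicator()
        p = stats.ttest_ind(betas.values[:, g == 1], betas.values[:, g == 0], axis=1).pvalue
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestInjectBatchEffects:
    def test_zero_amplitude_is_identity(self, null_betas, layout48_random):
        out, spec = inject_batch_effects(null_betas, layout48_random, amplitude=0.0, seed=1)
        np.testing.assert_array_equal(out.values, null_betas.values)
        assert all(v == 0 for v in spec.offsets.values())

    def test_one_offset_per_factor_level(self, null_betas, layout48_random):
        _, spec = inject_batch_effects(null_betas, layout48_random, seed=2)
        assert len(spec.offsets) == 8 + 6  # 8 rows + 6 chips at n = 48
        assert all(abs(v) <= 0.01 for v in spec.offsets.values())

    def test_unknown_factor_rejected(self, null_betas, layout48_random):
        with pytest.raises(KeyError):
            inject_batch_effects(null_betas, layout48_random, factors=("lane",))

    def test_offsets_recoverable_from_column_means(self):
        # regress sample column-means on the row factor: the estimated
        # centered per-level offsets must match the injected ones within
        # three standard errors
        prof = _profile_from_arrays(np.full(2000, 0.5), np.full(2000, 0.05))
        layout = assign_groups(build_layout(480), "random", seed=1)
        betas = generate_null_betas(prof, layout, seed=2)
        out, spec = inject_batch_effects(betas, layout, factors=("row",), seed=3)
        col_means = out.values.mean(axis=0)
        rows = layout.factor_codes("row")
        est = np.array([col_means[rows == r].mean() for r in range(8)])
        est_centered = est - est.mean()
        true = np.array([spec.offsets[("row", r)] for r in range(8)])
        true_centered = true - true.mean()
        resid = col_means - est[rows]
        se = np.sqrt(resid.var(ddof=8) / 60)
        assert np.all(np.abs(est_centered - true_centered) < 3 * se + 1e-12)

    def test_balanced_design_offsets_cancel_between_groups(self):
        # the balanced layout places each group equally often on every row
        # and chip, so the injected shift changes the case-control mean
        # difference by exactly zero
        prof = _profile_from_arrays(np.full(100, 0.5), np.full(100, 0.02))
        layout = assign_groups(build_layout(48), "balanced")
        betas = generate_null_betas(prof, layout, seed=4)
        out, _ = inject_batch_effects(betas, layout, seed=5)
        g = layout.group_indicator()
        shift = out.values - betas.values
        diff = shift[:, g == 1].mean(axis=1) - shift[:, g == 0].mean(axis=1)
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_provenance_flag(self, null_betas, layout48_random):
        out, _ = inject_batch_effects(null_betas, layout48_random, seed=6)
        assert out.provenance == "batch_injected"
        assert null_betas.provenance == "null"


class TestCalibrateEffectShift:
    def test_vanishes_as_p_approaches_one(self):
        assert calibrate_effect_shift(0.999999, 24, 24, 0.05) < 1e-6

    @pytest.mark.parametrize("target", [0.05, 1e-3, 1e-8, 1e-15])
    def test_round_trip_recovers_target_p(self, target):
        delta = calibrate_effect_shift(target, 24, 24, 0.05)
        t = delta / (0.05 * np.sqrt(1 / 24 + 1 / 24))
        p = 2 * stats.t.sf(t, 46)
        assert abs(p - target) < 1e-10

    def test_monotone_in_p_and_sd(self):
        targets = [0.5, 0.1, 0.01, 1e-4, 1e-8]
        shifts = [calibrate_effect_shift(p, 24, 24, 0.05) for p in targets]
        assert np.all(np.diff(shifts) > 0)  # smaller p needs bigger shift
        sds = [0.01, 0.02, 0.05, 0.1]
        shifts_sd = [calibrate_effect_shift(0.01, 24, 24, s) for s in sds]
        assert np.all(np.diff(shifts_sd) > 0)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_rejects_out_of_range_p(self, bad):
        with pytest.raises(ValueError):
            calibrate_effect_shift(bad, 24, 24, 0.05)


class TestSpikeGroupEffects:
    def test_zero_sites_is_identity(self, null_betas, layout48_random):
        spec = SpikeSpec(n_sites=0, target_p_values=(0.1,), seed=1)
        out = spike_group_effects(null_betas, layout48_random, spec)
        np.testing.assert_array_equal(out.values, null_betas.values)
        assert out.truth_mask.sum() == 0

    def test_equal_allocation_across_targets(self):
        spec = SpikeSpec(n_sites=2000, seed=1)
        alloc = spec.allocation()
        values, counts = np.unique(alloc, return_counts=True)
        assert len(values) == 20
        assert (counts == 100).all()

    def test_truth_mask_matches_site_count(self, small_profile, layout48_random):
        betas = None
        from methbatch import generate_null_betas

        betas = generate_null_betas(small_profile, layout48_random, seed=8)
        spec = SpikeSpec(n_sites=150, seed=2)
        out = spike_group_effects(betas, layout48_random, spec)
        assert out.truth_mask.sum() == 150
        assert out.provenance == "spiked"
        # only case-group columns move
        g = layout48_random.group_indicator()
        ctrl = out.values[:, g == 0]
        np.testing.assert_array_equal(ctrl, betas.values[:, g == 0])

    def test_strong_spikes_detected_by_t_test(self):
        # sites aimed at p = 1e-20 must realize p < 1e-10 almost always
        prof = _profile_from_arrays(np.full(3000, 0.5), np.full(3000, 0.03))
        layout = assign_groups(build_layout(48), "random", seed=3)
        betas = generate_null_betas(prof, layout, seed=9)
        spec = SpikeSpec(n_sites=200, target_p_values=(1e-20,), seed=4)
        out = spike_group_effects(betas, layout, spec)
        g = layout.group_indicator()
        p = stats.ttest_ind(
            out.values[out.truth_mask][:, g == 1],
            out.values[out.truth_mask][:, g == 0],
            axis=1,
        ).pvalue
        assert (p < 1e-10).mean() >= 0.95

    def test_rejects_more_sites_than_probes(self, null_betas, layout48_random):
        spec = SpikeSpec(n_sites=null_betas.n_probes + 1, seed=1)
        with pytest.raises(ValueError):
            spike_group_effects(null_betas, layout48_random, spec)
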