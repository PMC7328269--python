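import numpy as np
import pytest

from methbatch import (
    ComBatCorrector,
    combat_apply,
    combat_fit,
    from_mvalues,
    sequential_correct,
    to_mvalues,
)
from conftest import run_r_oracle, save_matrix


class TestMValueTransform:
    def test_symmetry_point(self):
        assert to_mvalues(np.array([0.5]))[0] == 0.0

    def test_known_value(self):
        np.testing.assert_allclose(to_mvalues(np.array([0.8])), [2.0])

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        beta = rng.uniform(0.001, 0.999, (50, 10))
        assert np.abs(from_mvalues(to_mvalues(beta)) - beta).max() < 1e-12


def _two_batch_data(seed=0, m=300, n=16, offset=0.8):
    rng = np.random.default_rng(seed)
    dat = rng.normal(0, 1, (m, n)) + rng.normal(0, 1.5, (m, 1))
    batch = np.repeat([0, 1], n // 2)
    dat[:, batch == 1] += offset
    return dat, batch


class TestCombatFit:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(2)
        dat = rng.normal(0, 1, (100, 12))
        fit = combat_fit(dat, np.zeros(12, dtype=int))
        out = combat_apply(dat, fit, np.zeros(12, dtype=int))
        assert np.abs(out - dat).max() < 1e-6

    def test_constant_offset_equalizes_batch_means(self):
        dat, batch = _two_batch_data(seed=3)
        before = dat[:, batch == 0].mean() - dat[:, batch == 1].mean()
        fit = combat_fit(dat, batch)
        out = combat_apply(dat, fit, batch)
        after = out[:, batch == 0].mean() - out[:, batch == 1].mean()
        # the grand batch-mean difference is essentially removed and the
        # per-probe residual batch differences shrink sharply
        assert abs(after) < 0.02 * abs(before)
        rms_before = np.sqrt(
            ((dat[:, batch == 0].mean(1) - dat[:, batch == 1].mean(1)) ** 2).mean()
        )
        rms_after = np.sqrt(
            ((out[:, batch == 0].mean(1) - out[:, batch == 1].mean(1)) ** 2).mean()
        )
        assert rms_after < rms_before / 3

    def test_refit_after_apply_shrinks_locations(self):
        # batches large enough that the refitted locations are not dominated
        # by their ~1/sqrt(n_batch) sampling noise floor
        dat, batch = _two_batch_data(seed=4, m=400, n=400, offset=1.5)
        fit = combat_fit(dat, batch)
        out = combat_apply(dat, fit, batch)
        refit = combat_fit(out, batch)
        assert np.abs(refit.gamma_hat).mean() < np.abs(fit.gamma_hat).mean() / 10

    def test_eb_shrinks_toward_prior_mean(self):
        dat, batch = _two_batch_data(seed=5)
        fit = combat_fit(dat, batch)
        raw = np.abs(fit.gamma_hat - fit.gamma_bar[:, None]).mean()
        post = np.abs(fit.gamma_star - fit.gamma_bar[:, None]).mean()
        assert post <= raw

    def test_posterior_scales_positive_and_converged(self):
        dat, batch = _two_batch_data(seed=6)
        fit = combat_fit(dat, batch)
        assert (fit.delta_star > 0).all()
        assert fit.converged.all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_always_finite(self, seed):
        rng = np.random.default_rng(seed)
        dat = rng.normal(0, rng.uniform(0.1, 3), (200, 18)) + rng.normal(
            0, 2, (200, 1)
        )
        batch = rng.integers(0, 3, 18)
        while np.bincount(batch, minlength=3).min() < 2:
            batch = rng.integers(0, 3, 18)
        fit = combat_fit(dat, batch)
        out = combat_apply(dat, fit, batch)
        assert np.isfinite(out).all()

    def test_variance_of_batch_means_never_grows(self):
        dat, batch = _two_batch_data(seed=7, offset=0.3)
        fit = combat_fit(dat, batch)
        out = combat_apply(dat, fit, batch)

        def batch_mean_var(x):
            means = np.stack([x[:, batch == b].mean(1) for b in (0, 1)])
            return means.var(axis=0).mean()

        assert batch_mean_var(out) <= batch_mean_var(dat)

    def test_singleton_batch_rejected(self):
        dat = np.random.default_rng(8).normal(size=(50, 5))
        with pytest.raises(ValueError, match="fewer than 2"):
            combat_fit(dat, np.array([0, 0, 0, 0, 1]))

    def test_nonparametric_not_implemented(self):
        dat, batch = _two_batch_data()
        with pytest.raises(NotImplementedError):
            combat_fit(dat, batch, parametric=False)

    def test_confounded_covariate_dropped_with_warning(self):
        dat, batch = _two_batch_data(seed=9)
        group = batch.astype(float)  # outcome identical to batch
        with pytest.warns(UserWarning, match="confounded"):
            fit = combat_fit(
                dat, batch, variant="WITH_OUTCOME_MODEL", group=group
            )
        assert fit.covariates_dropped
        assert fit.coef_covariates.shape[0] == 0


class TestReferenceOracle:
    """Elementwise agreement with an independent R implementation (sva)."""

    @pytest.mark.parametrize("with_mod", [False, True])
    def test_matches_reference_on_200x12(self, tmp_path, with_mod):
        rng = np.random.default_rng(42)
        dat = rng.normal(0, 1, (200, 12)) + rng.normal(0, 2, (200, 1))
        batch = np.array([0] * 6 + [1] * 6)
        dat[:, batch == 1] += rng.normal(0.5, 0.3, (200, 1))
        group = np.tile([0, 1], 6)
        dat = save_matrix(tmp_path / "dat.csv", dat)
        np.savetxt(tmp_path / "batch.txt", batch + 1, fmt="%d")
        np.savetxt(tmp_path / "group.txt", group, fmt="%d")
        args = [
            tmp_path / "dat.csv",
            tmp_path / "batch.txt",
            tmp_path / "out.csv",
        ]
        if with_mod:
            args.append(tmp_path / "group.txt")
        run_r_oracle("combat_reference.R", *args)
        ref = np.loadtxt(tmp_path / "out.csv", delimiter=",")
        if with_mod:
            fit = combat_fit(
                dat, batch, variant="WITH_OUTCOME_MODEL", group=group.astype(float)
            )
            mine = combat_apply(dat, fit, batch, covariates=group.astype(float))
        else:
            fit = combat_fit(dat, batch)
            mine = combat_apply(dat, fit, batch)
        assert np.abs(mine - ref).max() < 1e-6


class TestSequentialCorrect:
    def test_empty_factor_list_is_identity(self, null_betas, layout48_random):
        out = sequential_correct(null_betas, layout48_random, factors=())
        np.testing.assert_array_equal(out.values, null_betas.values)

    def test_two_pass_row_chip(self, null_betas, layout48_random):
        out = sequential_correct(
            null_betas, layout48_random, ("row", "chip"), "NO_MODEL"
        )
        assert out.provenance == "corrected"
        assert out.values.shape == null_betas.values.shape
        assert np.isfinite(out.values).all()

    def test_variants_differ_on_unbalanced_input(
        self, small_profile, layout48_unbalanced
    ):
        from methbatch import generate_null_betas

        betas = generate_null_betas(small_profile, layout48_unbalanced, seed=13)
        a = sequential_correct(betas, layout48_unbalanced, ("row", "chip"), "NO_MODEL")
        b = sequential_correct(
            betas, layout48_unbalanced, ("row", "chip"), "WITH_OUTCOME_MODEL"
        )
        assert np.abs(a.values - b.values).max() > 0

    def test_none_variant_rejected(self, null_betas, layout48_random):
        with pytest.raises(ValueError):
            sequential_correct(null_betas, layout48_random, ("row",), "NONE")


class TestComBatCorrectorEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = ComBatCorrector(variant="NO_MODEL", tol=1e-5)
        assert est.get_params()["tol"] == 1e-5
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_matches_functional_path(self):
        dat, batch = _two_batch_data(seed=10)
        fit = combat_fit(dat, batch)
        expected = combat_apply(dat, fit, batch)
        est = ComBatCorrector(variant="NO_MODEL").fit(dat.T, batch=batch)
        np.testing.assert_allclose(est.transform(dat.T), expected.T, atol=1e-12)

    def test_outcome_model_requires_y(self):
        dat, batch = _two_batch_data(seed=11)
        with pytest.raises(ValueError, match="requires y"):
            ComBatCorrector(variant="WITH_OUTCOME_MODEL").fit(dat.T, batch=batch)

    def test_fitted_attributes(self):
        dat, batch = _two_batch_data(seed=12)
        y = np.tile([0, 1], 8)
        est = ComBatCorrector(variant="WITH_OUTCOME_MODEL").fit(dat.T, y, batch=batch)
        assert est.fit_.gamma_star.shape == (2, 300)
        assert est.n_features_in_ == 300
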