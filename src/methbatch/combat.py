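"""Parametric empirical-Bayes batch correction (the ComBat algorithm).

The algorithm adjusts, per probe, the location and scale of each batch:

1. fit a per-probe linear model over batch indicators (plus, optionally, a
   protected outcome/covariate design) and standardize the data by the
   pooled variance;
2. estimate per-batch location (gamma_hat) and scale (delta_hat) of the
   standardized residuals;
3. shrink them toward common priors fitted across probes by method of
   moments — a normal prior for locations and an inverse-gamma prior for
   scales — via a per-batch fixed-point iteration for the posteriors
   (gamma_star, delta_star);
4. remove gamma_star, divide by sqrt(delta_star), and de-standardize,
   restoring any protected covariate effects.

Correction is usually applied on the M-value (logit) scale.  When the
protected covariate design is collinear with the batch indicators (a batch
factor perfectly confounded with the outcome) no such model can be fitted;
the covariates are then dropped for that factor with a loud warning and the
fit is flagged, mirroring how correction tools refuse or degrade on fully
confounded designs while letting a simulation run proceed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .layout import SampleLayout
from .simulate import BetaMatrix, clamp_betas


class CorrectionVariant(str, enum.Enum):
    """How the outcome of interest enters the correction.

    WITH_OUTCOME_MODEL — the case/control indicator is a protected covariate
    of the standardization model (the behaviour of pipeline-integrated
    correction, which passes the outcome automatically, and of a direct call
    with a model matrix).
    NO_MODEL — intercept-only standardization; batch effects are estimated
    ignoring the outcome.
    NONE — no correction at all.
    """

    WITH_OUTCOME_MODEL = "WITH_OUTCOME_MODEL"
    NO_MODEL = "NO_MODEL"
    NONE = "NONE"


def to_mvalues(values: np.ndarray, eps: float = 0.001) -> np.ndarray:
    """Beta -> M transform, log2(beta / (1 - beta)); assumes clamped input."""
    v = np.asarray(values, dtype=float)
    return np.log2(v / (1.0 - v))


def from_mvalues(mvalues: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_mvalues`."""
    m = np.asarray(mvalues, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


@dataclass
class CombatFit:
    """Standardization parameters and EB posteriors for one correction pass."""

    batch_levels: np.ndarray
    n_per_batch: np.ndarray
    grand_mean: np.ndarray          # per-probe weighted grand effect
    var_pooled: np.ndarray          # per-probe pooled variance
    coef_covariates: np.ndarray     # (k, probes) protected covariate effects
    gamma_hat: np.ndarray           # (batches, probes) raw locations
    delta_hat: np.ndarray           # (batches, probes) raw scales
    gamma_star: np.ndarray          # EB posterior locations
    delta_star: np.ndarray          # EB posterior scales
    gamma_bar: np.ndarray           # prior means, one per batch
    tau2: np.ndarray                # prior variances, one per batch
    a_prior: np.ndarray             # inverse-gamma shape, one per batch
    b_prior: np.ndarray             # inverse-gamma rate, one per batch
    n_iter: np.ndarray              # fixed-point iterations per batch
    converged: np.ndarray           # convergence flag per batch
    covariates_dropped: bool = False

    def summary(self) -> dict:
        """JSON-friendly hyperparameter and convergence summary."""
        return {
            "batch_levels": [int(x) for x in self.batch_levels],
            "n_per_batch": [int(x) for x in self.n_per_batch],
            "gamma_bar": [float(x) for x in self.gamma_bar],
            "tau2": [float(x) for x in self.tau2],
            "a_prior": [float(x) for x in self.a_prior],
            "b_prior": [float(x) for x in self.b_prior],
            "n_iter": [int(x) for x in self.n_iter],
            "converged": [bool(x) for x in self.converged],
            "covariates_dropped": self.covariates_dropped,
        }


def _as_codes(batch) -> tuple[np.ndarray, np.ndarray]:
    batch = np.asarray(batch)
    levels, codes = np.unique(batch, return_inverse=True)
    return levels, codes


def combat_fit(
    values: np.ndarray,
    batch,
    variant: CorrectionVariant | str = CorrectionVariant.NO_MODEL,
    group: np.ndarray | None = None,
    parametric: bool = True,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> CombatFit:
    """Fit the parametric EB batch model to a probes x samples matrix.

    ``group`` (a 0/1 indicator or covariate matrix of shape (samples, k))
    is protected during standardization when ``variant`` is
    WITH_OUTCOME_MODEL.  Every batch level needs at least two samples.  Only
    the parametric prior pathway is implemented.
    """
    variant = CorrectionVariant(variant)
    if variant is CorrectionVariant.NONE:
        raise ValueError("variant NONE means no correction; nothing to fit")
    if not parametric:
        raise NotImplementedError("nonparametric prior pathway is not implemented")
    dat = np.asarray(values, dtype=float)
    if dat.ndim != 2:
        raise ValueError("values must be a probes x samples matrix")
    m, n = dat.shape
    levels, codes = _as_codes(batch)
    if len(codes) != n:
        raise ValueError("batch length does not match sample count")
    nb = len(levels)
    counts = np.bincount(codes, minlength=nb)
    if (counts < 2).any():
        bad = levels[counts < 2]
        raise ValueError(f"batch level(s) {bad.tolist()} have fewer than 2 samples")

    batchmod = np.zeros((n, nb))
    batchmod[np.arange(n), codes] = 1.0

    cov = None
    if variant is CorrectionVariant.WITH_OUTCOME_MODEL:
        if group is None:
            raise ValueError("WITH_OUTCOME_MODEL requires group labels")
        cov = np.asarray(group, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # drop constant covariate columns (an intercept is implicit in the
        # batch indicators)
        keep = ~np.all(cov == cov[0], axis=0)
        cov = cov[:, keep] if keep.any() else None

    covariates_dropped = False
    if cov is not None:
        design = np.column_stack([batchmod, cov])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            warnings.warn(
                "protected covariates are confounded with the batch factor; "
                "dropping them for this correction pass (the batch model "
                "cannot separate outcome from batch on this design)",
                UserWarning,
                stacklevel=2,
            )
            cov = None
            covariates_dropped = True
    design = batchmod if cov is None else np.column_stack([batchmod, cov])

    # per-probe standardization fit (OLS; design is full rank here)
    bhat, *_ = np.linalg.lstsq(design, dat.T, rcond=None)  # (p, m)
    grand_mean = (counts / n) @ bhat[:nb]
    resid = dat - (design @ bhat).T
    var_pooled = np.einsum("ij,ij->i", resid, resid) / n
    if not np.all(np.isfinite(var_pooled)) or (var_pooled <= 0).any():
        raise FloatingPointError("non-positive or non-finite pooled variance")
    coef_cov = bhat[nb:] if cov is not None else np.empty((0, m))

    stand_mean = grand_mean[:, None] + (
        (design[:, nb:] @ coef_cov).T if cov is not None else 0.0
    )
    sd = np.sqrt(var_pooled)[:, None]
    s_data = (dat - stand_mean) / sd
    if not np.all(np.isfinite(s_data)):
        raise FloatingPointError("non-finite standardized values")

    gamma_hat = np.empty((nb, m))
    delta_hat = np.empty((nb, m))
    for i in range(nb):
        sub = s_data[:, codes == i]
        gamma_hat[i] = sub.mean(axis=1)
        delta_hat[i] = sub.var(axis=1, ddof=1)

    # method-of-moments hyperpriors across probes
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = (2.0 * d_var + d_mean**2) / d_var
        b_prior = (d_mean * d_var + d_mean**3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    n_iter = np.zeros(nb, dtype=int)
    converged = np.zeros(nb, dtype=bool)
    if nb == 1:
        # a single batch carries no batch structure; the adjustment is the
        # identity (gamma* = 0, delta* = 1) rather than a degenerate EB fit
        gamma_star[:] = 0.0
        delta_star[:] = 1.0
        converged[:] = True
        return CombatFit(
            batch_levels=levels,
            n_per_batch=counts,
            grand_mean=grand_mean,
            var_pooled=var_pooled,
            coef_covariates=coef_cov,
            gamma_hat=gamma_hat,
            delta_hat=delta_hat,
            gamma_star=gamma_star,
            delta_star=delta_star,
            gamma_bar=gamma_bar,
            tau2=tau2,
            a_prior=a_prior,
            b_prior=b_prior,
            n_iter=n_iter,
            converged=converged,
            covariates_dropped=covariates_dropped,
        )
    for i in range(nb):
        sub = s_data[:, codes == i]
        ni = counts[i]
        g_old = gamma_hat[i].copy()
        d_old = delta_hat[i].copy()
        for it in range(1, max_iter + 1):
            g_new = (tau2[i] * ni * gamma_hat[i] + d_old * gamma_bar[i]) / (
                tau2[i] * ni + d_old
            )
            sum2 = np.einsum("ij,ij->i", sub - g_new[:, None], sub - g_new[:, None])
            d_new = (0.5 * sum2 + b_prior[i]) / (ni / 2.0 + a_prior[i] - 1.0)
            # signed denominators mirror the reference fixed point exactly:
            # probes with a negative previous location contribute negative
            # ratios and thus never dominate the max
            with np.errstate(divide="ignore", invalid="ignore"):
                change = max(
                    np.max(np.abs(g_new - g_old) / g_old),
                    np.max(np.abs(d_new - d_old) / d_old),
                )
            g_old, d_old = g_new, d_new
            if change < tol:
                converged[i] = True
                break
        n_iter[i] = it
        gamma_star[i] = g_old
        delta_star[i] = d_old
    if not converged.all():
        warnings.warn(
            f"EB fixed point did not converge for batch level(s) "
            f"{levels[~converged].tolist()} within {max_iter} iterations",
            UserWarning,
            stacklevel=2,
        )
    if (delta_star <= 0).any():
        raise FloatingPointError("non-positive posterior scale")

    return CombatFit(
        batch_levels=levels,
        n_per_batch=counts,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        coef_covariates=coef_cov,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iter=n_iter,
        converged=converged,
        covariates_dropped=covariates_dropped,
    )


def combat_apply(
    values: np.ndarray,
    fit: CombatFit,
    batch,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Adjust a matrix with a fitted batch model.

    ``covariates`` are the protected covariate values of the samples being
    adjusted (same design as at fit time); required when the fit retained
    covariates.
    """
    dat = np.asarray(values, dtype=float)
    m, n = dat.shape
    if m != len(fit.var_pooled):
        raise ValueError("probe count does not match fit")
    levels, codes_all = np.unique(np.asarray(batch), return_inverse=True)
    if len(codes_all) != n:
        raise ValueError("batch length does not match sample count")
    if not np.array_equal(levels, fit.batch_levels):
        raise ValueError("batch levels differ from the fitted levels")
    k = fit.coef_covariates.shape[0]
    if k:
        if covariates is None:
            raise ValueError("fit retained covariates; pass their sample values")
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        keep = ~np.all(cov == cov[0], axis=0)
        cov = cov[:, keep]
        if cov.shape != (n, k):
            raise ValueError("covariate design does not match fit")
        stand_mean = fit.grand_mean[:, None] + (cov @ fit.coef_covariates).T
    else:
        stand_mean = np.broadcast_to(fit.grand_mean[:, None], (m, n)).copy()
    sd = np.sqrt(fit.var_pooled)[:, None]
    s_data = (dat - stand_mean) / sd
    out = np.empty_like(s_data)
    for i in range(len(levels)):
        sel = codes_all == i
        out[:, sel] = (
            s_data[:, sel] - fit.gamma_star[i][:, None]
        ) / np.sqrt(fit.delta_star[i])[:, None]
    adjusted = out * sd + stand_mean
    if not np.all(np.isfinite(adjusted)):
        raise FloatingPointError("non-finite values after adjustment")
    return adjusted


class ComBatCorrector(TransformerMixin, BaseEstimator):
    """Scikit-learn style empirical-Bayes batch-correction transformer.

    Operates on ``X`` of shape (n_samples, n_features) following the
    scikit-learn convention (transpose of the probes x samples layout used
    elsewhere in this package).

    Parameters
    ----------
    variant:
        ``WITH_OUTCOME_MODEL`` to protect the outcome labels ``y`` during
        standardization, ``NO_MODEL`` for intercept-only standardization.
    parametric:
        Only the parametric prior pathway exists; ``False`` raises.
    tol, max_iter:
        Fixed-point stopping rule for the EB posteriors.

    Attributes
    ----------
    fit_ : CombatFit
        Full standardization and shrinkage state.
    batch_ : ndarray
        Batch labels seen at fit time.
    """

    def __init__(
        self,
        variant: str = "NO_MODEL",
        parametric: bool = True,
        tol: float = 1e-4,
        max_iter: int = 500,
    ) -> None:
        self.variant = variant
        self.parametric = parametric
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, *, batch=None):
        if batch is None:
            raise ValueError("ComBatCorrector.fit requires batch labels")
        X = np.asarray(X, dtype=float)
        group = None
        if CorrectionVariant(self.variant) is CorrectionVariant.WITH_OUTCOME_MODEL:
            if y is None:
                raise ValueError("variant WITH_OUTCOME_MODEL requires y")
            y = np.asarray(y)
            group = (
                y.astype(float)
                if np.issubdtype(y.dtype, np.number)
                else (y == np.unique(y)[-1]).astype(float)
            )
            self._group_fit = group
        else:
            self._group_fit = None
        self.fit_ = combat_fit(
            X.T,
            batch,
            variant=self.variant,
            group=group,
            parametric=self.parametric,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.batch_ = np.asarray(batch)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, batch=None, y=None):
        if not hasattr(self, "fit_"):
            raise ValueError("ComBatCorrector is not fitted")
        X = np.asarray(X, dtype=float)
        if batch is None:
            if X.shape[0] != len(self.batch_):
                raise ValueError("pass batch labels to transform new samples")
            batch = self.batch_
        cov = None
        if self.fit_.coef_covariates.shape[0]:
            if y is not None:
                yarr = np.asarray(y)
                cov = (
                    yarr.astype(float)
                    if np.issubdtype(yarr.dtype, np.number)
                    else (yarr == np.unique(yarr)[-1]).astype(float)
                )
            else:
                cov = self._group_fit
        return combat_apply(X.T, self.fit_, batch, covariates=cov).T

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def sequential_correct(
    betas: BetaMatrix,
    layout: SampleLayout,
    factors: tuple[str, ...] = ("row", "chip"),
    variant: CorrectionVariant | str = CorrectionVariant.WITH_OUTCOME_MODEL,
    on_mvalues: bool = True,
    eps: float = 0.001,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> BetaMatrix:
    """Correct one batch factor at a time, in order, feeding each pass the next.

    Mirrors a pipeline loop over batch names: the EB model is single-factor,
    so multi-factor correction is sequential.  By default the matrix is
    moved to the M-value scale first and back-transformed (with clamping)
    at the end.  ``factors=()`` is the identity.
    """
    variant = CorrectionVariant(variant)
    if variant is CorrectionVariant.NONE:
        raise ValueError("variant NONE performs no correction; do not call")
    if not factors:
        return betas.copy_with(betas.values.copy(), provenance=betas.provenance)
    group = (
        layout.group_indicator().astype(float)
        if variant is CorrectionVariant.WITH_OUTCOME_MODEL
        else None
    )
    work = to_mvalues(betas.values, eps) if on_mvalues else betas.values.copy()
    for factor in factors:
        codes = layout.factor_codes(factor)
        fit = combat_fit(
            work,
            codes,
            variant=variant,
            group=group,
            tol=tol,
            max_iter=max_iter,
        )
        cov = None if fit.coef_covariates.shape[0] == 0 else group
        work = combat_apply(work, fit, codes, covariates=cov)
    values = clamp_betas(from_mvalues(work), eps) if on_mvalues else work
    return betas.copy_with(values, provenance="corrected")
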