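"""Probe-wise differential methylation statistics and inflation metrics.

Each probe is tested for a case-vs-control difference with a two-group
linear model whose residual variances are moderated by empirical Bayes:
the per-probe sample variances s2_j (df residual degrees of freedom each)
are assumed to follow a scaled F distribution around a prior variance s0^2
with prior degrees of freedom d0, both estimated across probes by the
method of moments on log s2_j.  The moderated t statistic uses the
shrunken variance s~2_j = (d0 s0^2 + df s2_j) / (d0 + df) and is referred
to a t distribution with d0 + df degrees of freedom.

Calibration of the resulting p-value set is summarized by the arithmetic
mean p, the genomic inflation factor lambda (median of the chi-square(1)
equivalents of the p-values over the null median 0.4549...), and the
counts of Benjamini-Hochberg FDR- and Bonferroni-significant probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .simulate import BetaMatrix

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))

_VAR_FLOOR = 1e-300


@dataclass
class DMPResult:
    """Per-probe differential methylation test results."""

    probe_ids: np.ndarray
    effect: np.ndarray            # case minus control mean difference
    s2: np.ndarray                # residual variance
    df_residual: float
    t: np.ndarray                 # moderated t
    p_value: np.ndarray
    df_prior: float               # d0 (may be inf: complete shrinkage)
    s2_prior: float               # s0^2
    df_total: np.ndarray
    q_bh: np.ndarray
    p_bonferroni: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # flagged floored probes

    @property
    def n_probes(self) -> int:
        return len(self.p_value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "effect": self.effect,
                "t": self.t,
                "p": self.p_value,
                "q_bh": self.q_bh,
                "p_bonf": self.p_bonferroni,
            }
        )


@dataclass
class MetricsSummary:
    """The results surface of one simulation run."""

    mean_p: float
    lam: float
    n_fdr: int
    n_bf: int
    n_probes: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_p <= 1.0:
            raise ValueError("mean_p outside [0, 1]")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not self.n_bf <= self.n_fdr <= self.n_probes:
            raise ValueError("expected n_bf <= n_fdr <= n_probes")

    def to_dict(self) -> dict:
        d = {
            "mean_p": self.mean_p,
            "lambda": self.lam,
            "n_fdr": self.n_fdr,
            "n_bf": self.n_bf,
            "n_probes": self.n_probes,
        }
        d.update(self.metadata)
        return d


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df1: float) -> tuple[float, float]:
    """Moments-of-log-variance fit of the scaled F model for s2_j.

    Returns (s0^2, d0); d0 = inf when the observed spread of log s2 is no
    larger than expected from sampling alone (complete shrinkage).
    """
    z = np.log(s2)
    e = z - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, df1 / 2.0))
    if e_var > 0:
        half_d0 = _trigamma_inverse(e_var)
        d0 = 2.0 * half_d0
        s20 = float(np.exp(e_mean + digamma(half_d0) - np.log(half_d0)))
    else:
        # spread of log s2 no larger than sampling alone: infinite prior df,
        # and the prior variance is the plain average of the variances
        d0 = np.inf
        s20 = float(s2.mean())
    return s20, d0


def fit_dmp(
    values: BetaMatrix | np.ndarray,
    groups: np.ndarray,
    probe_ids: np.ndarray | None = None,
    moderated: bool = True,
) -> DMPResult:
    """Two-group moderated-t test per probe.

    ``groups`` is a 0/1 case indicator (or case/control labels).  With
    ``moderated=False`` the ordinary pooled-variance t-test is returned
    (prior weight disabled), useful as an analytic cross-check.
    """
    if isinstance(values, BetaMatrix):
        mat = values.values
        if probe_ids is None:
            probe_ids = values.probe_ids
    else:
        mat = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if g.dtype.kind not in "biu":
        g = (g == "case").astype(int)
    g = g.astype(int)
    if mat.shape[1] != len(g):
        raise ValueError("groups length does not match sample count")
    n1 = int((g == 1).sum())
    n2 = int((g == 0).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    if probe_ids is None:
        probe_ids = np.arange(mat.shape[0])

    case = mat[:, g == 1]
    ctrl = mat[:, g == 0]
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    df = float(n1 + n2 - 2)
    rss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / df
    zero_var = s2 < _VAR_FLOOR
    s2 = np.maximum(s2, _VAR_FLOOR)

    if moderated:
        s2_prior, df_prior = _fit_f_dist(s2, df)
        if np.isfinite(df_prior):
            s2_post = (df_prior * s2_prior + df * s2) / (df_prior + df)
        else:
            s2_post = np.full_like(s2, s2_prior)
        df_total = np.minimum(df + df_prior, df * len(s2))
    else:
        s2_prior, df_prior = float("nan"), 0.0
        s2_post = s2
        df_total = np.full_like(s2, df)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = effect / se
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q_bh, p_bonf = adjust_multiplicity(p)
    return DMPResult(
        probe_ids=np.asarray(probe_ids),
        effect=effect,
        s2=s2,
        df_residual=df,
        t=t,
        p_value=p,
        df_prior=df_prior,
        s2_prior=s2_prior,
        df_total=df_total,
        q_bh=q_bh,
        p_bonferroni=p_bonf,
        zero_variance=zero_var,
    )


class ModeratedTTest(BaseEstimator):
    """Scikit-learn style estimator for the per-probe moderated t-test.

    ``fit(X, y)`` takes ``X`` of shape (n_samples, n_probes) and binary
    labels ``y``; fitted attributes carry per-probe statistics.

    Attributes
    ----------
    effect_, t_, p_value_, q_value_, p_bonferroni_ : ndarray, per probe
    df_prior_, s2_prior_ : float, shared moderation hyperparameters
    """

    def __init__(self, moderated: bool = True) -> None:
        self.moderated = moderated

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        res = fit_dmp(X.T, np.asarray(y), moderated=self.moderated)
        self.result_ = res
        self.effect_ = res.effect
        self.t_ = res.t
        self.p_value_ = res.p_value
        self.q_value_ = res.q_bh
        self.p_bonferroni_ = res.p_bonferroni
        self.df_prior_ = res.df_prior
        self.s2_prior_ = res.s2_prior
        self.n_features_in_ = X.shape[1]
        return self


def adjust_multiplicity(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg q-values and Bonferroni-adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q_bh = multipletests(p, alpha=0.05, method="fdr_bh")[1]
    p_bonf = np.minimum(1.0, p * len(p))
    return q_bh, p_bonf


def lambda_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor of a p-value set.

    lambda = median(chi2_1 quantile of 1 - p) / median(chi2_1); equals 1 in
    expectation for uniform p, exceeds 1 under inflation.  p-values of
    exactly 0 are mapped to the largest finite quantile with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn(
            "p-values of 0 mapped to the largest finite quantile", stacklevel=2
        )
        tiny = np.finfo(float).tiny
        p = np.maximum(p, tiny)
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def qq_points(p: np.ndarray) -> pd.DataFrame:
    """Observed vs expected -log10 p for a Q-Q plot.

    Expected quantiles use the (i - 0.5) / m order-statistic positions;
    observed values are sorted so row i pairs the i-th smallest p with the
    i-th smallest expected value.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value set")
    m = p.size
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.sort(p))
    return pd.DataFrame({"expected": expected[::-1], "observed": observed[::-1]})


def summarize_metrics(
    dmp: DMPResult,
    alpha: float = 0.05,
    metadata: dict | None = None,
) -> MetricsSummary:
    """Collapse a DMP result into the run-level metrics."""
    return MetricsSummary(
        mean_p=float(dmp.p_value.mean()),
        lam=lambda_inflation(dmp.p_value),
        n_fdr=int((dmp.q_bh < alpha).sum()),
        n_bf=int((dmp.p_bonferroni < alpha).sum()),
        n_probes=dmp.n_probes,
        metadata=dict(metadata or {}),
    )
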