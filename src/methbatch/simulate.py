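"""Null beta-matrix generation, batch-offset injection, and effect spike-in.

The simulator draws every value independently from Normal(mu_j, sd_j^2)
using the per-probe profile parameters, so the data carry no biological
signal and no batch structure by construction; anything a downstream
analysis "finds" in them is false.  Two optional perturbations are layered
on top:

* **batch offsets** — one Uniform(-a, +a) brightness offset per level of
  each batch factor (default amplitude a = 0.01 beta units, i.e. +/-1%),
  added to *all* probes of the affected samples;
* **spiked group effects** — a set of probes receives a calibrated mean
  shift in the case group so that the expected two-sample t-test p-value
  equals a chosen target, used to measure detection sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .layout import SampleLayout
from .params import CpGParameterProfile

#: Clamp margin keeping beta values inside (0, 1) for the logit transform.
BETA_EPS = 0.001

#: Default spike-in targets: two-sided p-values 1e-1 .. 1e-20.
DEFAULT_SPIKE_TARGETS: tuple[float, ...] = tuple(10.0 ** -k for k in range(1, 21))


@dataclass
class BetaMatrix:
    """Probes x samples methylation matrix with provenance flags."""

    values: np.ndarray
    probe_ids: np.ndarray
    sample_ids: np.ndarray
    provenance: str = "null"
    truth_mask: np.ndarray | None = None
    spike_target_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.truth_mask is None:
            self.truth_mask = np.zeros(len(self.probe_ids), dtype=bool)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray, provenance: str) -> "BetaMatrix":
        return BetaMatrix(
            values=values,
            probe_ids=self.probe_ids,
            sample_ids=self.sample_ids,
            provenance=provenance,
            truth_mask=None if self.truth_mask is None else self.truth_mask.copy(),
            spike_target_p=(
                None if self.spike_target_p is None else self.spike_target_p.copy()
            ),
        )


@dataclass
class BatchEffectSpec:
    """Record of injected per-level offsets for each batch factor."""

    amplitude: float
    offsets: dict = field(default_factory=dict)  # (factor, level) -> offset
    seed: int | None = None

    def validate(self) -> None:
        for key, off in self.offsets.items():
            if abs(off) > self.amplitude + 1e-12:
                raise ValueError(f"offset {off} for {key} exceeds amplitude")


@dataclass
class SpikeSpec:
    """Specification of spiked true group effects.

    ``n_sites`` probes are drawn at random and split as equally as possible
    across ``target_p_values``; each receives a shift calibrated (via
    :func:`calibrate_effect_shift`, using the probe's own profile SD) to
    yield that expected two-sided p-value.
    """

    n_sites: int = 2000
    target_p_values: tuple[float, ...] = DEFAULT_SPIKE_TARGETS
    seed: int = 0

    def validate(self) -> None:
        if any(not (0.0 < p < 1.0) for p in self.target_p_values):
            raise ValueError("all target p-values must be in (0, 1)")
        if 0 < self.n_sites < len(self.target_p_values):
            raise ValueError("need at least one site per target p-value")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")

    def allocation(self) -> np.ndarray:
        """Target p for each spiked site, sizes as equal as possible."""
        self.validate()
        k = len(self.target_p_values)
        reps = np.arange(self.n_sites) % k
        return np.asarray(self.target_p_values, dtype=float)[reps]


def clamp_betas(values: np.ndarray, eps: float = BETA_EPS) -> np.ndarray:
    """Clip beta values into [eps, 1 - eps]."""
    return np.clip(values, eps, 1.0 - eps)


def generate_null_betas(
    profile: CpGParameterProfile,
    layout: SampleLayout,
    seed: int,
    eps: float = BETA_EPS,
) -> BetaMatrix:
    """Draw a pure-noise beta matrix from the profile over the layout.

    Each entry is an independent Normal(mu_j, sd_j^2) draw clamped into
    [eps, 1-eps].  Deterministic given ``seed``.
    """
    if profile.n_probes == 0 or layout.n_samples == 0:
        raise ValueError("profile and layout must be non-empty")
    rng = np.random.default_rng(seed)
    mu = profile.mean_beta[:, None]
    sd = profile.sd_beta[:, None]
    values = rng.normal(mu, sd, size=(profile.n_probes, layout.n_samples))
    return BetaMatrix(
        values=clamp_betas(values, eps),
        probe_ids=profile.probe_ids,
        sample_ids=layout.sample_ids,
        provenance="null",
    )


def inject_batch_effects(
    betas: BetaMatrix,
    layout: SampleLayout,
    factors: tuple[str, ...] = ("row", "chip"),
    amplitude: float = 0.01,
    seed: int = 0,
    eps: float = BETA_EPS,
) -> tuple[BetaMatrix, BatchEffectSpec]:
    """Add a constant brightness offset per batch-factor level.

    For every factor and every one of its levels one offset is drawn from
    Uniform(-amplitude, +amplitude); each sample receives the sum of the
    offsets of the levels it belongs to, added to all of its probe values.
    """
    if betas.n_samples != layout.n_samples:
        raise ValueError("beta matrix and layout sample counts differ")
    rng = np.random.default_rng(seed)
    spec = BatchEffectSpec(amplitude=amplitude, seed=seed)
    shift = np.zeros(betas.n_samples)
    for factor in factors:
        codes = layout.factor_codes(factor)  # raises KeyError on unknown factor
        levels = np.unique(codes)
        offsets = rng.uniform(-amplitude, amplitude, size=len(levels))
        for lev, off in zip(levels, offsets):
            spec.offsets[(factor, int(lev))] = float(off)
        shift += offsets[np.searchsorted(levels, codes)]
    values = clamp_betas(betas.values + shift[None, :], eps)
    spec.validate()
    return betas.copy_with(values, provenance="batch_injected"), spec


def calibrate_effect_shift(target_p: float, n1: int, n2: int, sd: float) -> float:
    """Mean shift giving a two-sample pooled-variance t-test p of ``target_p``.

    delta = t^{-1}(1 - p/2; df = n1 + n2 - 2) * sd * sqrt(1/n1 + 1/n2), the
    shift for which group means differing by exactly delta with common SD
    ``sd`` produce the requested two-sided p-value.
    """
    if not 0.0 < target_p < 1.0:
        raise ValueError("target_p must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    df = n1 + n2 - 2
    tcrit = stats.t.ppf(1.0 - target_p / 2.0, df)
    return float(tcrit * sd * np.sqrt(1.0 / n1 + 1.0 / n2))


def spike_group_effects(
    betas: BetaMatrix,
    layout: SampleLayout,
    spec: SpikeSpec,
    eps: float = BETA_EPS,
) -> BetaMatrix:
    """Add calibrated true case-vs-control effects to randomly chosen probes.

    Shifts are always positive (case > control); the probes' profile SD is
    estimated from the matrix itself (per-probe sample SD), so spiking can
    follow generation directly or after injection.
    """
    spec.validate()
    if spec.n_sites > betas.n_probes:
        raise ValueError("more spike sites than probes")
    group = layout.group_indicator()
    n1 = int(group.sum())
    n2 = int(len(group) - n1)
    if n1 < 2 or n2 < 2:
        raise ValueError("spiking requires two groups with >= 2 samples each")
    out = betas.copy_with(betas.values.copy(), provenance="spiked")
    if spec.n_sites == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    sites = rng.choice(betas.n_probes, size=spec.n_sites, replace=False)
    targets = spec.allocation()
    sd = betas.values[sites].std(axis=1, ddof=1)
    sd = np.maximum(sd, 1e-6)
    shifts = np.array(
        [calibrate_effect_shift(p, n1, n2, s) for p, s in zip(targets, sd)]
    )
    case_cols = np.flatnonzero(group == 1)
    out.values[np.ix_(sites, case_cols)] += shifts[:, None]
    out.values = clamp_betas(out.values, eps)
    mask = np.zeros(betas.n_probes, dtype=bool)
    mask[sites] = True
    out.truth_mask = mask
    target_p = np.full(betas.n_probes, np.nan)
    target_p[sites] = targets
    out.spike_target_p = target_p
    return out
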