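"""Per-CpG generative parameters for the beta-value simulator.

A :class:`CpGParameterProfile` holds, for every probe of an array platform,
the mean and standard deviation of its methylation beta value, plus the
Infinium probe design type (I or II).  Profiles are either loaded from a
descriptive-statistics table derived from real arrays, or emulated with a
bimodal mixture that mimics the landscape of a whole-blood EPIC profile:
most CpGs sit near fully unmethylated (~0.1) or fully methylated (~0.9),
with a minority of intermediate sites, and per-probe SDs are small and
right-skewed (median around 0.02 beta units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nominal probe counts per Illumina platform generation.  The EPIC figure is
#: the size of the empirical profile the simulation design is based on, not
#: the marketing number (~850k).
PLATFORM_SIZES: dict[str, int] = {"EPIC": 758_289, "K450": 450_000, "K27": 27_000}

#: Emulator mixture defaults: (weight, a, b) of three Beta components for the
#: per-probe mean — hypomethylated, hypermethylated, intermediate.
EMULATOR_MEAN_MIXTURE: tuple[tuple[float, float, float], ...] = (
    (0.45, 5.0, 45.0),
    (0.45, 45.0, 5.0),
    (0.10, 8.0, 8.0),
)
#: Emulator SD distribution: log-normal with this median (beta units) and
#: log-scale sigma, clipped into (SD_FLOOR, SD_CEILING].
EMULATOR_SD_MEDIAN: float = 0.02
EMULATOR_SD_SIGMA: float = 0.6
SD_FLOOR: float = 1e-4
SD_CEILING: float = 0.5
#: Fraction of type II probes (EPIC arrays are predominantly type II).
EMULATOR_TYPE2_FRACTION: float = 0.84

_REQUIRED_COLUMNS = ("probe_id", "mean_beta", "sd_beta")


@dataclass
class CpGParameterProfile:
    """Per-probe generative parameters plus platform annotation.

    Attributes
    ----------
    table:
        DataFrame with columns ``probe_id``, ``mean_beta``, ``sd_beta`` and
        ``design_type``; one row per probe.
    platform:
        One of ``EPIC``, ``K450``, ``K27``.
    n_dropped:
        Number of rows rejected during validation (out-of-range mean or
        non-positive SD).
    """

    table: pd.DataFrame
    platform: str = "EPIC"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_probes(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    @property
    def mean_beta(self) -> np.ndarray:
        return self.table["mean_beta"].to_numpy(dtype=float)

    @property
    def sd_beta(self) -> np.ndarray:
        return self.table["sd_beta"].to_numpy(dtype=float)

    def validate(self) -> None:
        """Enforce profile invariants; raise ``ValueError`` on violation."""
        t = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"profile table is missing columns {missing}")
        if "design_type" not in t.columns:
            self.table = t = t.assign(design_type="II")
        if len(t) == 0:
            raise ValueError("profile has zero probes")
        if t["probe_id"].duplicated().any():
            dup = t["probe_id"][t["probe_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        mean = t["mean_beta"].to_numpy(dtype=float)
        sd = t["sd_beta"].to_numpy(dtype=float)
        if ((mean < 0) | (mean > 1)).any():
            raise ValueError("mean_beta outside [0, 1]")
        if ((sd <= 0) | (sd > SD_CEILING)).any():
            raise ValueError(f"sd_beta outside (0, {SD_CEILING}]")
        bad_type = ~t["design_type"].isin(["I", "II"])
        if bad_type.any():
            raise ValueError("design_type must be 'I' or 'II' for every probe")


def load_parameter_table(
    path,
    platform: str = "EPIC",
    *,
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> CpGParameterProfile:
    """Load a per-CpG parameter table from delimited text.

    The expected columns are ``probe_id``, ``mean_beta``, ``sd_beta`` and
    optionally ``design_type``; ``columns`` maps these canonical names to the
    header names actually present in the file (the schema of descriptive
    tables distributed alongside array studies varies).  Gzipped files are
    read transparently.  Rows with a mean outside [0, 1] or a non-positive
    (or implausibly large, > 0.5) SD are dropped and counted in
    ``profile.n_dropped``.
    """
    if sep is None:
        sep = "\t" if str(path).rstrip(".gz").endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    if columns:
        raw = raw.rename(columns={v: k for k, v in columns.items()})
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"parameter table {path} lacks columns {missing}; "
            "use `columns` to map your header names"
        )
    if "design_type" not in raw.columns:
        raw = raw.assign(design_type="II")
    mean = pd.to_numeric(raw["mean_beta"], errors="coerce")
    sd = pd.to_numeric(raw["sd_beta"], errors="coerce")
    ok = mean.between(0.0, 1.0) & (sd > 0.0) & (sd <= SD_CEILING)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} invalid parameter rows from {path}",
            stacklevel=2,
        )
    kept = raw.loc[ok, ["probe_id", "mean_beta", "sd_beta", "design_type"]]
    kept = kept.astype({"mean_beta": float, "sd_beta": float}).reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError(f"no valid parameter rows in {path}")
    if kept["probe_id"].duplicated().any():
        raise ValueError(f"duplicate probe ids in {path}")
    return CpGParameterProfile(table=kept, platform=platform, n_dropped=n_dropped)


def write_parameter_table(profile: CpGParameterProfile, path, *, sep: str = ",") -> None:
    """Write a profile back to the delimited table format (round-trips)."""
    profile.table.to_csv(path, sep=sep, index=False)


def emulate_parameter_profile(
    n_probes: int,
    seed: int,
    platform: str = "EPIC",
) -> CpGParameterProfile:
    """Draw a synthetic per-CpG parameter profile.

    Means come from a three-component Beta mixture (bimodal, concentrated
    near 0.1 and 0.9 with a 10% intermediate component); SDs from a
    right-skewed log-normal with median :data:`EMULATOR_SD_MEDIAN`.  The
    emulated profile stands in for an empirical descriptive-statistics table
    when none is supplied; it is deterministic given ``seed``.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([w for w, _, _ in EMULATOR_MEAN_MIXTURE])
    comp = rng.choice(len(weights), size=n_probes, p=weights)
    mean = np.empty(n_probes)
    for i, (_, a, b) in enumerate(EMULATOR_MEAN_MIXTURE):
        sel = comp == i
        mean[sel] = rng.beta(a, b, size=int(sel.sum()))
    sd = rng.lognormal(np.log(EMULATOR_SD_MEDIAN), EMULATOR_SD_SIGMA, size=n_probes)
    sd = np.clip(sd, SD_FLOOR, SD_CEILING)
    design = np.where(rng.random(n_probes) < EMULATOR_TYPE2_FRACTION, "II", "I")
    table = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(n_probes)],
            "mean_beta": mean,
            "sd_beta": sd,
            "design_type": design,
        }
    )
    return CpGParameterProfile(table=table, platform=platform)


def subsample_platform(
    profile: CpGParameterProfile,
    target: str,
    seed: int,
    size: int | None = None,
) -> CpGParameterProfile:
    """Derive a smaller-platform profile by uniform sampling without replacement.

    ``size`` defaults to the target platform's nominal probe count
    (:data:`PLATFORM_SIZES`).  Sampling order is randomised but the result is
    deterministic given ``seed``.
    """
    if size is None:
        try:
            size = PLATFORM_SIZES[target]
        except KeyError:
            raise ValueError(f"unknown platform {target!r}") from None
    if size > profile.n_probes:
        raise ValueError(
            f"target size {size} exceeds source profile size {profile.n_probes}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(profile.n_probes, size=size, replace=False))
    table = profile.table.iloc[idx].reset_index(drop=True)
    return CpGParameterProfile(table=table, platform=target)
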