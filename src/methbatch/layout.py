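"""Physical sample layout of Illumina BeadChip measurements.

Samples sit in 8 row positions on a chip; 12 chips fill a sample plate
(96 samples).  Row, chip and plate are the technical batch factors.  The
case/control outcome can be arranged three ways relative to the chips:

``balanced``
    fully crossed — every chip carries 4 cases and 4 controls, with the
    case rows alternating between chips so that each row position hosts
    both groups equally often.
``unbalanced``
    maximally confounded while remaining estimable — cases fill chips
    contiguously, but the two chips at the group boundary are split half
    case / half control by row.  A *perfectly* confounded fill (whole
    chips per group) makes the outcome inseparable from the chip factor:
    no location/scale batch model that protects the outcome can be fitted
    to it, and batch-correction tools refuse it.  The boundary split is
    the closest estimable encoding of "cases on the first chips".
``random``
    a uniformly random permutation of n/2 case and n/2 control labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

_SHEET_COLUMNS = ["sample_id", "plate", "chip", "row", "group"]


@dataclass
class SampleLayout:
    """Mapping of samples to plate/chip/row positions and outcome groups.

    ``table`` has one row per sample with 1-based ``plate``, ``chip``
    (global index) and ``row`` (position within chip) columns, an optional
    ``group`` column, and one column per extra (sweep-generated) factor.
    """

    table: pd.DataFrame
    chip_size: int = 8
    chips_per_plate: int = 12
    extra_factors: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def n_chips(self) -> int:
        return int(self.table["chip"].nunique())

    @property
    def n_plates(self) -> int:
        return int(self.table["plate"].nunique())

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table["sample_id"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        if "group" not in self.table.columns:
            raise ValueError("no groups assigned; call assign_groups first")
        return self.table["group"].to_numpy()

    def group_indicator(self) -> np.ndarray:
        """0/1 indicator of case membership."""
        return (self.groups == CASE).astype(int)

    def factor_codes(self, name: str) -> np.ndarray:
        """Integer level codes (0-based) for a batch or sweep factor."""
        if name not in self.table.columns:
            raise KeyError(f"unknown factor {name!r}")
        return pd.Categorical(self.table[name]).codes.astype(int)

    def validate(self) -> None:
        t = self.table
        if (t.groupby("chip").size() > self.chip_size).any():
            raise ValueError(f"a chip holds more than {self.chip_size} samples")
        per_plate = t.groupby("plate")["chip"].nunique()
        if (per_plate > self.chips_per_plate).any():
            raise ValueError(f"a plate holds more than {self.chips_per_plate} chips")
        if t.duplicated(["chip", "row"]).any():
            raise ValueError("duplicate (chip, row) position")


def build_layout(
    n_samples: int,
    chip_size: int = 8,
    chips_per_plate: int = 12,
) -> SampleLayout:
    """Fill chips sequentially (chip 1 rows 1..8, then chip 2, ...).

    Chips fill plates sequentially; a partial last chip is allowed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    idx = np.arange(n_samples)
    chip = idx // chip_size + 1
    row = idx % chip_size + 1
    plate = (chip - 1) // chips_per_plate + 1
    table = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in idx],
            "plate": plate,
            "chip": chip,
            "row": row,
        }
    )
    layout = SampleLayout(table, chip_size=chip_size, chips_per_plate=chips_per_plate)
    layout.validate()
    return layout


def _unbalanced_labels(layout: SampleLayout) -> np.ndarray:
    """Contiguous case fill with an estimable (half-chip) group boundary."""
    n = layout.n_samples
    chip = layout.table["chip"].to_numpy()
    row = layout.table["row"].to_numpy()
    size = layout.chip_size
    n_case = n // 2
    labels = np.full(n, CONTROL, dtype=object)
    full_case_chips, rem = divmod(n_case, size)
    if rem == 0 and layout.n_chips >= 2 and size % 2 == 0:
        # whole-chip fill would confound group with chip exactly; split the
        # two boundary chips half/half by row instead
        half = size // 2
        labels[chip <= full_case_chips - 1] = CASE
        labels[(chip == full_case_chips) & (row <= half)] = CASE
        labels[(chip == full_case_chips + 1) & (row <= half)] = CASE
    else:
        # boundary chip is already mixed by the contiguous fill
        labels[np.arange(n) < n_case] = CASE
    return labels


def assign_groups(
    layout: SampleLayout,
    design: str,
    seed: int = 0,
) -> SampleLayout:
    """Assign case/control labels under a balanced, unbalanced or random design.

    Returns a new layout; the input is not modified.  ``seed`` only matters
    for the random design.  n must be even.
    """
    n = layout.n_samples
    if design not in ("balanced", "unbalanced", "random"):
        raise ValueError(f"unknown design {design!r}")
    if n % 2 != 0:
        raise ValueError(f"{design} design requires an even sample count, got {n}")
    chip = layout.table["chip"].to_numpy()
    row = layout.table["row"].to_numpy()
    if design == "balanced":
        labels = np.where((chip + row) % 2 == 0, CASE, CONTROL)
    elif design == "unbalanced":
        labels = _unbalanced_labels(layout)
    else:
        rng = np.random.default_rng(seed)
        labels = np.array([CASE] * (n // 2) + [CONTROL] * (n // 2), dtype=object)
        labels = rng.permutation(labels)
    table = layout.table.copy()
    table["group"] = labels
    out = SampleLayout(
        table,
        chip_size=layout.chip_size,
        chips_per_plate=layout.chips_per_plate,
        extra_factors=list(layout.extra_factors),
    )
    if (out.groups == CASE).sum() != n // 2:
        raise AssertionError("group assignment is not 50/50")
    return out


def batch_factor_table(layout: SampleLayout) -> pd.DataFrame:
    """Per-sample categorical level codes for the row/chip/plate factors."""
    t = layout.table
    return pd.DataFrame(
        {
            "sample_id": t["sample_id"],
            "row": pd.Categorical(t["row"]).codes.astype(int),
            "chip": pd.Categorical(t["chip"]).codes.astype(int),
            "plate": pd.Categorical(t["plate"]).codes.astype(int),
        }
    )


def make_sweep_factor(n_samples: int, n_levels: int, seed: int) -> np.ndarray:
    """Random factor with ``n_levels`` levels of as-equal-as-possible size.

    Level sizes differ by at most one; assignment to samples is a uniform
    random permutation, deterministic given ``seed``.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if n_levels > n_samples:
        raise ValueError(f"n_levels {n_levels} exceeds n_samples {n_samples}")
    rng = np.random.default_rng(seed)
    levels = np.arange(n_samples) % n_levels
    return rng.permutation(levels)


def add_factor(layout: SampleLayout, name: str, levels: np.ndarray) -> SampleLayout:
    """Attach an extra factor column (e.g. a sweep factor) to a layout."""
    if len(levels) != layout.n_samples:
        raise ValueError("factor length does not match sample count")
    table = layout.table.copy()
    table[name] = np.asarray(levels)
    return SampleLayout(
        table,
        chip_size=layout.chip_size,
        chips_per_plate=layout.chips_per_plate,
        extra_factors=list(layout.extra_factors) + [name],
    )


def write_sample_sheet(layout: SampleLayout, path, *, sep: str = ",") -> None:
    """Serialize to a minimal sample sheet (no vendor header block)."""
    cols = [c for c in _SHEET_COLUMNS if c in layout.table.columns]
    cols += layout.extra_factors
    layout.table[cols].to_csv(path, sep=sep, index=False)


def read_sample_sheet(
    path,
    *,
    sep: str = ",",
    chip_size: int = 8,
    chips_per_plate: int = 12,
) -> SampleLayout:
    table = pd.read_csv(path, sep=sep)
    extra = [c for c in table.columns if c not in _SHEET_COLUMNS]
    layout = SampleLayout(
        table,
        chip_size=chip_size,
        chips_per_plate=chips_per_plate,
        extra_factors=extra,
    )
    layout.validate()
    return layout
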