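"""Orchestration of the simulation studies.

Every experiment follows the same pipeline per repetition:

    generate null betas -> [spike true effects] -> [inject batch offsets]
        -> [sequential EB correction] -> moderated-t DMP -> metrics

with all randomness derived from a single master seed through independent
substreams (one per repetition and stage), so that a run is exactly
reproducible from its configuration.

The five studies are: the design x correction-variant grid at n = 48, the
factor-level sweep (one synthetic factor, growing level count), the
factor-count sweep (growing number of two-level factors, corrected
sequentially), the sample-size sweep (48..768 across the three designs),
the platform sweep (27K / 450K / EPIC probe counts), and the spike-in
detection study.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .combat import CorrectionVariant, sequential_correct
from .dmpstats import MetricsSummary, fit_dmp, summarize_metrics
from .layout import SampleLayout, add_factor, assign_groups, build_layout, make_sweep_factor
from .params import CpGParameterProfile, emulate_parameter_profile, subsample_platform
from .simulate import (
    SpikeSpec,
    generate_null_betas,
    inject_batch_effects,
    spike_group_effects,
)


@dataclass
class ScenarioConfig:
    """Configuration of one simulated scenario.

    ``n_probes`` defaults to a reduced-scale profile of 20,000 probes: the
    calibration metrics (mean p, lambda) are probe-count invariant in
    expectation and significant-site counts scale roughly linearly with the
    probe count, so scenarios run at reduced scale and counts can be read
    per probe.  Set ``n_probes`` to the full platform size for absolute
    counts.
    """

    n_samples: int = 48
    design: str = "random"
    variant: str = "WITH_OUTCOME_MODEL"
    factors: tuple[str, ...] = ("row", "chip")
    inject_batch: bool = True
    amplitude: float = 0.01
    spike: SpikeSpec | None = None
    platform: str = "EPIC"
    n_probes: int = 20_000
    n_reps: int = 100
    master_seed: int = 0
    chip_size: int = 8
    chips_per_plate: int = 12
    on_mvalues: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        CorrectionVariant(self.variant)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["factors"] = list(self.factors)
        if self.spike is not None:
            d["spike"] = {
                "n_sites": self.spike.n_sites,
                "target_p_values": list(self.spike.target_p_values),
                "seed": self.spike.seed,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if d.get("spike"):
            s = d["spike"]
            d["spike"] = SpikeSpec(
                n_sites=s.get("n_sites", 2000),
                target_p_values=tuple(s.get("target_p_values", ())) or SpikeSpec().target_p_values,
                seed=s.get("seed", 0),
            )
        if "factors" in d:
            d["factors"] = tuple(d["factors"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ResultTable:
    """Per-repetition metrics plus aggregates for one scenario or sweep cell."""

    rows: pd.DataFrame
    config: ScenarioConfig | None = None

    def aggregate(self) -> dict:
        agg = {}
        for col in ("mean_p", "lambda", "n_fdr", "n_bf"):
            if col in self.rows.columns:
                agg[f"{col}_mean"] = float(self.rows[col].mean())
                agg[f"{col}_sd"] = float(self.rows[col].std(ddof=1)) if len(self.rows) > 1 else 0.0
        return agg

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _rep_seeds(master_seed: int, rep: int, n_streams: int = 4):
    """Independent substreams for stage randomness of one repetition."""
    return np.random.SeedSequence([int(master_seed), int(rep)]).spawn(n_streams)


def scenario_profile(config: ScenarioConfig) -> CpGParameterProfile:
    """The (fixed) parameter profile of a scenario: one emulated draw."""
    seed = int(
        np.random.SeedSequence([int(config.master_seed), 982_451_653]).generate_state(1)[0] >> 1
    )
    return emulate_parameter_profile(config.n_probes, seed=seed, platform=config.platform)


def run_scenario_once(
    config: ScenarioConfig,
    profile: CpGParameterProfile,
    rep: int,
    layout: SampleLayout | None = None,
    return_dmp: bool = False,
):
    """Execute the full pipeline for one repetition.

    Returns a :class:`MetricsSummary` (and the DMP result / beta matrix
    when ``return_dmp``).  The layout construction is deterministic; group
    assignment for the random design and all draws use substreams of
    ``(master_seed, rep)``.
    """
    s_group, s_betas, s_inject, s_spike = _rep_seeds(config.master_seed, rep)
    if layout is None:
        layout = build_layout(config.n_samples, config.chip_size, config.chips_per_plate)
        layout = assign_groups(layout, config.design, seed=s_group)
    betas = generate_null_betas(profile, layout, seed=s_betas)
    if config.spike is not None:
        spike = dataclasses.replace(config.spike, seed=s_spike)
        betas = spike_group_effects(betas, layout, spike)
    if config.inject_batch:
        betas, _ = inject_batch_effects(
            betas, layout, config.factors, config.amplitude, seed=s_inject
        )
    variant = CorrectionVariant(config.variant)
    if variant is not CorrectionVariant.NONE:
        betas = sequential_correct(
            betas, layout, config.factors, variant, on_mvalues=config.on_mvalues
        )
    dmp = fit_dmp(betas, layout.group_indicator())
    summary = summarize_metrics(
        dmp,
        alpha=config.alpha,
        metadata={
            "rep": rep,
            "n_samples": config.n_samples,
            "design": config.design,
            "variant": config.variant,
            "factors": "+".join(config.factors),
            "inject_batch": config.inject_batch,
            "master_seed": config.master_seed,
        },
    )
    if return_dmp:
        return summary, dmp, betas
    return summary


def replicate(config: ScenarioConfig, profile: CpGParameterProfile | None = None) -> ResultTable:
    """Run a scenario ``config.n_reps`` times with independent substreams."""
    if profile is None:
        profile = scenario_profile(config)
    rows = [run_scenario_once(config, profile, rep).to_dict() for rep in range(config.n_reps)]
    return ResultTable(rows=pd.DataFrame(rows), config=config)


def _metrics_row(summary: MetricsSummary, **extra) -> dict:
    d = summary.to_dict()
    d.update(extra)
    return d


def sweep_factor_levels(
    config: ScenarioConfig,
    levels_range=range(2, 13),
    profile: CpGParameterProfile | None = None,
) -> pd.DataFrame:
    """Correct a single synthetic batch factor with a growing level count.

    For each level count k a random factor with k near-equal levels is
    built, per-level offsets are injected (when ``config.inject_batch``),
    and that factor alone is corrected under ``config.variant``.  Returns
    per-(k, rep) metric rows; the first k whose mean FDR count reaches 1 is
    in ``df.attrs["first_significant_level"]``.
    """
    if profile is None:
        profile = scenario_profile(config)
    if max(levels_range) > config.n_samples:
        raise ValueError("more factor levels than samples")
    rows = []
    for k in levels_range:
        for rep in range(config.n_reps):
            s_group, s_betas, s_inject, s_factor = _rep_seeds(
                config.master_seed, rep * 1000 + k
            )
            layout = build_layout(config.n_samples, config.chip_size, config.chips_per_plate)
            layout = assign_groups(layout, config.design, seed=s_group)
            layout = add_factor(
                layout, "sweep", make_sweep_factor(config.n_samples, k, seed=s_factor)
            )
            betas = generate_null_betas(profile, layout, seed=s_betas)
            if config.inject_batch:
                betas, _ = inject_batch_effects(
                    betas, layout, ("sweep",), config.amplitude, seed=s_inject
                )
            if CorrectionVariant(config.variant) is not CorrectionVariant.NONE and k >= 2:
                betas = sequential_correct(
                    betas, layout, ("sweep",), config.variant, on_mvalues=config.on_mvalues
                )
            dmp = fit_dmp(betas, layout.group_indicator())
            summary = summarize_metrics(dmp, alpha=config.alpha)
            rows.append(_metrics_row(summary, n_levels=k, rep=rep))
    df = pd.DataFrame(rows)
    means = df.groupby("n_levels")["n_fdr"].mean()
    hit = means[means >= 1.0]
    df.attrs["first_significant_level"] = int(hit.index[0]) if len(hit) else None
    return df


def sweep_factor_count(
    config: ScenarioConfig,
    max_factors: int = 10,
    profile: CpGParameterProfile | None = None,
) -> pd.DataFrame:
    """Grow the number of two-level batch factors corrected sequentially.

    Factor f adds an independent random 2-level factor; all f factors are
    corrected one after another.  Returns per-(n_factors, rep) rows with the
    first factor count producing an FDR-significant site in
    ``df.attrs["first_significant_count"]``.
    """
    if profile is None:
        profile = scenario_profile(config)
    rows = []
    for f in range(1, max_factors + 1):
        for rep in range(config.n_reps):
            seeds = _rep_seeds(config.master_seed, rep * 1000 + f, n_streams=3 + f)
            s_group, s_betas, s_inject = seeds[:3]
            layout = build_layout(config.n_samples, config.chip_size, config.chips_per_plate)
            layout = assign_groups(layout, config.design, seed=s_group)
            names = []
            for j in range(f):
                name = f"factor{j + 1}"
                layout = add_factor(
                    layout,
                    name,
                    make_sweep_factor(config.n_samples, 2, seed=seeds[3 + j]),
                )
                names.append(name)
            betas = generate_null_betas(profile, layout, seed=s_betas)
            if config.inject_batch:
                betas, _ = inject_batch_effects(
                    betas, layout, tuple(names), config.amplitude, seed=s_inject
                )
            if CorrectionVariant(config.variant) is not CorrectionVariant.NONE:
                betas = sequential_correct(
                    betas, layout, tuple(names), config.variant, on_mvalues=config.on_mvalues
                )
            dmp = fit_dmp(betas, layout.group_indicator())
            summary = summarize_metrics(dmp, alpha=config.alpha)
            rows.append(_metrics_row(summary, n_factors=f, rep=rep))
    df = pd.DataFrame(rows)
    means = df.groupby("n_factors")["n_fdr"].mean()
    hit = means[means >= 1.0]
    df.attrs["first_significant_count"] = int(hit.index[0]) if len(hit) else None
    return df


def sweep_sample_size(
    config: ScenarioConfig,
    sizes=tuple(range(48, 769, 48)),
    designs: tuple[str, ...] = ("balanced", "random", "unbalanced"),
    profile: CpGParameterProfile | None = None,
) -> pd.DataFrame:
    """Run the row+chip correction across sample sizes and designs."""
    if profile is None:
        profile = scenario_profile(config)
    rows = []
    for n in sizes:
        for design in designs:
            cfg = dataclasses.replace(config, n_samples=int(n), design=design)
            for rep in range(cfg.n_reps):
                summary = run_scenario_once(cfg, profile, rep)
                rows.append(_metrics_row(summary, size=int(n)))
    return pd.DataFrame(rows)


def sweep_platform(
    config: ScenarioConfig,
    platform_sizes: dict[str, int],
    profile: CpGParameterProfile | None = None,
) -> pd.DataFrame:
    """Identical layouts and seeds across platforms; only probe count varies.

    ``platform_sizes`` maps platform name to probe count; each smaller
    platform is subsampled from the largest profile, mirroring how smaller
    arrays are nested in larger ones.
    """
    if profile is None:
        profile = scenario_profile(
            dataclasses.replace(config, n_probes=max(platform_sizes.values()))
        )
    rows = []
    for platform, size in platform_sizes.items():
        if size == profile.n_probes:
            sub = profile
        else:
            sub = subsample_platform(profile, platform, seed=config.master_seed, size=size)
        for rep in range(config.n_reps):
            summary = run_scenario_once(config, sub, rep)
            rows.append(_metrics_row(summary, platform=platform, n_probes_platform=size))
    return pd.DataFrame(rows)


def spike_detection_curve(
    config: ScenarioConfig,
    variants: tuple[str, ...] = ("NONE", "NO_MODEL", "WITH_OUTCOME_MODEL"),
    profile: CpGParameterProfile | None = None,
) -> pd.DataFrame:
    """Fraction of spiked sites detected (q < alpha) per target p and variant.

    The same spiked, batch-injected matrices are corrected under each
    variant, so curves are directly comparable.
    """
    if config.spike is None:
        raise ValueError("config.spike must be set for a detection curve")
    if profile is None:
        profile = scenario_profile(config)
    rows = []
    for rep in range(config.n_reps):
        s_group, s_betas, s_inject, s_spike = _rep_seeds(config.master_seed, rep)
        layout = build_layout(config.n_samples, config.chip_size, config.chips_per_plate)
        layout = assign_groups(layout, config.design, seed=s_group)
        base = generate_null_betas(profile, layout, seed=s_betas)
        spike = dataclasses.replace(config.spike, seed=s_spike)
        base = spike_group_effects(base, layout, spike)
        if config.inject_batch:
            base, _ = inject_batch_effects(
                base, layout, config.factors, config.amplitude, seed=s_inject
            )
        for variant in variants:
            if CorrectionVariant(variant) is CorrectionVariant.NONE:
                corrected = base
            else:
                corrected = sequential_correct(
                    base, layout, config.factors, variant, on_mvalues=config.on_mvalues
                )
            dmp = fit_dmp(corrected, layout.group_indicator())
            detected = dmp.q_bh < config.alpha
            targets = corrected.spike_target_p
            for target in sorted(set(spike.target_p_values), reverse=True):
                sel = corrected.truth_mask & np.isclose(targets, target)
                rows.append(
                    {
                        "rep": rep,
                        "variant": variant,
                        "target_p": target,
                        "n_sites": int(sel.sum()),
                        "detected_fraction": float(detected[sel].mean()),
                    }
                )
    return pd.DataFrame(rows)


def export_results(
    tables: dict[str, ResultTable | pd.DataFrame],
    out_dir,
    configs: dict[str, ScenarioConfig] | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write one CSV per table, a JSON-lines log, and a manifest.

    The manifest records configurations, master seeds and the package
    version so a run can be reproduced exactly.  With ``plots=True`` a Q-Q
    plot is rendered for any table carrying a ``lambda`` column (requires
    matplotlib).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    from . import __version__
    manifest: dict = {"version": __version__, "tables": {}, "configs": {}}
    for name, table in tables.items():
        df = table.rows if isinstance(table, ResultTable) else table
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        written.append(csv_path)
        jl_path = out / f"{name}.jsonl"
        with open(jl_path, "w") as fh:
            for record in df.to_dict(orient="records"):
                fh.write(json.dumps(record, default=float) + "\n")
        written.append(jl_path)
        manifest["tables"][name] = {"rows": int(len(df)), "csv": csv_path.name}
        cfg = None
        if isinstance(table, ResultTable) and table.config is not None:
            cfg = table.config
        elif configs and name in configs:
            cfg = configs[name]
        if cfg is not None:
            manifest["configs"][name] = cfg.to_dict()
    if configs:
        for name, cfg in configs.items():
            manifest["configs"].setdefault(name, cfg.to_dict())
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=float))
    written.append(manifest_path)
    if plots:
        written.extend(_render_plots(tables, out))
    return written


def _render_plots(tables, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for name, table in tables.items():
        df = table.rows if isinstance(table, ResultTable) else table
        if {"size", "n_fdr", "design"} <= set(df.columns):
            pivot = df.groupby(["design", "size"])["n_fdr"].mean().unstack("size")
            fig, ax = plt.subplots(figsize=(8, 3))
            im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="Reds")
            ax.set_yticks(range(len(pivot.index)), pivot.index)
            ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
            ax.set_xlabel("sample size")
            fig.colorbar(im, ax=ax, label="mean FDR-significant probes")
            path = out / f"{name}_heatmap.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    return written
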