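"""Design-matrix orchestration: the desk-scale analogue of the full study.

One synthetic "chromosome" of 20,000 target sites stands in for chr22's share
of a 1.3-million-SNP genome-wide target set (a 1/65 scale factor); the
observed-count ladder {400, 1,000, 5,000, 10,000} preserves the
observed-fraction ladder of targeted panels from 4,000 to 300,000 markers.
Every experiment cell is deterministic under the master seed: child seeds are
derived by a counter-based splitter keyed on (stage, cell labels, replicate).
Mirroring the study design, one reference panel and one set of replicate test
individuals are shared across all cells of an experiment (only pruning and
error injection vary per cell), so comparisons along a ladder are paired;
removing any cell still leaves every other cell's numbers unchanged, and
matched comparisons (error modes, panel composition) share panel/truth/pruning
seeds by construction.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .degradation import inject_dropin, inject_dropout, prune_to_fraction, prune_to_panel
from .evaluation import AggregateRecord, MetricsRecord, aggregate_samples, threshold_sweep
from .imputation_engine import HMMParams, forward_backward
from .synthetic_panel import (
    PopulationSplitConfig,
    make_genetic_map,
    recombine_panel,
    sample_truth_individual,
    simulate_founders,
    split_populations,
)
from .types import GeneticMap, HaplotypePanel

GENOME_TARGETS = 1_300_000  # genome-wide FIGG-scale target count the study scales down from


def child_seed(master_seed: int, *tags) -> int:
    """Counter-based seed splitter: stable child seed for a labelled stage."""
    key = tuple(zlib.crc32(repr(t).encode()) for t in tags)
    ss = np.random.SeedSequence(int(master_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class BenchmarkConfig:
    """Geometry, error modes, thresholds and replication for one benchmark run."""

    # panel geometry
    n_sites: int = 20_000
    n_founders: int = 100
    n_panel_haplotypes: int = 200
    maf_min: float = 0.02
    beta_a: float = 0.8
    beta_b: float = 0.8
    mean_spacing_bp: int = 1000
    rate_cm_per_mb: float = 1.0
    n_generations: int = 100
    # design matrix
    observed_counts: tuple = (400, 1000, 5000, 10_000)
    fractions: tuple = (0.10, 0.25, 0.50, 0.75)
    thresholds: tuple = (0.5, 0.9, 0.95, 0.99)
    call_threshold: float = 0.95
    dropin_rate: float = 0.1
    dropout_rate: float = 0.1
    n_replicates: int = 10
    truth_recombine: bool = True
    # populations (two-population scenarios)
    divergence: float = 0.1
    pop_sizes: tuple = (100, 100)
    # HMM
    ne: float = 1e4
    eps: float = 1e-3
    master_seed: int = 1

    def __post_init__(self) -> None:
        if any(n > self.n_sites for n in self.observed_counts):
            raise ValueError("observed count exceeds n_sites")

    def hmm_params(self) -> HMMParams:
        return HMMParams(ne=self.ne, eps=self.eps)

    @classmethod
    def from_yaml(cls, path: str) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k in ("observed_counts", "fractions", "thresholds", "pop_sizes"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        for k in ("observed_counts", "fractions", "thresholds", "pop_sizes"):
            d[k] = list(d[k])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def build_panel(
    cfg: BenchmarkConfig, seed: int, *, two_pops: bool = False
) -> tuple[HaplotypePanel, GeneticMap]:
    """Founders -> (optional population split) -> mosaic panel + genetic map."""
    founders = simulate_founders(
        cfg.n_founders,
        cfg.n_sites,
        cfg.maf_min,
        seed=seed,
        beta_a=cfg.beta_a,
        beta_b=cfg.beta_b,
        mean_spacing_bp=cfg.mean_spacing_bp,
        rate_cm_per_mb=cfg.rate_cm_per_mb,
    )
    gmap = make_genetic_map(founders.sites.pos, cfg.rate_cm_per_mb)
    if two_pops:
        split = PopulationSplitConfig(2, cfg.divergence, tuple(cfg.pop_sizes))
        panel = split_populations(
            founders, split, gmap, seed=seed + 1, n_generations=cfg.n_generations
        )
    else:
        panel = recombine_panel(
            founders, cfg.n_panel_haplotypes, gmap, cfg.n_generations, seed=seed + 1
        )
    return panel, gmap


@dataclass
class BenchmarkReport:
    """Tidy per-replicate metrics plus per-cell median/min/max aggregates."""

    per_replicate: pd.DataFrame
    aggregates: pd.DataFrame
    config: BenchmarkConfig

    def to_json(self) -> str:
        """Deterministic machine-readable summary (byte-identical per seed)."""
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self.config).items()},
            "aggregates": self.aggregates.sort_index(axis=1).to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    def write(self, out_prefix: str) -> None:
        self.per_replicate.to_csv(f"{out_prefix}_replicates.csv", index=False)
        self.aggregates.to_csv(f"{out_prefix}_aggregates.csv", index=False)
        with open(f"{out_prefix}.json", "w") as fh:
            fh.write(self.to_json())


def _records_to_frame(records: list[MetricsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(r.labels)
        row.update(
            n_total=r.n_total,
            n_observed=r.n_observed,
            n_imputed=r.n_imputed,
            n_erroneous=r.n_erroneous,
            call_rate=r.call_rate,
            error_rate=r.error_rate,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _aggregates_to_frame(aggs: list[AggregateRecord]) -> pd.DataFrame:
    rows = []
    for a in aggs:
        row = dict(a.labels)
        row.update(
            n_samples=a.n_samples,
            call_rate_median=a.call_rate_median,
            call_rate_min=a.call_rate_min,
            call_rate_max=a.call_rate_max,
            error_rate_median=a.error_rate_median,
            error_rate_min=a.error_rate_min,
            error_rate_max=a.error_rate_max,
            n_imputed_median=a.n_imputed_median,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _replicate_records(
    cfg: BenchmarkConfig,
    panel: HaplotypePanel,
    gmap: GeneticMap,
    cell_tag: tuple,
    rep: int,
    *,
    n_obs: int | None = None,
    fraction: float | None = None,
    error_mode: str = "none",
    pop: str = "any",
    reference: HaplotypePanel | None = None,
    extra_labels: dict | None = None,
) -> list[MetricsRecord]:
    """Run one replicate end-to-end and sweep the configured thresholds.

    The test individual depends only on (population, replicate), so the same
    replicate individuals recur across every cell of an experiment, as the
    study's fixed test-sample sets do; pruning and error draws are keyed on
    the cell as well.
    """
    ms = cfg.master_seed
    indiv = sample_truth_individual(
        panel,
        pop,
        seed=child_seed(ms, "truth", pop, rep),
        recombine=cfg.truth_recombine,
        ne=cfg.ne,
    )
    ref = reference if reference is not None else panel
    # exclusion contract: drop the sampled individual's haplotypes by identity
    # (the reference may be a re-indexed subset of the sampling panel)
    sampled_ids = set(str(panel.hap_ids[r]) for r in indiv.panel_rows)
    drop = [k for k in range(ref.K) if str(ref.hap_ids[k]) in sampled_ids]
    ref = ref.exclude_rows(drop)
    truth = indiv.genotypes
    if fraction is not None:
        obs = prune_to_fraction(truth, fraction, seed=child_seed(ms, "prune", *cell_tag, rep))
    else:
        obs = prune_to_panel(truth, n_obs, seed=child_seed(ms, "prune", *cell_tag, rep))
    if error_mode == "dropin":
        obs = inject_dropin(obs, cfg.dropin_rate, seed=child_seed(ms, "dropin", *cell_tag, rep))
    elif error_mode == "dropout":
        obs = inject_dropout(obs, cfg.dropout_rate, seed=child_seed(ms, "dropout", *cell_tag, rep))
    elif error_mode != "none":
        raise ValueError(f"unknown error mode {error_mode!r}")
    post = forward_backward(ref, obs, gmap, cfg.hmm_params())
    labels = {
        "n_observed_target": int(n_obs) if n_obs is not None else int(round(fraction * cfg.n_sites)),
        "error_mode": error_mode,
        "replicate": rep,
    }
    labels.update(extra_labels or {})
    return threshold_sweep(post, obs, truth, cfg.thresholds, labels)


def run_benchmark(cfg: BenchmarkConfig, *, error_mode: str = "none") -> BenchmarkReport:
    """Observed-count ladder x GP-threshold sweep over replicate individuals.

    Each observed-count cell gets its own panel (seeded by the cell label), so
    cells are mutually independent; error-mode variants of the same cell share
    panel, truth and pruning seeds and differ only in the injection stage.
    """
    records: list[MetricsRecord] = []
    panel, gmap = build_panel(cfg, child_seed(cfg.master_seed, "panel", "single"))
    for n_obs in cfg.observed_counts:
        cell_tag = ("cell", n_obs)
        for rep in range(cfg.n_replicates):
            records.extend(
                _replicate_records(
                    cfg, panel, gmap, cell_tag, rep, n_obs=n_obs, error_mode=error_mode
                )
            )
    aggs = _aggregate_by_cell(records)
    return BenchmarkReport(_records_to_frame(records), _aggregates_to_frame(aggs), cfg)


def run_fraction_benchmark(cfg: BenchmarkConfig) -> BenchmarkReport:
    """WGS-emulation: a uniform fraction of all target SNPs observed as input."""
    records: list[MetricsRecord] = []
    panel, gmap = build_panel(cfg, child_seed(cfg.master_seed, "panel", "single"))
    for frac in cfg.fractions:
        cell_tag = ("frac", frac)
        for rep in range(cfg.n_replicates):
            records.extend(
                _replicate_records(
                    cfg,
                    panel,
                    gmap,
                    cell_tag,
                    rep,
                    fraction=frac,
                    extra_labels={"fraction": float(frac)},
                )
            )
    aggs = _aggregate_by_cell(records)
    return BenchmarkReport(_records_to_frame(records), _aggregates_to_frame(aggs), cfg)


def run_error_mode_comparison(cfg: BenchmarkConfig) -> dict[str, BenchmarkReport]:
    """Three matched sub-runs (none / dropin / dropout) sharing all other seeds."""
    return {mode: run_benchmark(cfg, error_mode=mode) for mode in ("none", "dropin", "dropout")}


def run_population_comparison(cfg: BenchmarkConfig) -> BenchmarkReport:
    """Impute test individuals from each of two diverged populations (full panel)."""
    records: list[MetricsRecord] = []
    panel, gmap = build_panel(
        cfg, child_seed(cfg.master_seed, "panel", "twopop"), two_pops=True
    )
    for n_obs in cfg.observed_counts:
        cell_tag = ("popcell", n_obs)
        for pop in ("pop1", "pop2"):
            for rep in range(cfg.n_replicates):
                records.extend(
                    _replicate_records(
                        cfg,
                        panel,
                        gmap,
                        cell_tag + (pop,),
                        rep,
                        n_obs=n_obs,
                        pop=pop,
                        extra_labels={"population": pop},
                    )
                )
    aggs = _aggregate_by_cell(records)
    return BenchmarkReport(_records_to_frame(records), _aggregates_to_frame(aggs), cfg)


def run_panel_composition_comparison(cfg: BenchmarkConfig) -> BenchmarkReport:
    """Focal-population individuals imputed with vs without their own population
    in the reference panel (matched seeds; only panel composition differs)."""
    records: list[MetricsRecord] = []
    panel, gmap = build_panel(
        cfg, child_seed(cfg.master_seed, "panel", "twopop"), two_pops=True
    )
    ref_without = panel.restrict_pops(["pop2"])
    for n_obs in cfg.observed_counts:
        cell_tag = ("panelcomp", n_obs)
        for scenario, reference in (("included", panel), ("excluded", ref_without)):
            for rep in range(cfg.n_replicates):
                records.extend(
                    _replicate_records(
                        cfg,
                        panel,
                        gmap,
                        cell_tag,
                        rep,
                        n_obs=n_obs,
                        pop="pop1",
                        reference=reference,
                        extra_labels={"scenario": scenario},
                    )
                )
    aggs = _aggregate_by_cell(records)
    return BenchmarkReport(_records_to_frame(records), _aggregates_to_frame(aggs), cfg)


def _aggregate_by_cell(records: list[MetricsRecord]) -> list[AggregateRecord]:
    cells: dict[tuple, list[MetricsRecord]] = {}
    for r in records:
        cells.setdefault(r.condition_key(), []).append(r)
    return [aggregate_samples(v) for v in cells.values()]


def plot_median_minmax(
    aggregates: pd.DataFrame,
    x: str,
    out_path: str,
    *,
    group: str | None = None,
    logx: bool = False,
) -> None:
    """Two-panel figure (call rate, error rate): median points, min/max bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    groups = [(None, aggregates)] if group is None else list(aggregates.groupby(group))
    for name, df in groups:
        df = df.sort_values(x)
        label = None if name is None else f"{group}={name}"
        for ax, stat in zip(axes, ("call_rate", "error_rate")):
            med = df[f"{stat}_median"]
            lo = med - df[f"{stat}_min"]
            hi = df[f"{stat}_max"] - med
            ax.errorbar(df[x], med, yerr=[lo, hi], marker="o", capsize=3, label=label)
            ax.set_xlabel(x)
            ax.set_ylabel(stat.replace("_", " "))
            if logx:
                ax.set_xscale("log")
    if group is not None:
        axes[0].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
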