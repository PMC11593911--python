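"""Scoring: call rate, error rate, aggregation, genome extrapolation.

Call rate = (observed + imputed genotypes) / total targeted genotypes.
Error rate = erroneous assigned genotypes / (observed + imputed genotypes),
with 0/0 defined as 0.  Erroneous counts cover wrong imputed calls *and*
injected observed errors by default (an assigned genotype that differs from
the truth is wrong regardless of how it was assigned); a flag restricts the
numerator to imputed sites for sensitivity analysis.  All counts are exact
integers; rates are formed once, at the end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imputation_engine import (
    SOURCE_IMPUTED,
    SOURCE_OBSERVED,
    CalledGenotypes,
    PosteriorField,
    call_imputed,
)
from .types import ObservedGenotypes, TruthGenotypes


@dataclass
class MetricsRecord:
    """Per-sample metrics for one design cell."""

    n_total: int
    n_observed: int
    n_imputed: int
    n_erroneous: int
    call_rate: float
    error_rate: float
    labels: dict = field(default_factory=dict)

    def condition_key(self) -> tuple:
        """Labels identifying the design cell (replicate identifiers excluded)."""
        skip = {"seed", "replicate", "sample"}
        return tuple(sorted((k, v) for k, v in self.labels.items() if k not in skip))


@dataclass
class AggregateRecord:
    """median/min/max of call and error rate over replicate samples."""

    n_samples: int
    call_rate_median: float
    call_rate_min: float
    call_rate_max: float
    error_rate_median: float
    error_rate_min: float
    error_rate_max: float
    n_imputed_median: float
    labels: dict = field(default_factory=dict)


def _rates(n_total: int, n_assigned: int, n_err: int) -> tuple[float, float]:
    call_rate = n_assigned / n_total if n_total else 0.0
    if n_assigned == 0:
        if n_err:
            raise ValueError("erroneous genotypes without assigned genotypes")
        warnings.warn("no assigned genotypes; error rate defined as 0", stacklevel=3)
        return call_rate, 0.0
    return call_rate, n_err / n_assigned


def score_sample(
    called: CalledGenotypes,
    truth: TruthGenotypes,
    labels: dict | None = None,
    *,
    include_observed_errors: bool = True,
) -> MetricsRecord:
    """Score one called sample against its truth genotypes."""
    if len(truth.g) != len(called.genotype) or not called.sites.equals(truth.sites):
        raise ValueError("called/truth site lists differ")
    n_total = len(truth.g)
    n_obs = called.n_observed
    n_imp = called.n_imputed
    assigned = called.source >= 0
    wrong = assigned & (called.genotype != truth.g)
    if not include_observed_errors:
        wrong &= called.source == SOURCE_IMPUTED
    n_err = int(wrong.sum())
    call_rate, error_rate = _rates(n_total, n_obs + n_imp, n_err)
    return MetricsRecord(
        n_total, n_obs, n_imp, n_err, call_rate, error_rate, dict(labels or {})
    )


def threshold_sweep(
    post: PosteriorField,
    obs: ObservedGenotypes,
    truth: TruthGenotypes,
    thresholds,
    labels: dict | None = None,
    *,
    include_observed_errors: bool = True,
) -> list[MetricsRecord]:
    """One MetricsRecord per GP threshold, reusing a single posterior field."""
    out = []
    for q in thresholds:
        if not 0.0 <= q <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")
        called = call_imputed(post, obs, q)
        lab = dict(labels or {})
        lab["q_gp"] = float(q)
        out.append(
            score_sample(
                called, truth, lab, include_observed_errors=include_observed_errors
            )
        )
    return out


def aggregate_samples(records: list[MetricsRecord]) -> AggregateRecord:
    """median / min / max over replicate samples of one design cell.

    The median of an even count is the mean of the central pair (numpy's
    convention).
    """
    if not records:
        raise ValueError("cannot aggregate an empty record list")
    keys = {r.condition_key() for r in records}
    if len(keys) > 1:
        raise ValueError(f"mixed design cells in aggregation: {keys}")
    cr = np.array([r.call_rate for r in records])
    er = np.array([r.error_rate for r in records])
    ni = np.array([r.n_imputed for r in records])
    labels = {
        k: v
        for k, v in records[0].labels.items()
        if k not in {"seed", "replicate", "sample"}
    }
    return AggregateRecord(
        n_samples=len(records),
        call_rate_median=float(np.median(cr)),
        call_rate_min=float(cr.min()),
        call_rate_max=float(cr.max()),
        error_rate_median=float(np.median(er)),
        error_rate_min=float(er.min()),
        error_rate_max=float(er.max()),
        n_imputed_median=float(np.median(ni)),
        labels=labels,
    )


def extrapolate_genome(rec: MetricsRecord, n_total_genome: int) -> MetricsRecord:
    """Scale one-chromosome counts to a genome-wide target set.

    Counts scale by n_total_genome / n_total (rounded to nearest integer);
    rates are unchanged by construction.
    """
    if rec.n_total <= 0:
        raise ValueError("cannot extrapolate a zero-size record")
    f = n_total_genome / rec.n_total
    labels = dict(rec.labels)
    labels["extrapolated"] = True
    return MetricsRecord(
        n_total=n_total_genome,
        n_observed=int(round(rec.n_observed * f)),
        n_imputed=int(round(rec.n_imputed * f)),
        n_erroneous=int(round(rec.n_erroneous * f)),
        call_rate=rec.call_rate,
        error_rate=rec.error_rate,
        labels=labels,
    )


@dataclass
class ScenarioDelta:
    """Signed differences (excluded-panel minus included-panel) of median rates."""

    d_call_rate_median: float
    d_error_rate_median: float
    labels: dict = field(default_factory=dict)


def compare_panel_scenarios(
    rec_with: AggregateRecord, rec_without: AggregateRecord
) -> ScenarioDelta:
    """Delta report for a panel-composition experiment.

    Positive d_error_rate_median means excluding the focal population's
    reference samples increased the median error rate.
    """
    ignore = {"panel", "scenario"}
    lab_w = {k: v for k, v in rec_with.labels.items() if k not in ignore}
    lab_o = {k: v for k, v in rec_without.labels.items() if k not in ignore}
    if lab_w != lab_o:
        raise ValueError(f"mismatched design cells: {lab_w} vs {lab_o}")
    return ScenarioDelta(
        d_call_rate_median=rec_without.call_rate_median - rec_with.call_rate_median,
        d_error_rate_median=rec_without.error_rate_median - rec_with.error_rate_median,
        labels=lab_w,
    )
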