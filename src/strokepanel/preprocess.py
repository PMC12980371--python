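"""Cohort exclusion rules, low-expression filtering, TMM normalization,
log2-CPM transformation, and a simple location-scale batch adjustment.

The normalization follows the edgeR conventions: trimmed mean of M-values
(30% two-sided trim on M, 5% on A, inverse asymptotic-variance weights,
reference library chosen by the 75th-percentile rule) rescaled to
geometric mean 1, then log2 counts-per-million with a prior count.
Batch adjustment is a per-transcript, per-batch location-scale
standardization to the grand mean and pooled SD — a deliberately simple,
leakage-free alternative to count-level batch regression, applied only
within a pooled validation set and never across the train/validation
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthgen import ExpressionStudy

__all__ = [
    "ExclusionRule",
    "ExclusionRuleSet",
    "NormalizedStudy",
    "EmptyCohortError",
    "apply_exclusions",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "batch_adjust",
    "normalize_study",
    "default_training_rules",
]


class EmptyCohortError(ValueError):
    """All samples were excluded."""


@dataclass
class ExclusionRule:
    """A labelled predicate over the sample-metadata frame.

    ``predicate`` maps the metadata DataFrame to a boolean Series that is
    True for samples the rule removes.
    """

    label: str
    predicate: Callable[[pd.DataFrame], pd.Series]
    enabled: bool = True


@dataclass
class ExclusionRuleSet:
    """Ordered exclusion rules; each removed sample is annotated with the
    first rule that matched it."""

    rules: list[ExclusionRule] = field(default_factory=list)


def default_training_rules(
    min_read_depth: int = 0, nihss_min: int | None = None
) -> ExclusionRuleSet:
    """Training-cohort style rules: drop TIA, unknown diagnoses, and (when
    configured) low-depth samples and mild cases."""
    rules = [
        ExclusionRule("TIA", lambda m: m["diagnosis"] == "TIA"),
        ExclusionRule("unknown_diagnosis", lambda m: m["diagnosis"] == "unknown"),
        ExclusionRule(
            f"read_depth<{min_read_depth}",
            lambda m, d=min_read_depth: m["read_depth"] < d,
        ),
    ]
    if nihss_min is not None:
        rules.append(
            ExclusionRule(
                f"nihss<{nihss_min}",
                lambda m, c=nihss_min: m["nihss"].fillna(-1) < c,
            )
        )
    return ExclusionRuleSet(rules)


def apply_exclusions(
    study: ExpressionStudy, rules: ExclusionRuleSet
) -> tuple[ExpressionStudy, list[dict]]:
    """Apply enabled rules in declared order.

    Returns the filtered study and a log: one ``{"sample_id", "rule"}``
    record per removed sample, annotated with the first matching rule.
    """
    meta = study.sample_metadata
    assigned = pd.Series(index=meta.index, dtype=object)
    for rule in rules.rules:
        if not rule.enabled:
            continue
        hit = rule.predicate(meta).astype(bool)
        newly = hit & assigned.isna()
        assigned[newly] = rule.label
    removed = assigned.dropna()
    log = [
        {"sample_id": sid, "rule": rule_label} for sid, rule_label in removed.items()
    ]
    keep = [s for s in meta.index if s not in set(removed.index)]
    if not keep:
        raise EmptyCohortError("all samples excluded by the rule set")
    return study.subset_samples(keep), log


def filter_low_expression(
    study: ExpressionStudy, min_cpm: float = 1.0, min_samples: int | None = None
) -> pd.Series:
    """Boolean mask: True where CPM >= min_cpm in >= min_samples samples.

    ``min_samples`` defaults to 25% of the cohort (rounded up).
    """
    n = study.n_samples
    if min_samples is None:
        min_samples = int(np.ceil(0.25 * n))
    if min_samples > n:
        raise ValueError("min_samples exceeds the number of samples")
    lib = study.counts.sum(axis=0).to_numpy(dtype=float)
    cpm = study.counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    mask = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return pd.Series(mask, index=study.counts.index, name="filter_mask")


def tmm_factors(counts: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Follows the canonical definition: the reference library is the sample
    whose 75th-percentile count fraction is closest to the mean of those
    fractions; per sample, log2 ratios (M) against the reference are
    trimmed 30% on each tail and the log2 average abundances (A) 5% on
    each tail; the factor is 2 to the inverse-variance-weighted mean of
    the surviving M values.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with all-zero counts")
    f75 = np.quantile(x, 0.75, axis=0, method="linear") / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(x.shape[1])
    ref_col, n_ref = x[:, ref], lib[ref]
    for j in range(x.shape[1]):
        obs, n_obs = x[:, j], lib[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            log_r = np.log2((obs / n_obs) / (ref_col / n_ref))
            abs_e = (np.log2(obs / n_obs) + np.log2(ref_col / n_ref)) / 2.0
            v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref_col) / (n_ref * ref_col)
        fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
        log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
        if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
            continue
        n = log_r.size
        lo_l, hi_l = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        lo_s, hi_s = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rank_r = rankdata(log_r)
        rank_e = rankdata(abs_e)
        keep = (
            (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
        )
        if not keep.any():
            continue
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
        if np.isfinite(f):
            factors[j] = 2.0**f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    counts: pd.DataFrame | np.ndarray,
    size_factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame | np.ndarray:
    """log2 counts-per-million on TMM-effective library sizes:
    ``log2((count + prior) / (effective_lib + 2*prior) * 1e6)``."""
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    x = np.asarray(counts, dtype=float)
    lib = x.sum(axis=0)
    if size_factors is not None:
        lib = lib * np.asarray(size_factors, dtype=float)
    out = np.log2((x + prior_count) / (lib[None, :] + 2.0 * prior_count) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def batch_adjust(
    log_expression: pd.DataFrame, batch_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per-transcript, per-batch location-scale standardization to the
    grand mean and pooled within-batch SD.

    After adjustment every batch has the same per-transcript mean (within
    1e-9); within-batch rank order is preserved because the map is a
    monotone affine transform per batch.
    """
    batches = np.asarray(batch_labels)
    levels = pd.unique(batches)
    if len(levels) < 2:
        raise ValueError("need at least 2 batches")
    x = log_expression.to_numpy(dtype=float)
    out = np.empty_like(x)
    grand = x.mean(axis=1)
    var_parts, dfs = [], []
    for b in levels:
        cols = batches == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        var_parts.append(x[:, cols].var(axis=1, ddof=1) * (cols.sum() - 1))
        dfs.append(cols.sum() - 1)
    pooled_sd = np.sqrt(np.sum(var_parts, axis=0) / np.sum(dfs))
    for b in levels:
        cols = batches == b
        mu_b = x[:, cols].mean(axis=1)
        sd_b = x[:, cols].std(axis=1, ddof=1)
        scale = np.where(sd_b > 0, pooled_sd / np.where(sd_b > 0, sd_b, 1.0), 1.0)
        out[:, cols] = (x[:, cols] - mu_b[:, None]) * scale[:, None] + grand[:, None]
    return pd.DataFrame(out, index=log_expression.index, columns=log_expression.columns)


@dataclass
class NormalizedStudy:
    """Filtered, TMM-normalized, log2-CPM expression plus provenance.

    ``log_expression`` is restricted to transcripts passing the
    low-expression filter; ``size_factors`` have geometric mean 1;
    ``provenance`` is the append-only list of applied steps.
    """

    log_expression: pd.DataFrame
    size_factors: pd.Series
    filter_mask: pd.Series
    sample_metadata: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        if not np.all(np.isfinite(self.log_expression.to_numpy())):
            raise ValueError("log expression must be finite")


def normalize_study(
    study: ExpressionStudy,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    prior_count: float = 0.5,
    batch_adjust_labels: pd.Series | None = None,
) -> NormalizedStudy:
    """Standard preprocessing chain: low-expression filter -> TMM ->
    log2-CPM (-> optional within-pool batch adjustment).

    ``batch_adjust_labels`` must only ever come from within one pool
    (e.g. the validation sets); passing labels spanning the
    train/validation boundary would leak information across it.
    """
    mask = filter_low_expression(study, min_cpm=min_cpm, min_samples=min_samples)
    counts = study.counts.loc[mask.to_numpy()]
    factors = tmm_factors(counts)
    expr = log_cpm(counts, factors, prior_count=prior_count)
    provenance = [
        {"step": "filter_low_expression", "min_cpm": min_cpm, "kept": int(mask.sum())},
        {"step": "tmm_factors"},
        {"step": "log_cpm", "prior_count": prior_count},
    ]
    if batch_adjust_labels is not None:
        expr = batch_adjust(expr, batch_adjust_labels.loc[expr.columns])
        provenance.append({"step": "batch_adjust"})
    return NormalizedStudy(
        log_expression=expr,
        size_factors=pd.Series(factors, index=study.counts.columns, name="tmm"),
        filter_mask=mask,
        sample_metadata=study.sample_metadata.copy(),
        provenance=provenance,
    )
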