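"""Pearson correlation screening of transcripts against continuous
clinical targets (time since onset, admission NIHSS), with
Benjamini-Hochberg FDR control and train/validation replication."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_qvalues
from .preprocess import NormalizedStudy

__all__ = ["CorrelationScreen", "correlation_screen", "replicated_selection"]


@dataclass
class CorrelationScreen:
    """Per-transcript Pearson r against one clinical target.

    ``table`` has columns ``r``, ``p_value``, ``q_value`` indexed by
    transcript ID; ``selected`` is the set passing |r| >= r_min and
    q < q_max; ``n_used``/``n_dropped`` track missing-target handling.
    """

    table: pd.DataFrame
    target_name: str
    selected: set
    n_used: int
    n_dropped: int

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["target"] = self.target_name
        out.to_csv(path, sep="\t")


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x with y (vectorized)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc, axis=1) * np.sum(yc * yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    return np.where(np.isfinite(r), np.clip(r, -1.0, 1.0), 0.0)


def correlation_screen(
    normalized: NormalizedStudy,
    target: str,
    r_min: float = 0.6,
    q_max: float = 0.05,
    sample_mask: pd.Series | None = None,
) -> CorrelationScreen:
    """Screen every transcript's log2-CPM against a continuous covariate.

    Samples with a missing target value are dropped (the count is logged
    on the result); p-values come from the exact t-distribution transform
    of r, q-values from Benjamini-Hochberg over all screened transcripts.
    """
    meta = normalized.sample_metadata
    cols = meta.index if sample_mask is None else meta.index[sample_mask.loc[meta.index]]
    y = meta.loc[cols, target].to_numpy(dtype=float)
    present = np.isfinite(y)
    n_dropped = int((~present).sum())
    cols = cols[present]
    y = y[present]
    if len(y) < 5:
        raise ValueError(f"target {target!r} non-missing in fewer than 5 samples")
    if np.ptp(y) == 0:
        raise ValueError(f"target {target!r} has zero variance")
    x = normalized.log_expression.loc[:, cols].to_numpy(dtype=float)
    r = _pearson_rows(x, y)
    n = len(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    q = bh_qvalues(p)
    table = pd.DataFrame(
        {"r": r, "p_value": p, "q_value": q}, index=normalized.log_expression.index
    )
    selected = set(table.index[(np.abs(r) >= r_min) & (q < q_max)])
    return CorrelationScreen(
        table=table,
        target_name=target,
        selected=selected,
        n_used=n,
        n_dropped=n_dropped,
    )


def replicated_selection(
    train_screen: CorrelationScreen,
    valid_screen: CorrelationScreen,
    r_min_valid: float = 0.40,
    q_max: float = 0.05,
) -> set:
    """Transcripts selected in training that replicate in validation:
    sign-concordant r with |r| >= r_min_valid and q < q_max."""
    tt, tv = train_screen.table, valid_screen.table
    if not tt.index.equals(tv.index):
        raise ValueError("screens must share the same transcript universe")
    out = set()
    for tid in train_screen.selected:
        r_t = tt.at[tid, "r"]
        r_v = tv.at[tid, "r"]
        if (
            np.sign(r_v) == np.sign(r_t)
            and abs(r_v) >= r_min_valid
            and tv.at[tid, "q_value"] < q_max
        ):
            out.add(tid)
    return out
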