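"""Covariate-adjusted pairwise differential expression, the 1.5-fold /
p<0.05 retention rule, top-50 up/down selection, condition-unique
signature sets, and greedy Mahalanobis full matching.

Per transcript, (weighted) ordinary least squares is fit to
``log2CPM ~ group + covariates``; the group coefficient is the log2 fold
change, its two-sided t-test gives the p-value, and Benjamini-Hochberg
over the tested transcripts gives the q-value.  The retention rule gates
on raw p (not q) together with the fold-change threshold, and q-values
are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr
from statsmodels.stats.multitest import multipletests

from .preprocess import NormalizedStudy

__all__ = [
    "DEResult",
    "SignatureSets",
    "MatchResult",
    "mahalanobis_match",
    "differential_expression",
    "significant_set",
    "top_up_down",
    "unique_signatures",
    "signature_sets",
    "bh_qvalues",
    "DegenerateCovarianceError",
]


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-transcript differential expression for one pairwise contrast.

    ``table`` has columns ``log2fc`` (group1 - group2 on the log2-CPM
    scale), ``p_value`` and ``q_value``, indexed by transcript ID.
    """

    table: pd.DataFrame
    contrast: tuple[str, str]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["contrast"] = f"{self.contrast[0]}_vs_{self.contrast[1]}"
        out.to_csv(path, sep="\t")


@dataclass
class SignatureSets:
    """Condition-unique transcript sets.

    ``unique_all[c]`` — transcripts significant for condition c and for no
    other condition; ``unique_top100[c]`` — same uniqueness logic applied
    to each condition's top-50-up + top-50-down list.
    """

    unique_all: dict[str, set]
    unique_top100: dict[str, set]


@dataclass
class MatchResult:
    """Greedy Mahalanobis full matching output.

    ``set_id`` maps each matched sample to its matched-set index;
    ``weights`` are per-sample: every treated (minority-group) sample has
    weight 1 and the controls within a matched set share weight 1 equally.
    """

    set_id: pd.Series
    weights: pd.Series
    treated_group: str


class DegenerateCovarianceError(ValueError):
    pass


def mahalanobis_match(
    metadata: pd.DataFrame,
    group_labels: pd.Series,
    covariates: list[str],
    ridge: float = 1e-6,
) -> MatchResult:
    """Greedy full matching on Mahalanobis distance over clinical covariates.

    The minority group is treated: each treated sample claims its nearest
    unclaimed control (one pass, in metadata order), then every remaining
    control is attached to the matched set of its nearest treated sample.
    The goal is covariate balance ahead of differential expression, not
    optimal matching.
    """
    groups = group_labels.loc[metadata.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError("matching requires exactly two groups")
    counts = groups.value_counts()
    treated_group = counts.idxmin() if counts.iloc[0] != counts.iloc[1] else levels[0]
    x = metadata[covariates].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing covariate values; impute or drop first")
    cov = np.cov(x, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        cov_r = cov + ridge * np.eye(cov.shape[0])
        try:
            vi = np.linalg.inv(cov_r)
        except np.linalg.LinAlgError as exc:
            raise DegenerateCovarianceError(
                "covariate covariance singular even after ridge"
            ) from exc
    if not np.all(np.isfinite(vi)):
        raise DegenerateCovarianceError("covariate covariance not invertible")

    idx = metadata.index
    treated_pos = np.flatnonzero((groups == treated_group).to_numpy())
    control_pos = np.flatnonzero((groups != treated_group).to_numpy())
    diff = x[treated_pos][:, None, :] - x[control_pos][None, :, :]
    dist = np.einsum("tcd,de,tce->tc", diff, vi, diff)

    set_of = pd.Series(index=idx, dtype=float)
    claimed = np.zeros(len(control_pos), dtype=bool)
    for s, tp in enumerate(treated_pos):
        set_of.iloc[tp] = s
        free = np.flatnonzero(~claimed)
        if free.size:
            j = free[np.argmin(dist[s, free])]
            claimed[j] = True
            set_of.iloc[control_pos[j]] = s
    for j in np.flatnonzero(~claimed):
        s = int(np.argmin(dist[:, j]))
        set_of.iloc[control_pos[j]] = s

    weights = pd.Series(0.0, index=idx)
    weights.iloc[treated_pos] = 1.0
    for s in range(len(treated_pos)):
        members = (set_of == s) & (groups != treated_group)
        n_ctrl = int(members.sum())
        if n_ctrl:
            weights[members] = 1.0 / n_ctrl
    return MatchResult(
        set_id=set_of.astype(int), weights=weights, treated_group=treated_group
    )


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in piv[rank:]]


def differential_expression(
    normalized: NormalizedStudy,
    contrast: tuple[str, str],
    adjust_for: list[str] = ("age", "sex"),
    weights: pd.Series | None = None,
    group_column: str = "diagnosis",
) -> DEResult:
    """Per-transcript (weighted) OLS of log2-CPM on group membership plus
    covariates; two-sided t-test on the group coefficient.

    Transcripts that are constant across the contrast's samples get
    log2fc 0 and p 1 by convention.
    """
    meta = normalized.sample_metadata
    g1, g2 = contrast
    in_contrast = meta[group_column].isin([g1, g2])
    sub = meta[in_contrast]
    if (sub[group_column] == g1).sum() < 3 or (sub[group_column] == g2).sum() < 3:
        raise ValueError("both contrast groups need >= 3 samples")
    y_mat = normalized.log_expression.loc[:, sub.index].to_numpy(dtype=float)

    cols = ["intercept", "group"] + list(adjust_for)
    design = np.column_stack(
        [
            np.ones(len(sub)),
            (sub[group_column] == g1).to_numpy(dtype=float),
            *[sub[c].to_numpy(dtype=float) for c in adjust_for],
        ]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, cols)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    if weights is not None:
        w = weights.loc[sub.index].to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        sw = np.sqrt(w)
        xw = design * sw[:, None]
        yw = y_mat * sw[None, :]
    else:
        xw, yw = design, y_mat

    xtx_inv = np.linalg.inv(xw.T @ xw)
    beta = yw @ (xw @ xtx_inv)  # (T, p)
    resid = yw - beta @ xw.T
    n, p = design.shape
    df = n - p
    rss = np.sum(resid * resid, axis=1)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    log2fc = beta[:, 1]

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = log2fc / se
    p_val = 2.0 * stats.t.sf(np.abs(tstat), df)
    constant = np.ptp(y_mat, axis=1) == 0
    degenerate = (se == 0) | ~np.isfinite(tstat)
    p_val = np.where(degenerate & (np.abs(log2fc) < 1e-12), 1.0, p_val)
    p_val = np.where(degenerate & (np.abs(log2fc) >= 1e-12), 0.0, p_val)
    log2fc = np.where(constant, 0.0, log2fc)
    p_val = np.where(constant, 1.0, p_val)

    table = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p_val, "q_value": bh_qvalues(p_val)},
        index=normalized.log_expression.index,
    )
    return DEResult(table=table, contrast=(g1, g2))


def significant_set(
    de: DEResult, p_max: float = 0.05, fc_min: float = 1.5
) -> set[str]:
    """Retention rule: raw p < p_max and |log2fc| >= log2(fc_min)."""
    if p_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    keep = (t["p_value"] < p_max) & (t["log2fc"].abs() >= np.log2(fc_min))
    return set(t.index[keep])


def _ordered(t: pd.DataFrame, ascending_fc: bool) -> list[str]:
    # sort by effect, then smaller p, then transcript ID
    key = t.assign(_id=t.index).sort_values(
        ["log2fc", "p_value", "_id"], ascending=[ascending_fc, True, True], kind="stable"
    )
    return list(key.index)


def top_up_down(
    de: DEResult, k: int = 50, p_max: float = 0.05, fc_min: float = 1.5
) -> list[str]:
    """Top-k upregulated followed by top-k downregulated transcripts among
    the significant set; ties broken by smaller p then transcript ID."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = significant_set(de, p_max=p_max, fc_min=fc_min)
    t = de.table.loc[sorted(sig)]
    up = t[t["log2fc"] > 0]
    down = t[t["log2fc"] < 0]
    top_up = _ordered(up, ascending_fc=False)[:k]
    top_down = _ordered(down, ascending_fc=True)[:k]
    return top_up + top_down


def unique_signatures(sets: dict[str, set]) -> dict[str, set]:
    """Per condition, the transcripts found in that condition's set and in
    no other condition's set."""
    if len(sets) < 2:
        raise ValueError("need at least 2 conditions")
    out = {}
    for cond, ids in sets.items():
        others = set().union(*(v for c, v in sets.items() if c != cond))
        out[cond] = set(ids) - others
    return out


def signature_sets(
    de_by_condition: dict[str, list[DEResult]],
    k: int = 50,
    p_max: float = 0.05,
    fc_min: float = 1.5,
) -> SignatureSets:
    """Build condition-unique sets from each condition's pairwise DE results.

    A condition's signature set is the intersection over its contrasts of
    the retention-rule survivors — transcripts altered in that condition
    relative to *every* other group (a transcript significant only in,
    say, hemorrhagic-vs-ischemic separates the pair but is not specific
    to either).  The top-100 variant applies the same logic to the
    top-50-up/top-50-down lists.  Uniqueness then removes anything still
    shared with another condition's set.
    """
    all_sig = {
        cond: set.intersection(*(significant_set(de, p_max, fc_min) for de in des))
        for cond, des in de_by_condition.items()
    }
    top100 = {
        cond: set.intersection(*(set(top_up_down(de, k, p_max, fc_min)) for de in des))
        for cond, des in de_by_condition.items()
    }
    return SignatureSets(
        unique_all=unique_signatures(all_sig),
        unique_top100=unique_signatures(top100),
    )
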