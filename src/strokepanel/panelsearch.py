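"""Single-transcript HMM screening, exhaustive 3-5 transcript panel
enumeration, leakage-free panel evaluation, Youden-optimal posterior
thresholds, and deterministic representative-panel selection.

Every panel classifier is a Gaussian HMM fitted on training observations
only; hidden states are mapped to the binary task labels by majority
posterior vote on the training cohort, the decision threshold on the
positive-state posterior is optimized on training (Youden's J over
midpoints of adjacent sorted posteriors), and the frozen model plus
threshold are then applied unchanged to validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ghmm import GaussianHMMFit, GaussianHMMSpec, fit_em, forward_backward

__all__ = [
    "Metrics",
    "ScreenResult",
    "PanelEvaluation",
    "compute_metrics",
    "roc_auc",
    "optimize_threshold",
    "screen_single",
    "enumerate_panels",
    "evaluate_panel",
    "select_representative",
    "search_panels",
]


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix summary for one binary task.

    Ratios whose denominator is zero are ``None`` (flagged undefined,
    never silently zeroed); ``youden_j`` is defined only when both
    sensitivity and specificity are.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    youden_j: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "youden_j": self.youden_j,
            "auc": self.auc,
        }


def compute_metrics(tp: int, fp: int, fn: int, tn: int, auc: float | None = None) -> Metrics:
    """Accuracy, sensitivity, specificity and Youden's J from confusion counts."""
    for v in (tp, fp, fn, tn):
        if v < 0 or int(v) != v:
            raise ValueError("confusion counts must be non-negative integers")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("confusion counts are all zero")
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    youden = sens + spec - 1.0 if (sens is not None and spec is not None) else None
    return Metrics(
        tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn),
        accuracy=(tp + tn) / total, sensitivity=sens, specificity=spec,
        youden_j=youden, auc=auc,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute 1/2.

    Returns None when one class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    u = np.sum(ranks[y == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _confusion(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    y = labels.astype(bool)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    tn = int(np.sum(~pred & ~y))
    return tp, fp, fn, tn


def optimize_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Youden-optimal cut on the positive-state posterior.

    Candidate thresholds are the midpoints of adjacent sorted unique
    scores; ties on J resolve to the smallest candidate.  Under complete
    separation the chosen threshold is the midpoint of the separating gap
    and J = 1.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be present to optimize a threshold")
    uniq = np.unique(s)
    if uniq.size < 2:
        thr = 0.5
        tp, fp, fn, tn = _confusion(s, y, thr)
        m = compute_metrics(tp, fp, fn, tn)
        return thr, m.youden_j
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_thr, best_j = None, -np.inf
    for thr in candidates:
        tp, fp, fn, tn = _confusion(s, y, thr)
        j = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if j > best_j + 1e-12:
            best_thr, best_j = float(thr), float(j)
    return best_thr, best_j


@dataclass
class ScreenResult:
    """Single-transcript screening outcome.

    ``table`` has per-transcript ``accuracy``, ``passed`` (perfect
    separation at the configured floor) and ``degenerate`` flags.
    """

    table: pd.DataFrame
    accuracy_floor: float

    @property
    def passing_ids(self) -> list[str]:
        return sorted(self.table.index[self.table["passed"]])


def _map_states(
    gamma: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each hidden state to the label with the larger total
    posterior mass; posterior-mass ties resolve toward the rarer
    (positive) class.  Returns (state_to_class, positive_scores)."""
    y = labels.astype(int)
    mass_pos = gamma[y == 1].sum(axis=0)
    mass_neg = gamma[y == 0].sum(axis=0)
    state_to_class = np.where(mass_pos >= mass_neg, 1, 0)
    pos_states = state_to_class == 1
    scores = gamma[:, pos_states].sum(axis=1)
    return state_to_class, scores


def screen_single(
    normalized_train: pd.DataFrame,
    labels: pd.Series,
    candidate_ids: list[str],
    spec: GaussianHMMSpec | None = None,
    seed: int = 0,
    accuracy_floor: float = 1.0,
    n_restarts: int = 4,
    max_iter: int = 300,
) -> ScreenResult:
    """Screen candidate transcripts one at a time with a single-feature HMM.

    Per transcript: fit on the training column, map states to classes by
    majority posterior vote, classify at posterior 0.5, record training
    accuracy.  A transcript passes iff accuracy >= accuracy_floor
    (default 1.0 — perfect separation).  Constant transcripts are flagged
    degenerate, scored at the majority-class prevalence, and never pass.
    """
    y = labels.loc[normalized_train.columns].to_numpy().astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    missing = [t for t in candidate_ids if t not in normalized_train.index]
    if missing:
        raise KeyError(f"candidates absent from the expression matrix: {missing}")
    base_spec = spec or GaussianHMMSpec(n_states=2, n_features=1)
    prevalence = max(np.mean(y == 1), np.mean(y == 0))
    rows = []
    for tid in candidate_ids:
        obs = normalized_train.loc[tid].to_numpy(dtype=float)[:, None]
        if np.ptp(obs) == 0:
            rows.append((tid, prevalence, False, True))
            continue
        fit = fit_em(
            obs, base_spec, n_restarts=n_restarts, max_iter=max_iter, seed=seed
        )
        gamma, _ = forward_backward(fit, obs)
        _, scores = _map_states(gamma, y)
        acc = float(np.mean((scores >= 0.5).astype(int) == y))
        rows.append((tid, acc, acc >= accuracy_floor - 1e-12, False))
    table = pd.DataFrame(
        rows, columns=["transcript", "accuracy", "passed", "degenerate"]
    ).set_index("transcript")
    return ScreenResult(table=table, accuracy_floor=accuracy_floor)


def enumerate_panels(
    passing_ids: list[str],
    size_min: int = 3,
    size_max: int = 5,
    cap: int = 250_000,
) -> list[tuple[str, ...]]:
    """All transcript subsets of each size, lexicographically ordered.

    The count equals ``sum_s C(n, s)``; if it would exceed ``cap`` the
    search refuses rather than silently subsampling.
    """
    if size_min > size_max:
        raise ValueError("size_min must be <= size_max")
    ids = sorted(passing_ids)
    if len(ids) < size_min:
        raise ValueError(
            f"need at least {size_min} passing transcripts, got {len(ids)}"
        )
    total = sum(
        math.comb(len(ids), s) for s in range(size_min, min(size_max, len(ids)) + 1)
    )
    if total > cap:
        raise ValueError(
            f"{total} panels exceed the cap of {cap}; tighten the screening step"
        )
    panels: list[tuple[str, ...]] = []
    for s in range(size_min, min(size_max, len(ids)) + 1):
        panels.extend(itertools.combinations(ids, s))
    return panels


@dataclass
class PanelEvaluation:
    """One transcript panel with its frozen model and both cohort metrics.

    ``threshold_gap`` is the width of the separating posterior gap on
    training (min positive score minus max negative score; <= 0 when the
    cohorts overlap) and drives the threshold-stability criterion of
    representative selection.
    """

    transcripts: tuple[str, ...]
    fit: GaussianHMMFit
    state_to_class: tuple[int, ...]
    threshold: float
    threshold_gap: float
    metrics_train: Metrics
    metrics_valid: Metrics
    youden_j: float | None
    mapping_tie: bool = False

    def to_dict(self) -> dict:
        return {
            "transcripts": list(self.transcripts),
            "state_to_class": list(self.state_to_class),
            "threshold": self.threshold,
            "threshold_gap": self.threshold_gap,
            "metrics_train": self.metrics_train.to_dict(),
            "metrics_valid": self.metrics_valid.to_dict(),
            "youden_j": self.youden_j,
            "fit": self.fit.to_dict(),
        }


def _panel_scores(fit: GaussianHMMFit, state_to_class: np.ndarray, obs: np.ndarray) -> np.ndarray:
    gamma, _ = forward_backward(fit, obs)
    return gamma[:, state_to_class == 1].sum(axis=1)


def evaluate_panel(
    panel_ids: tuple[str, ...],
    train: pd.DataFrame,
    valid: pd.DataFrame,
    labels_train: pd.Series,
    labels_valid: pd.Series,
    spec: GaussianHMMSpec | None = None,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 300,
) -> PanelEvaluation:
    """Fit on training only; freeze model, state map and threshold; then
    score validation.  Validation data never touch the fitting path."""
    for tid in panel_ids:
        if tid not in train.index or tid not in valid.index:
            raise KeyError(f"panel transcript {tid!r} missing from a matrix")
    spec = spec or GaussianHMMSpec(n_states=2, n_features=len(panel_ids))
    if spec.n_features != len(panel_ids):
        spec = GaussianHMMSpec(
            n_states=spec.n_states,
            n_features=len(panel_ids),
            sequence_mode=spec.sequence_mode,
        )
    y_tr = labels_train.loc[train.columns].to_numpy().astype(int)
    y_va = labels_valid.loc[valid.columns].to_numpy().astype(int)
    obs_tr = train.loc[list(panel_ids)].to_numpy(dtype=float).T
    obs_va = valid.loc[list(panel_ids)].to_numpy(dtype=float).T

    fit = fit_em(obs_tr, spec, n_restarts=n_restarts, max_iter=max_iter, seed=seed)
    gamma_tr, _ = forward_backward(fit, obs_tr)
    mass_pos = gamma_tr[y_tr == 1].sum(axis=0)
    mass_neg = gamma_tr[y_tr == 0].sum(axis=0)
    mapping_tie = bool(np.any(np.isclose(mass_pos, mass_neg)))
    state_to_class = np.where(mass_pos >= mass_neg, 1, 0)
    scores_tr = gamma_tr[:, state_to_class == 1].sum(axis=1)

    threshold, _ = optimize_threshold(scores_tr, y_tr)
    pos_tr, neg_tr = scores_tr[y_tr == 1], scores_tr[y_tr == 0]
    gap = float(pos_tr.min() - neg_tr.max()) if (pos_tr.size and neg_tr.size) else 0.0

    m_tr = compute_metrics(*_confusion(scores_tr, y_tr, threshold), auc=roc_auc(scores_tr, y_tr))
    scores_va = _panel_scores(fit, state_to_class, obs_va)
    m_va = compute_metrics(*_confusion(scores_va, y_va, threshold), auc=roc_auc(scores_va, y_va))
    return PanelEvaluation(
        transcripts=tuple(panel_ids),
        fit=fit,
        state_to_class=tuple(int(c) for c in state_to_class),
        threshold=threshold,
        threshold_gap=gap,
        metrics_train=m_tr,
        metrics_valid=m_va,
        youden_j=m_va.youden_j,
        mapping_tie=mapping_tie,
    )


def _n_mstrg(transcripts: tuple[str, ...]) -> int:
    return sum(t.startswith("MSTRG") for t in transcripts)


def select_representative(evaluations: list[PanelEvaluation]) -> PanelEvaluation:
    """Deterministic representative among performance-equivalent panels.

    Criteria ladder: (1) maximize min(train, validation accuracy);
    (2) maximize the training separating-gap width (threshold stability);
    (3) prefer smaller panels; (4) prefer fewer unannotated MSTRG
    transcripts; (5) lexicographically smallest transcript tuple.
    """
    if not evaluations:
        raise ValueError("no panel evaluations to select from")

    def key(ev: PanelEvaluation):
        return (
            -min(ev.metrics_train.accuracy, ev.metrics_valid.accuracy),
            -ev.threshold_gap,
            len(ev.transcripts),
            _n_mstrg(ev.transcripts),
            ev.transcripts,
        )

    return min(evaluations, key=key)


def search_panels(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    labels_train: pd.Series,
    labels_valid: pd.Series,
    candidate_ids: list[str],
    spec: GaussianHMMSpec | None = None,
    seed: int = 0,
    size_min: int = 3,
    size_max: int = 5,
    accuracy_floor: float = 1.0,
    min_candidates: int | None = None,
    n_restarts: int = 4,
    cap: int = 250_000,
) -> tuple[ScreenResult, list[PanelEvaluation], PanelEvaluation]:
    """Full screen -> enumerate -> evaluate -> select pipeline for one task.

    When fewer transcripts pass the perfect-separation screen than
    ``min_candidates`` (default: the minimum panel size), the candidate
    pool is backfilled with the highest-accuracy non-degenerate
    transcripts — panels are built from perfect or near-perfect
    separators, so a panel can always be formed.
    """
    if min_candidates is None:
        min_candidates = size_min
    screen = screen_single(
        train, labels_train, candidate_ids,
        spec=GaussianHMMSpec(
            n_states=(spec.n_states if spec else 2), n_features=1,
            sequence_mode=(spec.sequence_mode if spec else "per_sample"),
        ),
        seed=seed, accuracy_floor=accuracy_floor, n_restarts=n_restarts,
    )
    pool = screen.passing_ids
    if len(pool) < max(min_candidates, size_min) and min_candidates > 0:
        ranked = screen.table[~screen.table["degenerate"]].sort_values(
            ["accuracy"], ascending=False, kind="stable"
        )
        for tid in ranked.index:
            if tid not in pool:
                pool.append(tid)
            if len(pool) >= max(min_candidates, size_min):
                break
        pool = sorted(pool)
    panels = enumerate_panels(pool, size_min=size_min, size_max=size_max, cap=cap)
    evaluations = [
        evaluate_panel(
            p, train, valid, labels_train, labels_valid,
            spec=spec, seed=seed, n_restarts=n_restarts,
        )
        for p in panels
    ]
    return screen, evaluations, select_representative(evaluations)
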