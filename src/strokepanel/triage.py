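"""Task label definitions and the hierarchical triage cascade.

The cascade mirrors acute stroke triage: stage 1 rules hemorrhagic stroke
in or out on every sample; stage 2 separates ischemic stroke from stroke
mimics among stage-1 negatives; samples called ischemic are then assessed
for the thrombolysis window (onset <= 3.5 h, i.e. the 4.5 h guideline
minus a 60-minute door-to-needle target) and for severity (NIHSS >= 5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panelsearch import Metrics, PanelEvaluation, _panel_scores, compute_metrics, roc_auc

__all__ = [
    "TaskDefinition",
    "TriageReport",
    "TASKS",
    "build_labels",
    "run_cascade",
    "held_out_audit",
]

STROKE_CLASSES = ("hemorrhagic", "ischemic", "mimic")


@dataclass(frozen=True)
class TaskDefinition:
    """One binary classification task over sample metadata.

    ``name`` is one of hemorrhage_vs_rest, ischemic_vs_mimic, window_3p5h,
    severity_nihss.  Eligibility and the positive-label rule follow the
    cohort design: the window task runs on ischemic samples with a known
    onset (positive iff onset_hours <= time_cutoff_h, inclusive); the
    severity task runs on ischemic samples with an NIHSS score (positive
    iff NIHSS >= nihss_cutoff).
    """

    name: str
    time_cutoff_h: float = 3.5
    nihss_cutoff: int = 5

    def __post_init__(self) -> None:
        if self.name not in (
            "hemorrhage_vs_rest", "ischemic_vs_mimic", "window_3p5h", "severity_nihss"
        ):
            raise ValueError(f"unknown task {self.name!r}")
        if self.time_cutoff_h <= 0 or self.nihss_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


TASKS = {
    name: TaskDefinition(name)
    for name in ("hemorrhage_vs_rest", "ischemic_vs_mimic", "window_3p5h", "severity_nihss")
}


def build_labels(
    metadata: pd.DataFrame, task: TaskDefinition, require_both_classes: bool = True
) -> tuple[pd.Series, pd.Series]:
    """Binary labels plus eligibility mask for one task.

    Samples failing eligibility (wrong diagnosis stratum, missing onset or
    NIHSS) carry label NA and mask False.
    """
    diag = metadata["diagnosis"]
    if task.name == "hemorrhage_vs_rest":
        eligible = diag.isin(STROKE_CLASSES)
        positive = diag == "hemorrhagic"
    elif task.name == "ischemic_vs_mimic":
        eligible = diag.isin(["ischemic", "mimic"])
        positive = diag == "ischemic"
    elif task.name == "window_3p5h":
        onset = metadata["onset_hours"]
        eligible = (diag == "ischemic") & onset.notna()
        positive = onset <= task.time_cutoff_h
    else:  # severity_nihss
        nihss = metadata["nihss"]
        eligible = (diag == "ischemic") & nihss.notna()
        positive = nihss >= task.nihss_cutoff
    labels = pd.Series(np.nan, index=metadata.index, dtype=float)
    labels[eligible] = positive[eligible].astype(float)
    if require_both_classes:
        vals = labels.dropna().unique()
        if len(vals) < 2:
            raise ValueError(
                f"task {task.name}: need both classes after eligibility filtering"
            )
    return labels, eligible


@dataclass
class TriageReport:
    """Per-sample cascade calls and per-stage cohort metrics.

    ``calls`` is a per-sample DataFrame (posterior and call per stage;
    stage-2/window/severity fields are NaN where the cascade did not reach
    them); ``stage_metrics`` maps stage name to a Metrics (or None when no
    labelled samples were available); ``config_hash`` fingerprints the
    models and thresholds used.
    """

    calls: pd.DataFrame
    stage_metrics: dict
    config_hash: str
    provenance: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "provenance": self.provenance,
                "stage_metrics": {
                    k: (m.to_dict() if m is not None else None)
                    for k, m in self.stage_metrics.items()
                },
                "calls": self.calls.replace({np.nan: None}).to_dict(orient="index"),
            },
            indent=1,
        )

    def calls_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t")


def _hash_models(models: dict[str, PanelEvaluation]) -> str:
    payload = {
        name: {
            "transcripts": list(pe.transcripts),
            "threshold": pe.threshold,
            "means": pe.fit.means.tolist(),
        }
        for name, pe in sorted(models.items())
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _stage_scores(pe: PanelEvaluation, expr: pd.DataFrame, samples: pd.Index) -> pd.Series:
    missing = [t for t in pe.transcripts if t not in expr.index]
    if missing:
        raise KeyError(f"panel transcript(s) missing from study: {missing}")
    obs = expr.loc[list(pe.transcripts), samples].to_numpy(dtype=float).T
    scores = _panel_scores(pe.fit, np.asarray(pe.state_to_class), obs)
    return pd.Series(scores, index=samples)


def _stage_metrics(
    scores: pd.Series, calls: pd.Series, labels: pd.Series
) -> Metrics | None:
    ok = labels.loc[scores.index].notna()
    if not ok.any():
        return None
    y = labels.loc[scores.index][ok].to_numpy().astype(int)
    s = scores[ok].to_numpy()
    c = calls[ok].to_numpy().astype(bool)
    tp = int(np.sum(c & (y == 1)))
    fp = int(np.sum(c & (y == 0)))
    fn = int(np.sum(~c & (y == 1)))
    tn = int(np.sum(~c & (y == 0)))
    return compute_metrics(tp, fp, fn, tn, auc=roc_auc(s, y))


def run_cascade(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    models: dict[str, PanelEvaluation],
    conditional: bool = True,
    tasks: dict[str, TaskDefinition] | None = None,
) -> TriageReport:
    """Apply the staged classifiers to a (preprocessed) cohort.

    ``expression`` must be on the same log2-CPM scale the models were
    trained on.  ``models`` maps stage names (``hemorrhage``, ``ischemic``
    and optionally ``window``, ``severity``) to frozen PanelEvaluations.
    With ``conditional=True`` (clinical logic) stage 2 runs only on
    stage-1 negatives and window/severity only on ischemic-called
    samples; with False every stage scores every sample (research mode).
    """
    tasks = tasks or TASKS
    samples = pd.Index(metadata.index)
    if "hemorrhage" not in models or "ischemic" not in models:
        raise ValueError("cascade needs at least 'hemorrhage' and 'ischemic' models")

    calls = pd.DataFrame(index=samples)
    hem = models["hemorrhage"]
    hem_scores = _stage_scores(hem, expression, samples)
    hem_call = hem_scores >= hem.threshold
    calls["hemorrhage_posterior"] = hem_scores
    calls["hemorrhage_call"] = hem_call.astype(int)

    stage2_samples = samples[~hem_call] if conditional else samples
    isch = models["ischemic"]
    isch_scores = _stage_scores(isch, expression, stage2_samples)
    isch_call = isch_scores >= isch.threshold
    calls["ischemic_posterior"] = isch_scores.reindex(samples)
    calls["ischemic_call"] = isch_call.astype(int).reindex(samples)

    ischemic_called = isch_call.index[isch_call]
    downstream = ischemic_called if conditional else samples
    for stage in ("window", "severity"):
        if stage not in models:
            continue
        pe = models[stage]
        sc = _stage_scores(pe, expression, downstream)
        calls[f"{stage}_posterior"] = sc.reindex(samples)
        calls[f"{stage}_call"] = (sc >= pe.threshold).astype(int).reindex(samples)

    # ground-truth labels where metadata allows them
    label_map = {
        "hemorrhage": "hemorrhage_vs_rest",
        "ischemic": "ischemic_vs_mimic",
        "window": "window_3p5h",
        "severity": "severity_nihss",
    }
    stage_metrics: dict[str, Metrics | None] = {}
    for stage, task_name in label_map.items():
        if stage not in models or f"{stage}_posterior" not in calls:
            continue
        labels, _ = build_labels(metadata, tasks[task_name], require_both_classes=False)
        scored = calls[f"{stage}_posterior"].dropna().index
        stage_metrics[stage] = _stage_metrics(
            calls.loc[scored, f"{stage}_posterior"],
            calls.loc[scored, f"{stage}_call"],
            labels,
        )

    provenance = [
        {"stage": name, "transcripts": list(models[name].transcripts),
         "threshold": models[name].threshold}
        for name in models
    ]
    return TriageReport(
        calls=calls,
        stage_metrics=stage_metrics,
        config_hash=_hash_models(models),
        provenance=provenance,
    )


def held_out_audit(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    models: dict[str, PanelEvaluation],
    conditional: bool = True,
) -> dict:
    """Run the cascade on an excluded cohort and report per-stage metrics.

    Classes absent from the cohort yield undefined (None) sensitivity or
    specificity flags rather than errors; an empty cohort yields an empty
    report.
    """
    if len(metadata) == 0:
        return {"n_samples": 0, "stage_metrics": {}}
    report = run_cascade(expression, metadata, models, conditional=conditional)
    return {
        "n_samples": int(len(metadata)),
        "stage_metrics": report.stage_metrics,
        "calls": report.calls,
        "config_hash": report.config_hash,
    }
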