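import numpy as np
import pandas as pd
import pytest

import strokepanel as sp


@pytest.fixture(scope="session")
def cohort_study():
    """Training-cohort-shaped synthetic study (13/29/42 samples)."""
    cfg = sp.SimulationConfig(n_transcripts=400, seed=42)
    return sp.simulate_study(cfg)


@pytest.fixture(scope="session")
def normalized_cohort(cohort_study):
    return sp.normalize_study(cohort_study)


def make_panel_problem(seed: int, signature_log2fc: float = 4.0, n_sig: int = 3):
    """A train/validation pair with a planted separating signature.

    One study of double cohort size (26/58/84) is split in half so the two
    halves share transcripts; the hemorrhage task then has `n_sig`
    perfectly separating transcripts among the rest (53 transcripts total
    when n_sig=3: 3 task-separating + 50 task-noise).
    """
    cfg = sp.SimulationConfig(
        n_transcripts=44 + 3 * n_sig,
        n_signature_per_class=n_sig,
        signature_log2fc=signature_log2fc,
        n_time_transcripts=0,
        n_severity_transcripts=0,
        class_sizes={"hemorrhagic": 26, "ischemic": 58, "mimic": 84},
        seed=seed,
    )
    study = sp.simulate_study(cfg)
    train, valid = sp.split_train_validation(study, 0.5, seed)
    norm_tr = sp.normalize_study(train)
    norm_va = sp.normalize_study(valid)
    common = norm_tr.log_expression.index.intersection(norm_va.log_expression.index)
    lab_tr, _ = sp.build_labels(train.sample_metadata, sp.TASKS["hemorrhage_vs_rest"])
    lab_va, _ = sp.build_labels(valid.sample_metadata, sp.TASKS["hemorrhage_vs_rest"])
    return {
        "train": norm_tr.log_expression.loc[common],
        "valid": norm_va.log_expression.loc[common],
        "labels_train": lab_tr,
        "labels_valid": lab_va,
        "planted": set(study.truth["signature"]["hemorrhagic"]),
        "study": study,
    }


def make_null_problem(seed: int):
    """Label-independent train/validation pair (no planted effects)."""
    cfg = sp.SimulationConfig(
        n_transcripts=53,
        n_signature_per_class=0,
        n_time_transcripts=0,
        n_severity_transcripts=0,
        class_sizes={"hemorrhagic": 26, "ischemic": 58, "mimic": 84},
        seed=seed,
    )
    study = sp.simulate_study(cfg)
    train, valid = sp.split_train_validation(study, 0.5, seed)
    norm_tr = sp.normalize_study(train)
    norm_va = sp.normalize_study(valid)
    common = norm_tr.log_expression.index.intersection(norm_va.log_expression.index)
    lab_tr, _ = sp.build_labels(train.sample_metadata, sp.TASKS["hemorrhage_vs_rest"])
    lab_va, _ = sp.build_labels(valid.sample_metadata, sp.TASKS["hemorrhage_vs_rest"])
    return {
        "train": norm_tr.log_expression.loc[common],
        "valid": norm_va.log_expression.loc[common],
        "labels_train": lab_tr,
        "labels_valid": lab_va,
    }


def brute_force_bh(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


def brute_force_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
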