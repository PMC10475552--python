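"""Temporal properties of connectivity states.

Mean dwell time (in windows), fraction of time per state and number of
state transitions for each subject, covariate-adjusted group comparisons,
and partial correlation of the metrics with epilepsy duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import glm_contrast, partial_pearson

__all__ = [
    "mean_dwell_time",
    "fraction_of_time",
    "n_transitions",
    "metrics_table",
    "compare_metrics",
    "duration_correlation",
]


def _check_vector(state_vector) -> np.ndarray:
    v = np.asarray(state_vector, dtype=int)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("state vector must be a nonempty 1-D sequence")
    return v


def run_lengths(state_vector):
    """Maximal consecutive runs as (state, length) pairs."""
    v = _check_vector(state_vector)
    change = np.flatnonzero(np.diff(v) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [v.size]])
    return [(int(v[s]), int(e - s)) for s, e in zip(starts, ends)]


def mean_dwell_time(state_vector, state: int) -> float:
    """Mean length (windows) of maximal consecutive runs of ``state``.

    A state the subject never visits has dwell time 0 — the convention under
    which group summaries include subjects that never enter a state (their
    large SDs are only consistent with zeros being counted).
    """
    v = _check_vector(state_vector)
    if state < 1:
        raise ValueError(f"unknown state id {state}; states are numbered from 1")
    lens = [ln for st, ln in run_lengths(v) if st == state]
    return float(np.mean(lens)) if lens else 0.0


def fraction_of_time(state_vector, state: int) -> float:
    """Proportion of windows spent in ``state``."""
    v = _check_vector(state_vector)
    return float((v == state).mean())


def n_transitions(state_vector) -> int:
    """Number of switches between different states."""
    v = _check_vector(state_vector)
    return int((np.diff(v) != 0).sum())


def metrics_table(assignments: np.ndarray, subject_ids=None,
                  k: int = None) -> pd.DataFrame:
    """Per-subject temporal metrics from a (n_subjects, n_windows) assignment.

    Columns: ``mdt_s<state>`` and ``frac_s<state>`` for each state plus
    ``transitions``.
    """
    A = np.asarray(assignments, dtype=int)
    if k is None:
        k = int(A.max())
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(A.shape[0])]
    rows = []
    for sid, vec in zip(subject_ids, A):
        row = {"subject_id": sid}
        for s in range(1, k + 1):
            row[f"mdt_s{s}"] = mean_dwell_time(vec, s)
            row[f"frac_s{s}"] = fraction_of_time(vec, s)
        row["transitions"] = n_transitions(vec)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_metrics(metrics: pd.DataFrame, group, age, sex,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Covariate-adjusted group comparison of each temporal metric.

    GLM ``metric ~ intercept + group + age + sex`` per metric column, with
    ``group`` coded 0 = control, 1 = patient.  Reports the group effect
    (adjusted patient-minus-control difference), t, p, significance at
    ``alpha`` and the raw group means.
    """
    group = np.asarray(group, dtype=float)
    X = np.column_stack([np.ones(len(group)), group,
                         np.asarray(age, float), np.asarray(sex, float)])
    rows = []
    value_cols = [c for c in metrics.columns if c != "subject_id"]
    for col in value_cols:
        y = metrics[col].to_numpy(dtype=float)
        est, t, p = glm_contrast(y, X, contrast_index=1)
        rows.append({
            "metric": col,
            "group_effect": est,
            "t": t,
            "p": p,
            "sig": p < alpha,
            "mean_patient": float(y[group == 1].mean()),
            "mean_control": float(y[group == 0].mean()),
        })
    return pd.DataFrame(rows)


def duration_correlation(metrics: pd.DataFrame, duration, age, sex,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Partial Pearson correlation of each metric with epilepsy duration.

    Both the metric and duration are residualised on age and sex (patients
    only; rows with missing duration are dropped).  Requires >= 5 patients.
    """
    duration = np.asarray(duration, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    keep = ~np.isnan(duration)
    if keep.sum() < 5:
        raise ValueError("need at least 5 patients with duration")
    cov = np.column_stack([age[keep], sex[keep]])
    rows = []
    value_cols = [c for c in metrics.columns if c != "subject_id"]
    for col in value_cols:
        y = metrics[col].to_numpy(dtype=float)[keep]
        if np.ptp(y) == 0:
            rows.append({"metric": col, "r": np.nan, "p": np.nan,
                         "sig": False, "note": "constant metric"})
            continue
        try:
            r, p = partial_pearson(y, duration[keep], cov)
        except ValueError as err:
            rows.append({"metric": col, "r": np.nan, "p": np.nan,
                         "sig": False, "note": str(err)})
            continue
        rows.append({"metric": col, "r": r, "p": p, "sig": p < alpha, "note": ""})
    return pd.DataFrame(rows)
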