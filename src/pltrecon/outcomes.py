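"""Clinical outcome definitions and predictive-performance metrics.

Thrombocytopenia (the study endpoint): mean of the last 12 platelet
measurements in the day +29..+180 window below 75e9/L (strict).  Engraftment:
first of three consecutive days with platelets >= 20e9/L.  Discrimination is
summarized as AUROC with a percentile-bootstrap confidence interval, accuracy
as the mean relative deviation of predicted from observed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "THROMBOCYTOPENIA_THRESHOLD",
    "ENGRAFTMENT_THRESHOLD",
    "classify_thrombocytopenia",
    "thrombocytopenia_score",
    "engraftment_day",
    "mean_relative_deviation",
    "auroc",
    "bootstrap_auroc_ci",
    "crossvalidate",
    "evaluate_cohort",
    "EvaluationSummary",
]

THROMBOCYTOPENIA_THRESHOLD = 75.0  # 1e9/L
ENGRAFTMENT_THRESHOLD = 20.0  # 1e9/L


def _window_values(times, values, window_start, window_end, k):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("observations must be time-sorted")
    mask = (times >= window_start) & (times <= window_end)
    selected = values[mask]
    if selected.size == 0:
        return None
    return selected[-min(k, selected.size):]


def thrombocytopenia_score(
    times,
    values,
    window_start: float = 29.0,
    window_end: float = 180.0,
    k: int = 12,
) -> float | None:
    """Mean of the last ``k`` values in the prediction window, or None if empty.

    Subjects with fewer than ``k`` in-window measurements contribute the mean
    of all available ones (at least one).
    """
    last = _window_values(times, values, window_start, window_end, k)
    if last is None:
        return None
    return float(np.mean(last))


def classify_thrombocytopenia(
    times,
    values,
    window_start: float = 29.0,
    window_end: float = 180.0,
    k: int = 12,
    threshold: float = THROMBOCYTOPENIA_THRESHOLD,
) -> bool | None:
    """True iff the last-``k`` mean is strictly below ``threshold``.

    Returns ``None`` (undefined, subject excluded) when no measurement falls
    inside the window — never a silent ``False``.
    """
    score = thrombocytopenia_score(times, values, window_start, window_end, k)
    if score is None:
        return None
    return score < threshold


def engraftment_day(
    days,
    values,
    threshold: float = ENGRAFTMENT_THRESHOLD,
    consecutive: int = 3,
    start_day: float | None = None,
) -> int | None:
    """First of ``consecutive`` days with platelet counts >= ``threshold``.

    ``days`` must be consecutive integer days (resample a trajectory first).
    ``start_day`` restricts the scan, which matters when counts are still
    falling from baseline through the threshold early on: engraftment means
    *recovery*, so population summaries scan from the post-HCT nadir
    (see docs/methods.md).  Returns None if no qualifying run exists.
    """
    days = np.asarray(days)
    values = np.asarray(values, dtype=float)
    if days.size != values.size:
        raise ValueError("days and values must have the same length")
    if days.size and (np.any(np.diff(days) != 1) or np.any(days != np.round(days))):
        raise ValueError("engraftment_day requires consecutive integer days")
    ok = values >= threshold
    for i in range(days.size - consecutive + 1):
        if start_day is not None and days[i] < start_day:
            continue
        if ok[i : i + consecutive].all():
            return int(days[i])
    return None


def mean_relative_deviation(predicted, observed) -> float:
    """Mean over times of |pred - obs| / obs; zero-valued observations skipped."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must be paired")
    keep = observed > 0
    if not keep.all():
        warnings.warn(
            f"skipping {int((~keep).sum())} zero-valued observation(s) in "
            "mean_relative_deviation",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no positive observations to compare against")
    return float(np.mean(np.abs(predicted[keep] - observed[keep]) / observed[keep]))


def auroc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUROC with midrank tie handling."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_auroc_ci(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subjects; degenerate resamples are skipped."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUROC requires both classes present")
    rng = np.random.default_rng(seed)
    n = scores.size
    stats = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lab = labels[idx]
        if lab.all() or not lab.any():
            skipped += 1
            continue
        stats.append(roc_auc_score(lab, scores[idx]))
    if skipped:
        warnings.warn(
            f"skipped {skipped} single-class bootstrap resample(s)", stacklevel=2
        )
    if not stats:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class EvaluationSummary:
    """Per-cutoff discrimination and accuracy of the forecasts on a cohort."""

    cutoffs: tuple
    auroc: dict = field(default_factory=dict)  # cutoff -> point estimate
    auroc_ci: dict = field(default_factory=dict)  # cutoff -> (lo, hi)
    mean_relative_deviations: dict = field(default_factory=dict)  # cutoff -> array
    n_subjects: int = 0
    n_thrombocytopenia: int = 0

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_thrombocytopenia": self.n_thrombocytopenia,
            "cutoffs": list(self.cutoffs),
            "auroc": {str(c): self.auroc[c] for c in self.cutoffs},
            "auroc_ci": {str(c): list(self.auroc_ci[c]) for c in self.cutoffs},
            "mean_relative_deviation": {
                str(c): float(np.mean(self.mean_relative_deviations[c]))
                for c in self.cutoffs
            },
        }


def _forecast_scores(subjects, pop, cutoff, **forecast_kwargs):
    """Risk scores, labels and MRDs for one cutoff over a list of subjects."""
    from .forecast import forecast  # deferred: avoids a module cycle

    scores, labels, mrds = [], [], []
    for subject in subjects:
        label = subject.observed_label()
        if label is None:
            continue
        result = forecast(subject, pop, cutoff, **forecast_kwargs)
        if result.thrombocytopenia_score is None:
            continue
        scores.append(result.thrombocytopenia_score)
        labels.append(label)
        obs = subject.observations_after(cutoff)
        if obs[0].size:
            pred = result.trajectory.at(obs[0])
            mrds.append(mean_relative_deviation(pred, obs[1]))
    return np.asarray(scores), np.asarray(labels, dtype=bool), np.asarray(mrds)


def evaluate_cohort(
    subjects,
    pop,
    cutoffs=(7, 14, 21, 28),
    n_boot: int = 1000,
    seed=None,
    **forecast_kwargs,
) -> EvaluationSummary:
    """MAP-forecast every subject at each cutoff and summarize performance."""
    rng = np.random.default_rng(seed)
    summary = EvaluationSummary(cutoffs=tuple(cutoffs))
    for cutoff in cutoffs:
        scores, labels, mrds = _forecast_scores(subjects, pop, cutoff, **forecast_kwargs)
        summary.auroc[cutoff] = auroc(scores, labels)
        summary.auroc_ci[cutoff] = bootstrap_auroc_ci(
            scores, labels, n_boot=n_boot, seed=rng
        )
        summary.mean_relative_deviations[cutoff] = mrds
        summary.n_subjects = labels.size
        summary.n_thrombocytopenia = int(labels.sum())
    return summary


def crossvalidate(
    subjects,
    pop,
    n_folds: int = 5,
    seed=None,
    cutoffs=(7, 14, 21, 28),
    n_boot: int = 200,
    **forecast_kwargs,
):
    """Fold-wise forecast performance (fold assignment by subject).

    Population priors are fixed (re-estimating them is out of scope), so the
    cross-validation examines the fold-to-fold stability of the metrics.
    Folds in which only one outcome class occurs are flagged with NaN metrics.
    Returns a pandas DataFrame with one row per (fold, cutoff).
    """
    import pandas as pd

    subjects = list(subjects)
    if len(subjects) < n_folds:
        raise ValueError("need at least n_folds subjects")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(len(subjects)) % n_folds
    rows = []
    for fold in range(n_folds):
        members = [s for s, a in zip(subjects, assignment) if a == fold]
        for cutoff in cutoffs:
            scores, labels, mrds = _forecast_scores(
                members, pop, cutoff, **forecast_kwargs
            )
            row = {
                "fold": fold,
                "cutoff": cutoff,
                "n": int(labels.size),
                "n_thrombocytopenia": int(labels.sum()),
            }
            if labels.size and 0 < labels.sum() < labels.size:
                row["auroc"] = auroc(scores, labels)
                lo, hi = bootstrap_auroc_ci(scores, labels, n_boot=n_boot, seed=rng)
                row["auroc_lo"], row["auroc_hi"] = lo, hi
            else:  # degenerate fold: flagged, not silently dropped
                row["auroc"] = row["auroc_lo"] = row["auroc_hi"] = np.nan
            row["mrd"] = float(np.mean(mrds)) if mrds.size else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
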