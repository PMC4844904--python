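"""The framework proper, plus the LOSO and s-LOO comparison baselines.

The framework trains one classifier per vocal test on that test's
selected features, evaluates it by leave-one-out over subjects (each
subject has exactly one recording per test, so plain LOO never splits a
subject), and fuses the per-test predictions by majority vote.

Baselines:

LOSO
    all recordings pooled into one matrix; each subject's recordings are
    held out together and predicted from everyone else's recordings;
    scored per *recording* (n_subjects x n_tests predictions).

s-LOO
    each subject's recordings are collapsed feature-wise to summary
    statistics (central tendency and dispersion), then a per-subject
    leave-one-out runs on the summary vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .classifiers import ClassifierSpec, fit_predict
from .dataset_io import RecordingTable, feature_columns
from .feature_selection import (
    FeatureSelectionResult,
    SelectionPlan,
    build_selection_plan,
    select_features,
)
from .metrics_report import MetricsReport, compute_metrics, confusion
from .preprocessing import (
    VocalTestSubset,
    apply_zscore,
    separate_by_test,
    zscore_normalize,
    zscore_params,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# per-subset leave-one-out
# --------------------------------------------------------------------------

def loo_predict_subset(
    subset: VocalTestSubset,
    features,
    spec: ClassifierSpec,
    fold_safe: bool = False,
) -> np.ndarray:
    """Leave-one-out predictions for one vocal test.

    ``features`` are 1-based feature indices; the classifier sees only
    those columns.  With ``fold_safe`` the z-score transform is re-fit on
    each training fold and applied to the held-out row (leakage-free);
    otherwise the matrix is used as given.
    """
    cols = np.asarray(sorted(features), dtype=int) - 1
    if cols.size == 0:
        raise ValueError("need at least one feature")
    if subset.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    X = subset.matrix[:, cols]
    y = subset.labels
    preds = np.empty(subset.n_subjects, dtype=int)
    for i in range(subset.n_subjects):
        mask = np.ones(subset.n_subjects, dtype=bool)
        mask[i] = False
        tr_X, te_X = X[mask], X[~mask]
        if fold_safe:
            mean, sd = zscore_params(tr_X)
            tr_X = apply_zscore(tr_X, mean, sd)
            te_X = apply_zscore(te_X, mean, sd)
        preds[i] = fit_predict(spec, tr_X, y[mask], te_X)[0]
    return preds


# --------------------------------------------------------------------------
# majority voting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionMatrix:
    """Per-(test, subject) predicted labels; omitted tests are simply absent."""

    entries: dict[tuple[int, str], int]
    subject_ids: tuple[str, ...]
    included_tests: tuple[int, ...]

    def votes_for(self, subject_id: str) -> list[int]:
        return [
            self.entries[(t, subject_id)]
            for t in self.included_tests
            if (t, subject_id) in self.entries
        ]


def majority_vote(preds: PredictionMatrix) -> pd.Series:
    """Fuse per-test votes into one label per subject.

    A subject is labelled PD (1) iff at least half of its votes are 1:
    strict majorities decide, and an exact tie goes to PD — in a
    screening setting a false negative is costlier than a false positive.
    """
    out = {}
    for sid in preds.subject_ids:
        votes = preds.votes_for(sid)
        if not votes:
            raise ValueError(f"subject {sid!r} received no votes")
        ones = sum(votes)
        out[sid] = 1 if ones * 2 >= len(votes) else 0
    return pd.Series(out, name="predicted")


# --------------------------------------------------------------------------
# framework runner
# --------------------------------------------------------------------------

@dataclass
class FrameworkResult:
    metrics: MetricsReport
    per_test_accuracy: pd.Series  # index test_id, accuracy % of included tests
    plan: SelectionPlan
    predictions: PredictionMatrix
    subject_predictions: pd.Series  # voted label per subject
    truth: pd.Series  # true label per subject


def run_framework(
    table: RecordingTable,
    mode: str = "a-mcfs",
    spec: ClassifierSpec = ClassifierSpec("svm_rbf"),
    alpha: float = 0.05,
    fallback_k: int = 4,
    fold_safe: bool = False,
) -> FrameworkResult:
    """Separate -> normalise -> select -> per-test LOO -> majority vote.

    The default protocol fits the z-score transform and the feature
    selection once on the full data before cross-validation (the
    historical protocol this framework reproduces; the held-out subject
    influences scaling and selection).  With ``fold_safe`` the entire
    pipeline — normalisation, selection, and the MCFS/A-MCFS plan — is
    re-fit from scratch for each held-out subject, so no information
    about the held-out subject leaks into training.  ``plan`` in the
    result is always the full-data plan (in fold-safe mode the operative
    per-fold plans vary and the full-data plan is reported for
    reference).
    """
    subsets = separate_by_test(table)
    truth = table.subject_labels()
    subject_ids = tuple(truth.index)

    normed = [zscore_normalize(s) for s in subsets]
    results = [select_features(s, alpha) for s in normed]
    plan = build_selection_plan(results, mode=mode, fallback_k=fallback_k, alpha=alpha)

    entries: dict[tuple[int, str], int] = {}
    if not fold_safe:
        for s in normed:
            feats = plan.per_test_features.get(s.test_id)
            if feats is None:
                continue
            preds = loo_predict_subset(s, feats, spec, fold_safe=False)
            for sid, p in zip(subject_ids, preds):
                entries[(s.test_id, sid)] = int(p)
    else:
        n = len(subject_ids)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            fold_results: list[FeatureSelectionResult] = []
            fold_norm: dict[int, tuple[np.ndarray, np.ndarray]] = {}
            for s in subsets:
                mean, sd = zscore_params(s.matrix[mask])
                tr = apply_zscore(s.matrix[mask], mean, sd)
                te = apply_zscore(s.matrix[~mask], mean, sd)
                fold_norm[s.test_id] = (tr, te)
                tr_subset = VocalTestSubset(
                    s.test_id, tr, s.labels[mask], tuple(np.array(subject_ids)[mask])
                )
                fold_results.append(select_features(tr_subset, alpha))
            fold_plan = build_selection_plan(
                fold_results, mode=mode, fallback_k=fallback_k, alpha=alpha
            )
            for s in subsets:
                feats = fold_plan.per_test_features.get(s.test_id)
                if feats is None:
                    continue
                cols = np.asarray(sorted(feats)) - 1
                tr, te = fold_norm[s.test_id]
                pred = fit_predict(spec, tr[:, cols], s.labels[mask], te[:, cols])[0]
                entries[(s.test_id, subject_ids[i])] = int(pred)

    included = tuple(sorted({t for t, _ in entries}))
    pm = PredictionMatrix(entries, subject_ids, included)
    voted = majority_vote(pm).loc[list(subject_ids)]
    metrics = compute_metrics(confusion(truth.to_numpy(), voted.to_numpy()))

    per_test = {}
    for t in included:
        pairs = [(entries[(t, sid)], truth[sid]) for sid in subject_ids if (t, sid) in entries]
        pred_t = np.array([p for p, _ in pairs])
        true_t = np.array([tr for _, tr in pairs])
        per_test[t] = 100.0 * float((pred_t == true_t).mean())
    per_test_acc = pd.Series(per_test, name="accuracy").sort_index()

    return FrameworkResult(metrics, per_test_acc, plan, pm, voted, truth)


# --------------------------------------------------------------------------
# LOSO baseline (per-recording scoring)
# --------------------------------------------------------------------------

def loso_cv(table: RecordingTable, spec: ClassifierSpec) -> MetricsReport:
    """Leave-one-subject-out over the pooled recording matrix.

    All n_subjects x n_tests recordings form one matrix (z-scored
    column-wise, no feature selection); each subject's recordings are
    held out together and each is predicted individually, so the metrics
    are per recording.
    """
    if table.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    fcols = feature_columns(table.n_features)
    X = table.data[fcols].to_numpy(dtype=float)
    y = table.data["label"].to_numpy(dtype=int)
    subj = table.data["subject_id"].to_numpy()
    mean, sd = zscore_params(X)
    X = apply_zscore(X, mean, sd)
    preds = np.empty(len(y), dtype=int)
    for sid in table.subjects:
        mask = subj != sid
        preds[~mask] = fit_predict(spec, X[mask], y[mask], X[~mask])
    return compute_metrics(confusion(y, preds))


# --------------------------------------------------------------------------
# s-LOO baseline (summary vectors, per-subject scoring)
# --------------------------------------------------------------------------

def _mean_abs_dev(a: np.ndarray, axis: int) -> np.ndarray:
    return np.mean(np.abs(a - a.mean(axis=axis, keepdims=True)), axis=axis)


SUMMARY_STATS = ("mean", "median", "trimmed_mean25", "sd", "mad", "iqr")

# the numbering convention of the summary-statistic codes:
# 1 mean, 2 median, 3 trimmed mean (25% removed), 4 SD, 5 mean absolute
# deviation, 6 interquartile range
STAT_CODES = {
    "1-4": ("mean", "sd"),
    "2-5": ("median", "mad"),
    "3-6": ("trimmed_mean25", "iqr"),
    "all": SUMMARY_STATS,
}


def sloo_summarize(
    table: RecordingTable,
    stats=("mean", "sd"),
    trim_fraction: float = 0.125,
) -> pd.DataFrame:
    """Collapse each subject's recordings to per-feature summary statistics.

    Returns one row per subject (table order) with columns in
    statistic-major, feature-minor order (``mean_f1 .. mean_fN, sd_f1,
    ...``) plus a ``label`` column.  ``trimmed_mean25`` removes 25% of
    the values in total, ``trim_fraction`` = 12.5% from each tail by
    default (set 0.25 for the per-tail reading).  ``mad`` is the mean
    absolute deviation about the mean.
    """
    if not stats:
        raise ValueError("need at least one summary statistic")
    unknown = set(stats) - set(SUMMARY_STATS)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}")
    fcols = feature_columns(table.n_features)
    order = table.subjects
    # (subjects, tests, features) array in fixed subject/test order
    wide = (
        table.data.set_index(["subject_id", "test_id"])[fcols]
        .loc[order]
        .to_numpy()
        .reshape(len(order), table.n_tests, table.n_features)
    )
    funcs = {
        "mean": lambda a: a.mean(axis=1),
        "median": lambda a: np.median(a, axis=1),
        "trimmed_mean25": lambda a: sp_stats.trim_mean(a, trim_fraction, axis=1),
        "sd": lambda a: a.std(axis=1, ddof=1),
        "mad": lambda a: _mean_abs_dev(a, axis=1),
        "iqr": lambda a: sp_stats.iqr(a, axis=1),
    }
    blocks = []
    names = []
    for st in stats:
        blocks.append(funcs[st](wide))
        names.extend(f"{st}_f{j}" for j in range(1, table.n_features + 1))
    out = pd.DataFrame(np.hstack(blocks), index=pd.Index(order, name="subject_id"), columns=names)
    out["label"] = table.subject_labels().to_numpy()
    return out


def sloo_cv(
    table: RecordingTable,
    stats=("mean", "sd"),
    spec: ClassifierSpec = ClassifierSpec("svm_linear"),
    trim_fraction: float = 0.125,
) -> MetricsReport:
    """Summarised leave-one-out: z-scored summary vectors, one prediction per subject."""
    summary = sloo_summarize(table, stats, trim_fraction)
    y = summary.pop("label").to_numpy(dtype=int)
    X = summary.to_numpy(dtype=float)
    mean, sd = zscore_params(X)
    X = apply_zscore(X, mean, sd)
    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = fit_predict(spec, X[mask], y[mask], X[~mask])[0]
    return compute_metrics(confusion(y, preds))
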