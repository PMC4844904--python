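"""Per-vocal-test separation and z-score normalisation.

Each vocal test's 40 recordings form one modelling unit; the table is
split into one ``VocalTestSubset`` per test, all sharing the same subject
order.  Each subset is z-scored column-wise before feature selection and
classification.

Note on protocol: the default pipeline normalises (and selects features)
once on the full subset before cross-validation, matching the historical
protocol this framework reproduces.  Leakage-free per-fold refitting is
available via the ``fold_safe`` flag of the validation layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dataset_io import RecordingTable, feature_columns

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VocalTestSubset:
    """One vocal test's recordings: a subjects x features matrix with labels.

    Subject order is fixed and shared across all subsets produced from one
    table, so fold ``i`` always holds out the same subject everywhere.
    """

    test_id: int
    matrix: np.ndarray  # (n_subjects, n_features)
    labels: np.ndarray  # (n_subjects,), values in {0, 1}
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.labels) or len(self.labels) != len(self.subject_ids):
            raise ValueError("matrix rows, labels and subject_ids must align")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def separate_by_test(table: RecordingTable) -> list[VocalTestSubset]:
    """Split a recording table into one subset per vocal test.

    Returns ``table.n_tests`` subsets in test order, each with one row per
    subject; rows are ordered by the subject's first appearance in the
    table, identically across subsets.
    """
    order = table.subjects
    fcols = feature_columns(table.n_features)
    labels = table.subject_labels().to_numpy()
    subsets = []
    for test_id, grp in table.data.groupby("test_id", sort=True):
        grp = grp.set_index("subject_id").loc[order]
        subsets.append(
            VocalTestSubset(
                test_id=int(test_id),
                matrix=grp[fcols].to_numpy(dtype=float),
                labels=labels.copy(),
                subject_ids=tuple(order),
            )
        )
    return subsets


def zscore_params(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and sample (n-1) standard deviations for z-scoring."""
    if matrix.shape[0] < 2:
        raise ValueError("z-scoring requires at least 2 rows")
    return matrix.mean(axis=0), matrix.std(axis=0, ddof=1)


def apply_zscore(matrix: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Apply a fitted z-score transform; constant columns (sd 0) map to zeros."""
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (matrix - mean) / sd_safe
    out[:, sd == 0] = 0.0
    return out


def zscore_normalize(subset: VocalTestSubset) -> VocalTestSubset:
    """Z-score each feature column to sample mean 0, sample SD 1.

    Constant columns cannot be scaled; they are mapped to all-zeros and a
    warning is logged (real voicing counts can be constant in small
    samples).
    """
    mean, sd = zscore_params(subset.matrix)
    if (sd == 0).any():
        const = [j + 1 for j in np.flatnonzero(sd == 0)]
        log.warning("test %d: constant feature column(s) %s mapped to zeros", subset.test_id, const)
    return replace(subset, matrix=apply_zscore(subset.matrix, mean, sd))
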