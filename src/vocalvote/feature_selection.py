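"""Correlation-filter feature selection and the MCFS / A-MCFS policies.

For each vocal test, every feature is correlated with the binary class
label (Pearson's r, which for a binary y is the point-biserial
correlation); the r is converted to a two-sided p-value through the
Student-t transform t = r * sqrt((n-2) / (1 - r^2)) on n-2 degrees of
freedom, and features with p < alpha (default 0.05) are selected.  A test
for which no feature survives is *unsuccessful*.  Two policies resolve
unsuccessful tests:

MCFS
    every test still votes; unsuccessful tests fall back to the
    ``fallback_k`` features most frequently selected across all tests
    (ties broken by lower feature index).

A-MCFS
    unsuccessful tests are simply omitted from the ensemble.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import VocalTestSubset

log = logging.getLogger(__name__)


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant input vector."""


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation between two equal-length vectors.

    Raises :class:`ConstantVectorError` when either vector is constant
    (degenerate correlation; callers treat such features as unselected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ConstantVectorError("constant input vector")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def r_to_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a correlation via the Student-t transform.

    Uses t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom; returns
    0 for |r| = 1.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class FeatureCorrelation:
    """One feature's correlation with the label on one vocal test."""

    feature_index: int  # 1-based
    r: float
    p_value: float
    selected: bool


@dataclass(frozen=True)
class FeatureSelectionResult:
    """Selection outcome for one vocal test."""

    test_id: int
    selected_features: tuple[int, ...]  # 1-based, ascending
    correlations: tuple[FeatureCorrelation, ...] = ()

    @property
    def successful(self) -> bool:
        return len(self.selected_features) > 0


def select_features(subset: VocalTestSubset, alpha: float = 0.05) -> FeatureSelectionResult:
    """Select the features of one subset whose label-correlation p < alpha.

    Selection is scale-invariant (correlation is unchanged by positive
    affine transforms), so it may run on raw or z-scored matrices.
    Constant features are never selected.
    """
    n = subset.n_subjects
    cors = []
    selected = []
    for j in range(subset.n_features):
        try:
            r = pearson_r(subset.matrix[:, j], subset.labels)
        except ConstantVectorError:
            cors.append(FeatureCorrelation(j + 1, np.nan, np.nan, False))
            continue
        p = r_to_pvalue(r, n)
        sel = p < alpha
        cors.append(FeatureCorrelation(j + 1, r, p, sel))
        if sel:
            selected.append(j + 1)
    return FeatureSelectionResult(subset.test_id, tuple(selected), tuple(cors))


def feature_frequencies(results: list[FeatureSelectionResult]) -> dict[int, int]:
    """How many tests selected each feature (features never selected get 0)."""
    counts: Counter[int] = Counter()
    for res in results:
        counts.update(res.selected_features)
    n_features = max(
        (c.feature_index for r in results for c in r.correlations),
        default=max(counts, default=0),
    )
    return {j: counts.get(j, 0) for j in range(1, n_features + 1)}


@dataclass(frozen=True)
class SelectionPlan:
    """Which features each vocal test uses for classification.

    Under A-MCFS only successful tests appear in ``per_test_features``;
    under MCFS every test appears and unsuccessful tests map to
    ``fallback_features``.
    """

    mode: str  # "mcfs" | "a-mcfs"
    per_test_features: dict[int, tuple[int, ...]]
    fallback_features: tuple[int, ...] = ()
    alpha: float = 0.05
    fallback_k: int = 4


def _normalize_mode(mode: str) -> str:
    m = mode.lower().replace("_", "-")
    if m not in ("mcfs", "a-mcfs"):
        raise ValueError(f"mode must be 'mcfs' or 'a-mcfs', got {mode!r}")
    return m


def build_selection_plan(
    results: list[FeatureSelectionResult],
    mode: str = "a-mcfs",
    fallback_k: int = 4,
    alpha: float = 0.05,
) -> SelectionPlan:
    """Resolve per-test selections into a classification plan.

    MCFS maps each unsuccessful test to the ``fallback_k`` most frequently
    selected features (ties broken by lower index; fewer than k if fewer
    features were ever selected); A-MCFS drops unsuccessful tests.
    """
    mode = _normalize_mode(mode)
    plan: dict[int, tuple[int, ...]] = {}
    if mode == "a-mcfs":
        for res in results:
            if res.successful:
                plan[res.test_id] = res.selected_features
        return SelectionPlan(mode, plan, (), alpha, fallback_k)

    freqs = feature_frequencies(results)
    ranked = sorted((j for j, c in freqs.items() if c > 0), key=lambda j: (-freqs[j], j))
    if not ranked:
        raise ValueError("MCFS fallback undefined: no feature selected on any test")
    fallback = tuple(sorted(ranked[:fallback_k]))
    log.info("MCFS fallback features: %s", fallback)
    for res in results:
        plan[res.test_id] = res.selected_features if res.successful else fallback
    return SelectionPlan(mode, plan, fallback, alpha, fallback_k)


def selection_report(results: list[FeatureSelectionResult]) -> pd.DataFrame:
    """Long-format selection table: test_id, feature_index, r, p_value, selected."""
    rows = [
        (r.test_id, c.feature_index, c.r, c.p_value, c.selected)
        for r in results
        for c in r.correlations
    ]
    return pd.DataFrame(rows, columns=["test_id", "feature_index", "r", "p_value", "selected"])
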