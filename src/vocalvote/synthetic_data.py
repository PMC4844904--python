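"""Synthetic recording tables with the structure the framework assumes.

The generator emulates a balanced case/control voice study: ``n_subjects``
subjects (half PD, half control) each contribute one recording per vocal
test, and every recording carries ``n_features`` acoustic features.  A
chosen subset of *informative* tests carries a class signal — on those
tests, a chosen subset of features has its PD-class mean shifted by
``effect`` noise standard deviations — while every other test is pure
noise, identically distributed in both classes.  Features within a test
are drawn from a multivariate Gaussian with exchangeable correlation
``feature_corr``, mimicking the strong inter-correlation of real jitter /
shimmer feature families.

Defaults are the study conditions of the dataset this package targets:
40 subjects (20/20), 26 tests x 26 features, signal confined to tests
{4, 6, 7} with a 1.5-SD shift on features {1, 2, 3, 4}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import RecordingTable, feature_columns


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``effect`` is the class-mean shift, in units of ``noise_sd``, applied
    to ``informative_features`` of ``informative_tests`` in the PD class.
    ``feature_corr`` is the common pairwise correlation of features within
    one test (0 = independent).  The same ``seed`` always yields a
    bit-identical table.
    """

    n_subjects: int = 40
    n_tests: int = 26
    n_features: int = 26
    informative_tests: frozenset[int] = frozenset({4, 6, 7})
    informative_features: frozenset[int] = frozenset({1, 2, 3, 4})
    effect: float = 1.5
    noise_sd: float = 1.0
    feature_corr: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects % 2 != 0 or self.n_subjects < 4:
            raise ValueError("n_subjects must be even and >= 4 (balanced classes)")
        if not set(self.informative_tests) <= set(range(1, self.n_tests + 1)):
            raise ValueError("informative_tests must lie in 1..n_tests")
        if self.informative_tests and not (
            set(self.informative_features) <= set(range(1, self.n_features + 1))
        ):
            raise ValueError("informative_features must lie in 1..n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.feature_corr < 1:
            raise ValueError("feature_corr must be in [0, 1)")


def generate(spec: SyntheticSpec) -> RecordingTable:
    """Draw one recording table from ``spec``'s generative model."""
    rng = np.random.default_rng(spec.seed)
    n, t, p = spec.n_subjects, spec.n_tests, spec.n_features
    half = n // 2

    # exchangeable correlation via one shared factor per (subject, test)
    rho = spec.feature_corr
    labels = np.array([1] * half + [0] * half)
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    inf_feat = np.array(sorted(spec.informative_features), dtype=int) - 1
    rows = []
    for test_id in range(1, t + 1):
        shared = rng.standard_normal((n, 1))
        unique = rng.standard_normal((n, p))
        x = np.sqrt(rho) * shared + np.sqrt(1 - rho) * unique
        x *= spec.noise_sd
        if test_id in spec.informative_tests and inf_feat.size:
            x[np.ix_(labels == 1, inf_feat)] += spec.effect * spec.noise_sd
        df = pd.DataFrame(x, columns=feature_columns(p))
        df.insert(0, "test_id", test_id)
        df.insert(0, "subject_id", subject_ids)
        df["label"] = labels
        rows.append(df)

    data = pd.concat(rows, ignore_index=True)
    data = data.sort_values(["subject_id", "test_id"], kind="stable").reset_index(drop=True)
    return RecordingTable(data, n_tests=t, n_features=p)
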