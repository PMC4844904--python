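"""Recording-level data model and CSV I/O.

The universal input is a *recording table*: one row per (subject, vocal
test) carrying a fixed-length acoustic feature vector and a binary class
label (1 = Parkinson's disease, 0 = control).  Two on-disk dialects are
supported:

``tidy``
    Headered CSV ``subject_id,test_id,f1,...,fN,label``; the dialect this
    package writes.

``uci_train``
    The headerless dialect of the UCI "Parkinson Speech Dataset with
    Multiple Types of Sound Recordings" train file: subject id first, 26
    features, an optional UPDRS score, class label last, with the 26
    recordings of a subject on consecutive rows.  Vocal-test identity is
    not recorded in the file; ``test_id`` 1..26 is assigned by row order
    within each subject block (first row = sustained vowel "a").  The
    UPDRS column, when present (29 columns instead of 28), is detected by
    column count and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """Malformed file content (row width, non-numeric field, bad label)."""


class TableStructureError(ValueError):
    """A parsed table violates the recording-table invariants."""


def feature_columns(n_features: int) -> list[str]:
    return [f"f{j}" for j in range(1, n_features + 1)]


@dataclass
class RecordingTable:
    """Tidy recording-level table.

    ``data`` has columns ``subject_id`` (str), ``test_id`` (int, 1-based),
    ``f1..fN`` (float) and ``label`` (int in {0, 1}).  Every subject has
    exactly one row per test, all rows of a subject share one label, and
    both classes are represented.
    """

    data: pd.DataFrame
    n_tests: int = 26
    n_features: int = 26

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        expected = ["subject_id", "test_id", *feature_columns(self.n_features), "label"]
        if list(self.data.columns) != expected:
            raise TableStructureError(
                f"expected columns {expected[:3]}...{expected[-2:]}, got {list(self.data.columns)[:4]}..."
            )
        if len(self.data) == 0:
            raise TableStructureError("table has no rows")
        labels = self.data["label"].to_numpy()
        if not np.isin(labels, (0, 1)).all():
            raise TableFormatError("labels must be 0 (control) or 1 (PD)")
        tests = self.data["test_id"].to_numpy()
        if tests.min() < 1 or tests.max() > self.n_tests:
            raise TableStructureError(f"test_id outside 1..{self.n_tests}")
        per_subject = self.data.groupby("subject_id", sort=False)
        for sid, grp in per_subject:
            if sorted(grp["test_id"]) != list(range(1, self.n_tests + 1)):
                raise TableStructureError(
                    f"subject {sid!r} does not have exactly one row per test 1..{self.n_tests}"
                )
            if grp["label"].nunique() != 1:
                raise TableStructureError(f"subject {sid!r} carries conflicting labels")
        subj_labels = per_subject["label"].first()
        if not ((subj_labels == 1).any() and (subj_labels == 0).any()):
            raise TableStructureError("both classes must be present")
        feats = self.data[feature_columns(self.n_features)]
        if feats.isna().any().any():
            raise TableFormatError("missing feature values are not supported")

    # -- accessors --------------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        """Subject ids ordered by first appearance in the table."""
        return list(dict.fromkeys(self.data["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_labels(self) -> pd.Series:
        """Label per subject, indexed by subject id in table order."""
        order = self.subjects
        lab = self.data.groupby("subject_id", sort=False)["label"].first()
        return lab.loc[order]


def _tidy_from_frame(df: pd.DataFrame, n_features: int) -> RecordingTable:
    n_tests = int(df["test_id"].max())
    return RecordingTable(df.reset_index(drop=True), n_tests=n_tests, n_features=n_features)


def read_table(path, dialect: str = "tidy", label_map: dict | None = None) -> RecordingTable:
    """Read a recording table.

    Parameters
    ----------
    path : path-like
        CSV file to read.
    dialect : {"tidy", "uci_train"}
    label_map : dict, optional
        Explicit remapping applied to the raw label column (e.g.
        ``{2: 0}`` for datasets coding controls as 2).  Labels are never
        remapped silently.
    """
    if dialect == "tidy":
        df = pd.read_csv(path)
        if "subject_id" not in df.columns or "label" not in df.columns:
            raise TableFormatError("tidy dialect requires a subject_id,test_id,f...,label header")
        n_features = len(df.columns) - 3
        expected = ["subject_id", "test_id", *feature_columns(n_features), "label"]
        if list(df.columns) != expected:
            raise TableFormatError(f"unexpected tidy header: {list(df.columns)}")
        df["subject_id"] = df["subject_id"].astype(str)
        df["test_id"] = df["test_id"].astype(int)
        if label_map:
            df["label"] = df["label"].replace(label_map)
        df["label"] = df["label"].astype(int)
        df[feature_columns(n_features)] = df[feature_columns(n_features)].astype(float)
        return _tidy_from_frame(df, n_features)

    if dialect == "uci_train":
        raw = pd.read_csv(path, header=None, dtype=str)
        widths = raw.notna().sum(axis=1)
        if widths.nunique() != 1:
            bad = int(widths[widths != widths.mode()[0]].index[0]) + 1
            raise TableFormatError(f"inconsistent row width at line {bad}")
        width = int(widths.iloc[0])
        if width not in (28, 29):
            raise TableFormatError(
                f"uci_train rows must have 28 columns (or 29 with UPDRS); got {width}"
            )
        n_features = 26
        has_updrs = width == 29
        try:
            feats = raw.iloc[:, 1 : 1 + n_features].astype(float)
        except ValueError as exc:
            raise TableFormatError(f"non-numeric feature value: {exc}") from exc
        labels = raw.iloc[:, -1].astype(float)
        if label_map:
            labels = labels.replace(label_map)
        if not labels.isin((0, 1)).all():
            raise TableFormatError("labels must be 0 or 1 (pass label_map to remap)")
        subj = raw.iloc[:, 0].astype(str)
        # test_id by row order within each subject block
        test_id = subj.groupby(subj, sort=False).cumcount() + 1
        df = pd.DataFrame({"subject_id": subj, "test_id": test_id})
        feats.columns = feature_columns(n_features)
        df = pd.concat([df, feats], axis=1)
        df["label"] = labels.astype(int)
        _ = has_updrs  # penultimate UPDRS column intentionally dropped
        return _tidy_from_frame(df, n_features)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_table(table: RecordingTable, path, dialect: str = "tidy") -> None:
    """Write a recording table; ``read_table(write_table(t))`` is the identity."""
    if dialect != "tidy":
        raise ValueError(f"unsupported write dialect {dialect!r}")
    table.validate()
    # repr-roundtrip precision so re-reading reproduces every float bit
    table.data.to_csv(path, index=False, float_format="%.17g")
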