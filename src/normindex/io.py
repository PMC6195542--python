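"""Readers and writers for the package's delimited-text formats.

Formats
-------
wide CSV
    header ``subject_id,<feature 1>,...,<feature p>``; one row per subject.
    Used for both reference cohorts and subject files; a subject file must
    carry the reference's features in the reference's order.
long gait CSV
    columns ``subject_id,angle,cycle_pct,value`` with cycle_pct in
    {0, 2, ..., 100}; pivoted to the angle-major 459-column wide layout.
results CSV
    ``subject_id,measure,basis,k_retained,value[,scaled_value]``.

All writers use a fixed 12-significant-digit float format and deterministic
column order so outputs are diffable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ReferenceMatrix, SubjectVector
from .distances import AbnormalityResult
from .gait import ANGLE_NAMES, CYCLE_PCT

__all__ = [
    "read_reference_csv",
    "read_subjects_csv",
    "write_reference_csv",
    "write_subjects_csv",
    "read_long_gait_table",
    "write_long_gait_table",
    "write_results_csv",
]

FLOAT_FORMAT = "%.12g"


def _read_wide(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a subject-id column plus at least one feature")
    id_col = df.columns[0]
    if df[id_col].isna().any():
        raise ValueError(f"{path}: missing subject id(s)")
    dup = df[id_col][df[id_col].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate subject id(s): {', '.join(map(str, dup[:5]))}")
    features = df.columns[1:]
    block = df[features].apply(pd.to_numeric, errors="coerce")
    if block.isna().any().any():
        rows, cols = np.where(block.isna().to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise ValueError(
            f"{path}: empty or non-numeric cell at row {r + 2} "
            f"(subject {df[id_col].iloc[r]!r}), column {features[c]!r}"
        )
    df[features] = block
    return df


def read_reference_csv(path: Union[str, Path]) -> ReferenceMatrix:
    """Load a wide CSV as a reference matrix, preserving file feature order."""
    df = _read_wide(path)
    return ReferenceMatrix(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        subject_ids=tuple(df.iloc[:, 0]),
        feature_labels=tuple(df.columns[1:]),
    )


def read_subjects_csv(
    path: Union[str, Path],
    expected_labels: Optional[Sequence[str]] = None,
) -> list[SubjectVector]:
    """Load a wide CSV of subjects; optionally enforce the reference's feature order."""
    df = _read_wide(path)
    labels = tuple(df.columns[1:])
    if expected_labels is not None:
        expected = tuple(expected_labels)
        if labels != expected:
            if set(labels) == set(expected):
                raise ValueError(f"{path}: feature order mismatch with reference")
            raise ValueError(f"{path}: feature labels do not match reference")
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    ids = df.iloc[:, 0].tolist()
    return [
        SubjectVector(values=values[i], feature_labels=labels, subject_id=str(ids[i]))
        for i in range(len(ids))
    ]


def _write_wide(path, values, subject_ids, labels) -> None:
    df = pd.DataFrame(values, columns=list(labels))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_reference_csv(ref: ReferenceMatrix, path: Union[str, Path]) -> None:
    _write_wide(path, ref.values, ref.subject_ids, ref.feature_labels)


def write_subjects_csv(subjects: Sequence[SubjectVector], path: Union[str, Path]) -> None:
    if not subjects:
        raise ValueError("no subjects to write")
    labels = subjects[0].feature_labels
    for s in subjects[1:]:
        if s.feature_labels != labels:
            raise ValueError("subjects have inconsistent feature labels")
    _write_wide(path, np.vstack([s.values for s in subjects]), [s.subject_id for s in subjects], labels)


def read_long_gait_table(path: Union[str, Path]) -> ReferenceMatrix:
    """Pivot a long gait table to the angle-major wide 459-column layout.

    Every subject must supply all 9 angles x 51 cycle points; missing cells
    are reported explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"subject_id": str, "angle": str})
    required = {"subject_id", "angle", "cycle_pct", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: long gait table needs columns {sorted(required)}")
    bad_angles = set(df["angle"]) - set(ANGLE_NAMES)
    if bad_angles:
        raise ValueError(f"{path}: unknown angle name(s): {sorted(bad_angles)}")
    bad_pct = set(df["cycle_pct"]) - set(CYCLE_PCT.tolist())
    if bad_pct:
        raise ValueError(f"{path}: cycle_pct values must be in 0,2,...,100; got {sorted(bad_pct)[:5]}")
    if df["value"].isna().any():
        raise ValueError(f"{path}: missing values in 'value' column")
    wide = df.pivot_table(
        index="subject_id", columns=["angle", "cycle_pct"], values="value", aggfunc="first"
    )
    full_cols = pd.MultiIndex.from_tuples(
        [(a, int(c)) for a in ANGLE_NAMES for c in CYCLE_PCT], names=["angle", "cycle_pct"]
    )
    missing = full_cols.difference(wide.columns)
    wide = wide.reindex(columns=full_cols)
    holes = wide.isna()
    if holes.any().any():
        cells = [
            f"{subj}:{a}@{c}%"
            for subj in wide.index
            for (a, c) in wide.columns[holes.loc[subj].to_numpy()]
        ]
        raise ValueError(f"{path}: missing gait cells: {', '.join(cells[:10])}"
                         + ("..." if len(cells) > 10 else ""))
    del missing
    labels = tuple(f"{a}_{c:03d}" for a, c in wide.columns)
    # keep the file's subject order (pivot_table sorts the index)
    order = list(dict.fromkeys(df["subject_id"]))
    wide = wide.loc[order]
    return ReferenceMatrix(
        values=wide.to_numpy(dtype=float),
        subject_ids=tuple(wide.index),
        feature_labels=labels,
    )


def write_long_gait_table(ref: ReferenceMatrix, path: Union[str, Path]) -> None:
    """Write a 459-feature matrix as a long (subject_id, angle, cycle_pct, value) table."""
    if ref.p != len(ANGLE_NAMES) * len(CYCLE_PCT):
        raise ValueError("long gait tables require the 9 x 51 = 459 feature layout")
    angles = np.repeat(ANGLE_NAMES, len(CYCLE_PCT))
    pcts = np.tile(CYCLE_PCT, len(ANGLE_NAMES))
    frames = [
        pd.DataFrame(
            {
                "subject_id": sid,
                "angle": angles,
                "cycle_pct": pcts,
                "value": ref.values[i],
            }
        )
        for i, sid in enumerate(ref.subject_ids)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_results_csv(results: Iterable[AbnormalityResult], path: Union[str, Path]) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "measure": r.measure,
            "basis": r.basis,
            "k_retained": r.k,
            "value": r.value,
            "scaled_value": r.scaled_value if r.scaled_value is not None else "",
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["subject_id", "measure", "basis", "k_retained", "value", "scaled_value"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )
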