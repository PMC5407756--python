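"""Reading and writing of recordings and feature tables.

Everything is plain delimited text so that released datasets, manual
fixtures and synthetic cohorts interchange freely.  Acceleration units are
deliberately not interpreted: every downstream feature is either
scale-covariant or compared across subjects recorded identically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, FormatError, ParseError, ValidationError

DEFAULT_RATE_HZ = 200.0

#: default header names for the three acceleration axes
DEFAULT_DIALECT = {"x": "x", "y": "y", "z": "z"}


class Group(str, enum.Enum):
    """Faller status of a subject ("have you fallen within the past year?")."""

    FALLER = "faller"
    NON_FALLER = "non_faller"
    UNKNOWN = "unknown"

    @classmethod
    def coerce(cls, value) -> "Group":
        if isinstance(value, Group):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(f"unknown group label {value!r}") from None


@dataclass
class TriaxialRecording:
    """Raw triaxial accelerometer samples for one subject.

    The three axis arrays must be equal length (>= 2 samples) and free of
    missing values; ``rate`` is the sampling rate in Hz.
    """

    subject_id: str
    group: Group
    rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.group = Group.coerce(self.group)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValidationError("axis arrays must have equal length")
        if len(self.x) < 2:
            raise DegenerateInputError("recording must contain at least 2 samples")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"axis {name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class CohortTable:
    """Per-subject feature values plus a faller / non-faller label.

    Wraps a DataFrame with columns ``subject_id``, ``group`` and one column
    per feature, in a fixed order.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        for col in ("subject_id", "group"):
            if col not in df.columns:
                raise FormatError(f"cohort table lacks required column '{col}'")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValidationError(f"duplicated subject_id(s): {dupes}")
        bad = set(df["group"]) - {g.value for g in Group}
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")
        # canonical column order: id, group, then features as given
        feats = [c for c in df.columns if c not in ("subject_id", "group")]
        self.data = df[["subject_id", "group"] + feats].reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("subject_id", "group")]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (faller, non-faller) value arrays for one feature."""
        df = self.data
        pos = df.loc[df["group"] == Group.FALLER.value, feature].to_numpy(float)
        neg = df.loc[df["group"] == Group.NON_FALLER.value, feature].to_numpy(float)
        return pos, neg


def read_recording(
    path,
    rate: float = DEFAULT_RATE_HZ,
    dialect: dict | None = None,
    subject_id: str | None = None,
    group: Group | str = Group.UNKNOWN,
    sep: str = ",",
) -> TriaxialRecording:
    """Read one subject's raw recording from a delimited text file.

    ``dialect`` maps axis names to file column headers, e.g.
    ``{"x": "ax", "y": "ay", "z": "az"}``; unmapped axes default to their
    own name.  A time or sample-index column, if present, is ignored: the
    sampling rate is supplied explicitly (timestamp columns are often
    jittery and the acquisition rate is known).
    """
    colmap = dict(DEFAULT_DIALECT)
    colmap.update(dialect or {})
    try:
        df = pd.read_csv(path, sep=sep, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    axes = {}
    for axis in ("x", "y", "z"):
        col = colmap[axis]
        if col not in df.columns:
            raise FormatError(f"{path}: missing column '{col}' for axis {axis}")
        raw = df[col]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna()
        if bad.any():
            idx = int(bad.idxmax())
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"{path}: non-numeric value {raw.iloc[idx]!r} in column "
                f"'{col}' at line {idx + 2}",
                line=idx + 2,
            )
        axes[axis] = vals.to_numpy(float)
    if len(df) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 samples")
    return TriaxialRecording(
        subject_id=subject_id if subject_id is not None else str(path),
        group=Group.coerce(group),
        rate=rate,
        **axes,
    )


def write_feature_table(table: CohortTable, path) -> None:
    """Write a cohort table as CSV (``subject_id,group,<feature...>``).

    Floats are rendered at full shortest-round-trip precision so that
    ``read_feature_table`` reproduces the table bit-exactly.
    """
    if table.n_subjects == 0:
        raise ValidationError("refusing to write an empty cohort table")
    table.data.to_csv(path, index=False)


def read_feature_table(path) -> CohortTable:
    """Read a cohort feature table written by :func:`write_feature_table`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty feature table") from None
    if "group" not in df.columns:
        raise FormatError(f"{path}: feature table lacks a 'group' column")
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: feature table lacks a 'subject_id' column")
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(df)
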