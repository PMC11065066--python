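"""Life-calendar state sequences: data model, I/O, alignment, completeness filtering.

A life calendar records one categorical employment state per subject-year.
Sequences are aligned to a common age span (default ages 16 up to, but not
including, 65 — 49 states per subject) before any dissimilarity computation.
Years without information are stored as the missing marker ``MISSING_STATE``;
subjects with any missing year inside the span are dropped by
:func:`filter_complete`, mirroring the complete-history inclusion rule used
in retrospective cohort analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for an unobserved subject-year. State codes start at 1, so 0 is free.
MISSING_STATE = 0

#: Default span: half-open [16, 65) -> 49 ages.
DEFAULT_START_AGE = 16
DEFAULT_END_AGE = 65


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered coding of the categorical states, codes contiguous from 1."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.entries]
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError(
                f"alphabet codes must be unique and contiguous from 1, got {codes}"
            )

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _ in self.entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, lab in self.entries)

    def label_of(self, code: int) -> str:
        return self.entries[code - 1][1]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: object) -> bool:
        return isinstance(code, (int, np.integer)) and 1 <= int(code) <= len(self.entries)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, str]) -> "StateAlphabet":
        return cls(tuple(sorted(((int(c), str(lab)) for c, lab in mapping.items()))))


#: The 8-category employment-state coding used throughout: full-time and
#: part-time employment, self-employment, unemployment, home/family work,
#: retirement, full-time education, and a residual "other" bundling illness or
#: disability, voluntary work, military service and travelling.
DEFAULT_ALPHABET = StateAlphabet(
    (
        (1, "Employed full-time"),
        (2, "Employed part-time"),
        (3, "Self-employed"),
        (4, "Unemployed"),
        (5, "Home/family"),
        (6, "Retired"),
        (7, "Full-time education"),
        (8, "Other"),
    )
)


@dataclass
class StateSequence:
    """One subject's aligned categorical trajectory.

    ``states[i]`` is the state held at age ``start_age + i``; ``MISSING_STATE``
    marks unobserved years.
    """

    subject_id: str
    gender: str
    birth_year: int
    states: np.ndarray
    start_age: int = DEFAULT_START_AGE

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D vector")

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def is_complete(self) -> bool:
        return bool(np.all(self.states != MISSING_STATE))

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start_age, self.start_age + len(self))


@dataclass
class SequencePanel:
    """A set of sequences sharing one alphabet and one age span."""

    alphabet: StateAlphabet
    sequences: list[StateSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.subject_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids in panel: {dup}")
        if self.sequences:
            s0 = self.sequences[0]
            for s in self.sequences:
                if s.start_age != s0.start_age or len(s) != len(s0):
                    raise ValueError(
                        f"panel is not aligned: subject {s.subject_id!r} spans "
                        f"({s.start_age}, {len(s)}) vs ({s0.start_age}, {len(s0)})"
                    )
        for s in self.sequences:
            bad = set(np.unique(s.states)) - {MISSING_STATE} - set(self.alphabet.codes)
            if bad:
                raise ValueError(
                    f"subject {s.subject_id!r} has state codes outside the "
                    f"alphabet: {sorted(int(b) for b in bad)}"
                )

    @property
    def span(self) -> tuple[int, int]:
        """(start_age, length); (DEFAULT_START_AGE, 0) when empty."""
        if not self.sequences:
            return (DEFAULT_START_AGE, 0)
        return (self.sequences[0].start_age, len(self.sequences[0]))

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.sequences]

    def state_matrix(self) -> np.ndarray:
        """n x L integer matrix of states (row order = panel order)."""
        start, length = self.span
        if not self.sequences:
            return np.empty((0, length), dtype=np.int64)
        return np.vstack([s.states for s in self.sequences])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


# ---------------------------------------------------------------------------
# I/O — long and wide CSV dialects
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["subject_id", "gender", "birth_year", "age", "state"]


def _as_frame(table: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(table, (str, Path)):
        return pd.read_csv(table)
    return table.copy()


def read_long(
    table: pd.DataFrame | str | Path,
    alphabet: StateAlphabet = DEFAULT_ALPHABET,
    span: tuple[int, int] | None = None,
) -> SequencePanel:
    """Build a panel from long format (one row per subject-year).

    Parameters
    ----------
    table
        DataFrame or CSV path with columns subject_id, gender, birth_year,
        age, state. Rows with a missing state are treated as unobserved years.
    span
        (start_age, end_age) half-open; inferred from the observed ages when
        omitted. Years of the span absent from the table become missing.
    """
    df = _as_frame(table)
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long table missing columns: {missing_cols}")
    if df.empty:
        return SequencePanel(alphabet, [])

    df = df.copy()
    df["age"] = df["age"].astype(int)
    dup = df.duplicated(subset=["subject_id", "age"], keep=False)
    if dup.any():
        subj = sorted(df.loc[dup, "subject_id"].unique().tolist())
        raise ValueError(f"duplicate (subject_id, age) rows for subjects: {subj}")

    observed = df["state"].notna()
    bad = df.loc[observed & ~df.loc[observed, "state"].astype(int).isin(alphabet.codes)]
    if len(bad):
        raise ValueError(
            f"unknown state codes {sorted(bad['state'].astype(int).unique().tolist())}"
        )

    if span is None:
        start_age = int(df["age"].min())
        end_age = int(df["age"].max()) + 1
    else:
        start_age, end_age = span
    length = end_age - start_age
    if length <= 0:
        raise ValueError(f"empty span ({start_age}, {end_age})")

    sequences = []
    for sid, grp in df.groupby("subject_id", sort=False):
        states = np.full(length, MISSING_STATE, dtype=np.int64)
        inside = (grp["age"] >= start_age) & (grp["age"] < end_age) & grp["state"].notna()
        grp_in = grp.loc[inside]
        states[grp_in["age"].to_numpy() - start_age] = grp_in["state"].astype(int).to_numpy()
        sequences.append(
            StateSequence(
                subject_id=str(sid),
                gender=str(grp["gender"].iloc[0]),
                birth_year=int(grp["birth_year"].iloc[0]),
                states=states,
                start_age=start_age,
            )
        )
    return SequencePanel(alphabet, sequences)


def write_long(panel: SequencePanel, path: str | Path | None = None) -> pd.DataFrame:
    """Long-format frame (observed years only); optionally written as CSV."""
    rows = []
    for s in panel:
        for age, state in zip(s.ages, s.states):
            if state != MISSING_STATE:
                rows.append((s.subject_id, s.gender, s.birth_year, int(age), int(state)))
    df = pd.DataFrame(rows, columns=LONG_COLUMNS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def _age_columns(df: pd.DataFrame) -> list[int]:
    ages = []
    for col in df.columns:
        if col.startswith("age_"):
            ages.append(int(col.split("_", 1)[1]))
    return sorted(ages)


def read_wide(
    table: pd.DataFrame | str | Path,
    alphabet: StateAlphabet = DEFAULT_ALPHABET,
    span: tuple[int, int] | None = None,
) -> SequencePanel:
    """Build a panel from wide format (one row per subject, columns age_16...).

    Empty cells are unobserved years. With an explicit ``span``, any age
    column outside it is an error; without one the span is the contiguous
    range covering the age columns present.
    """
    df = _as_frame(table)
    for c in ("subject_id", "gender", "birth_year"):
        if c not in df.columns:
            raise ValueError(f"wide table missing column {c!r}")
    ages = _age_columns(df)
    if not ages and df.empty:
        return SequencePanel(alphabet, [])
    if not ages:
        raise ValueError("wide table has no age_* columns")

    if span is None:
        start_age, end_age = ages[0], ages[-1] + 1
    else:
        start_age, end_age = span
        outside = [a for a in ages if not (start_age <= a < end_age)]
        if outside:
            raise ValueError(
                f"age columns outside span [{start_age}, {end_age}): {outside}"
            )
    if df.duplicated(subset=["subject_id"]).any():
        raise ValueError("duplicate subject_id rows in wide table")

    length = end_age - start_age
    sequences = []
    for _, row in df.iterrows():
        states = np.full(length, MISSING_STATE, dtype=np.int64)
        for a in ages:
            v = row[f"age_{a}"]
            if pd.notna(v):
                code = int(v)
                if code not in alphabet:
                    raise ValueError(
                        f"unknown state code {code} for subject {row['subject_id']!r}"
                    )
                states[a - start_age] = code
        sequences.append(
            StateSequence(
                subject_id=str(row["subject_id"]),
                gender=str(row["gender"]),
                birth_year=int(row["birth_year"]),
                states=states,
                start_age=start_age,
            )
        )
    return SequencePanel(alphabet, sequences)


def write_wide(panel: SequencePanel, path: str | Path | None = None) -> pd.DataFrame:
    """Wide-format frame; missing years become empty cells."""
    start, length = panel.span
    cols = [f"age_{start + i}" for i in range(length)]
    records = []
    for s in panel:
        rec: dict[str, object] = {
            "subject_id": s.subject_id,
            "gender": s.gender,
            "birth_year": s.birth_year,
        }
        for i, c in enumerate(cols):
            rec[c] = int(s.states[i]) if s.states[i] != MISSING_STATE else pd.NA
        records.append(rec)
    df = pd.DataFrame(records, columns=["subject_id", "gender", "birth_year", *cols])
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# Alignment and completeness filtering
# ---------------------------------------------------------------------------


def align(
    panel: SequencePanel,
    start_age: int = DEFAULT_START_AGE,
    end_age: int = DEFAULT_END_AGE,
) -> SequencePanel:
    """Restrict every sequence to ages in the half-open [start_age, end_age).

    The default yields 49 states per subject. Ages outside the span are
    discarded; span years a subject was not observed for become missing.
    Idempotent for a fixed span.
    """
    if start_age >= end_age:
        raise ValueError(f"start_age {start_age} must be < end_age {end_age}")
    length = end_age - start_age
    out = []
    for s in panel:
        states = np.full(length, MISSING_STATE, dtype=np.int64)
        # overlap of [s.start_age, s.start_age + len) with [start_age, end_age)
        lo = max(start_age, s.start_age)
        hi = min(end_age, s.start_age + len(s))
        if lo < hi:
            states[lo - start_age : hi - start_age] = s.states[
                lo - s.start_age : hi - s.start_age
            ]
        out.append(
            StateSequence(s.subject_id, s.gender, s.birth_year, states, start_age)
        )
    return SequencePanel(panel.alphabet, out)


def filter_complete(panel: SequencePanel) -> tuple[SequencePanel, dict]:
    """Keep only sequences with no missing year inside the span.

    Returns the filtered panel plus an exclusion report. Retained sequences
    are passed through untouched (no imputation).
    """
    kept = [s for s in panel if s.is_complete]
    report = {
        "n_input": len(panel),
        "n_retained": len(kept),
        "n_excluded_incomplete": len(panel) - len(kept),
        "excluded_subject_ids": [s.subject_id for s in panel if not s.is_complete],
    }
    return SequencePanel(panel.alphabet, kept), report
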