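"""Pairwise Hamming dissimilarity between aligned categorical sequences.

The Hamming distance counts the ages at which two equal-length sequences hold
different states. Because no shifting or insertions are allowed it is
sensitive to *timing*: the same spell of unemployment at age 25 versus age 55
contributes the same number of mismatches but against different comparison
states, so trajectories that differ in when transitions happen are kept
apart. This is the deliberate choice here over edit-distance families
(optimal matching), which trade timing sensitivity for sequencing
flexibility and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .life_calendar import SequencePanel


@dataclass
class DissimilarityMatrix:
    """Dense symmetric matrix of pairwise mismatch counts.

    ``values[i, j]`` is the number of positions at which sequences ``ids[i]``
    and ``ids[j]`` differ; ``length`` is the common sequence length L, so all
    entries lie in [0, L] (or [0, 1] after length normalization).
    """

    ids: list[str]
    values: np.ndarray
    length: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("entries must be non-negative")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, length: int, normalized: bool = False) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float), length, normalized)


def hamming_matrix(panel: SequencePanel) -> DissimilarityMatrix:
    """All-pairs positionwise mismatch counts for an aligned, complete panel.

    Raises if any sequence has a missing year: unobserved states cannot be
    compared and must be handled by ``filter_complete`` first.
    """
    incomplete = [s.subject_id for s in panel if not s.is_complete]
    if incomplete:
        raise ValueError(
            f"panel has incomplete sequences (missing years): {incomplete[:5]}"
        )
    start, length = panel.span
    if length == 0:
        raise ValueError("cannot compute distances on an empty span")
    x = panel.state_matrix()
    # scipy's hamming metric returns the mismatch *fraction*; scale back to counts
    d = squareform(pdist(x, metric="hamming")) * length
    return DissimilarityMatrix(panel.subject_ids, np.round(d, 10), length)


def normalize(D: DissimilarityMatrix, by: str = "length") -> DissimilarityMatrix:
    """Rescale distances; ``by='length'`` maps counts into [0, 1], ``by='none'`` is identity."""
    if by == "none":
        return DissimilarityMatrix(list(D.ids), D.values.copy(), D.length, D.normalized)
    if by == "length":
        if D.length <= 0:
            raise ValueError("length must be positive to normalize")
        if D.normalized:
            return DissimilarityMatrix(list(D.ids), D.values.copy(), D.length, True)
        return DissimilarityMatrix(list(D.ids), D.values / D.length, D.length, True)
    raise ValueError(f"unknown normalization {by!r}; use 'none' or 'length'")
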