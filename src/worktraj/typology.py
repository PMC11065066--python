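"""Descriptive typology outputs: chronograms and cluster composition tables.

A chronogram is the per-cluster distribution of states at each age — the
numeric content behind the stacked-area trajectory plots used to name
employment types. Cluster naming itself is a qualitative judgement and stays
user-supplied; the modal state path per cluster is provided to assist it.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .life_calendar import SequencePanel


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding (2.25 -> 2.3 at 1 decimal), as in printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class Chronogram:
    """Per-cluster state-by-age proportion matrices.

    ``tables[c]`` is a DataFrame with one row per alphabet state and one
    column per age; each age column sums to 1 over states for complete panels.
    """

    tables: dict[object, pd.DataFrame]

    def to_csv(self, outdir: str | Path, prefix: str = "chronogram") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for c, tab in self.tables.items():
            p = outdir / f"{prefix}_cluster_{c}.csv"
            tab.to_csv(p)
            paths.append(p)
        return paths


def chronogram(panel: SequencePanel, labels: Sequence[object]) -> Chronogram:
    """Fraction of each cluster's subjects in each state at each age."""
    labels = np.asarray(labels)
    if len(labels) != len(panel):
        raise ValueError(f"{len(labels)} labels for {len(panel)} sequences")
    if len(panel) == 0:
        raise ValueError("empty panel")
    x = panel.state_matrix()
    start, length = panel.span
    ages = np.arange(start, start + length)
    codes = panel.alphabet.codes
    tables: dict[object, pd.DataFrame] = {}
    for c in pd.unique(labels):
        members = x[labels == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c!r} is empty")
        props = np.stack(
            [(members == code).mean(axis=0) for code in codes]
        )
        tables[c] = pd.DataFrame(
            props, index=list(panel.alphabet.labels), columns=ages
        )
    return Chronogram(tables)


def modal_state_path(panel: SequencePanel, labels: Sequence[object], cluster: object) -> np.ndarray:
    """Most frequent state at each age within one cluster (ties to lowest code)."""
    labels = np.asarray(labels)
    members = panel.state_matrix()[labels == cluster]
    if members.shape[0] == 0:
        raise ValueError(f"cluster {cluster!r} is empty")
    codes = np.array(panel.alphabet.codes)
    counts = np.stack([(members == code).sum(axis=0) for code in codes])
    return codes[np.argmax(counts, axis=0)]


def summarize(
    panel: SequencePanel,
    labels: Sequence[object],
    label_names: Mapping[object, str] | None = None,
    medoid_ids: Mapping[object, str] | None = None,
) -> pd.DataFrame:
    """Cluster composition table: n, percentage, name, modal path, medoid.

    Percentages use the panel as denominator and are rounded half-up to one
    decimal, matching the usual "n (pct)" presentation of typology tables.
    Clusters missing from ``label_names`` fall back to their numeric label.
    """
    labels = np.asarray(labels)
    if len(labels) != len(panel):
        raise ValueError(f"{len(labels)} labels for {len(panel)} sequences")
    n_total = len(panel)
    label_names = dict(label_names or {})
    medoid_ids = dict(medoid_ids or {})
    rows = []
    for c in pd.unique(labels):
        n_c = int((labels == c).sum())
        path = modal_state_path(panel, labels, c)
        rows.append(
            {
                "cluster": c,
                "name": label_names.get(c, str(c)),
                "n": n_c,
                "percent": round_half_up(100.0 * n_c / n_total, 1),
                "modal_path": "-".join(str(int(s)) for s in path),
                "medoid_id": medoid_ids.get(c, ""),
            }
        )
    df = pd.DataFrame(rows).sort_values("n", ascending=False).reset_index(drop=True)
    return df
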