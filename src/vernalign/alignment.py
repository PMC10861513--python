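"""Between-variety transcriptome alignment by Euclidean distance.

Each time point of a variety/tissue is a vector of replicate-collapsed
FPKM values over genes.  The alignment is the matrix of Euclidean
distances between every pair of time points across the two varieties,
optionally restricted to a gene subset (e.g. flowering genes), together
with the minimum-distance traces: for each row day the nearest column day
and vice versa.  Missing days on one side simply shrink that axis; no
imputation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .expression import TimePointProfile


@dataclass
class DistanceMatrix:
    """Row-variety-day by column-variety-day Euclidean distances."""

    values: pd.DataFrame  # index = row days, columns = col days
    gene_subset_label: str = "all"

    @property
    def row_days(self) -> list[int]:
        return [int(d) for d in self.values.index]

    @property
    def col_days(self) -> list[int]:
        return [int(d) for d in self.values.columns]


@dataclass
class MinTrace:
    """Per-row and per-column nearest-day assignments.

    ``row_min`` maps each row day to the column day at minimum distance
    (ties broken towards the earliest day), ``col_min`` the converse.
    """

    row_min: dict[int, int]
    col_min: dict[int, int]


def _aligned_values(
    profile_row: TimePointProfile,
    profile_col: TimePointProfile,
    gene_subset: Sequence[str] | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if gene_subset is not None:
        genes = pd.Index(gene_subset)
        missing_r = [g for g in genes if g not in profile_row.values.index]
        missing_c = [g for g in genes if g not in profile_col.values.index]
        if missing_r or missing_c:
            raise ValueError(
                f"subset genes missing from profiles: row {missing_r[:10]}, "
                f"col {missing_c[:10]}"
            )
    else:
        genes = profile_row.values.index.intersection(profile_col.values.index)
        if len(genes) == 0:
            raise ValueError("profiles share no genes")
    return profile_row.values.loc[genes], profile_col.values.loc[genes]


def distance_matrix(
    profile_row: TimePointProfile,
    profile_col: TimePointProfile,
    gene_subset: Sequence[str] | None = None,
    label: str | None = None,
) -> DistanceMatrix:
    """Euclidean distances between all row-day/column-day pairs.

    Entry (i, j) is the distance between the gene-expression vectors of
    row day i and column day j, with genes in identical order on both
    sides (restricted to ``gene_subset`` when given).
    """
    vals_r, vals_c = _aligned_values(profile_row, profile_col, gene_subset)
    d = cdist(vals_r.T.to_numpy(), vals_c.T.to_numpy(), metric="euclidean")
    frame = pd.DataFrame(d, index=profile_row.days, columns=profile_col.days)
    if label is None:
        label = "all" if gene_subset is None else f"subset({len(vals_r)})"
    return DistanceMatrix(values=frame, gene_subset_label=label)


def min_traces(d: DistanceMatrix) -> MinTrace:
    """Nearest column day per row day and nearest row day per column day.

    Ties resolve towards the earliest day (lowest index, since day axes
    are ascending).
    """
    if d.values.size == 0:
        raise ValueError("distance matrix is empty")
    arr = d.values.to_numpy()
    row_days, col_days = d.row_days, d.col_days
    row_min = {row_days[i]: col_days[int(np.argmin(arr[i]))] for i in range(arr.shape[0])}
    col_min = {col_days[j]: row_days[int(np.argmin(arr[:, j]))] for j in range(arr.shape[1])}
    return MinTrace(row_min=row_min, col_min=col_min)


def trace_table(d: DistanceMatrix) -> pd.DataFrame:
    """Long-form minimum-trace table: direction, from_day, to_day, distance."""
    t = min_traces(d)
    rows = [
        {"direction": "row", "from_day": fd, "to_day": td,
         "distance": float(d.values.loc[fd, td])}
        for fd, td in t.row_min.items()
    ] + [
        {"direction": "col", "from_day": fd, "to_day": td,
         "distance": float(d.values.loc[td, fd])}
        for fd, td in t.col_min.items()
    ]
    return pd.DataFrame(rows)
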