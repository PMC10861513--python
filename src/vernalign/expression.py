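"""Expression tables, replicate collapsing, expression classification and filtering.

The analysis consumes gene-by-sample FPKM matrices produced upstream by an
alignment/quantification pipeline.  This module holds the two in-memory
containers everything else is built on — :class:`ExpressionSeries` (raw
samples plus metadata) and :class:`TimePointProfile` (replicate pools
averaged per sampling day) — together with the expressed-gene rule
(max FPKM across the series >= 2.0, inclusive), the three-stage prefilter
applied before self-organising-map clustering, and the variety-specific /
shared expressed-gene set computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Expression threshold (FPKM).  A gene is "expressed" when its maximal
#: value across the time series is greater than or equal to this.
EXPRESSION_THRESHOLD = 2.0

REQUIRED_META_COLUMNS = ("variety", "tissue", "day", "pool")


@dataclass
class ExpressionSeries:
    """Gene-by-sample FPKM matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID, one column per sample ID.  All
        entries must be non-negative.
    sample_meta
        DataFrame indexed by sample ID with columns ``variety``,
        ``tissue``, ``day`` (integer days post-sowing) and ``pool``
        (replicate-pool number).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs in expression table: {dupes[:10]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values in expression table")
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        unknown = [s for s in self.values.columns if s not in self.sample_meta.index]
        if unknown:
            raise ValueError(f"samples missing from metadata: {unknown}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_for(self, variety: str, tissue: str) -> pd.DataFrame:
        meta = self.sample_meta.loc[list(self.values.columns)]
        mask = (meta["variety"] == variety) & (meta["tissue"] == tissue)
        return meta[mask]


@dataclass
class TimePointProfile:
    """Replicate-collapsed gene-by-timepoint matrix for one variety/tissue."""

    values: pd.DataFrame  # genes x days, columns are integer days ascending
    variety: str
    tissue: str

    def __post_init__(self) -> None:
        days = list(self.values.columns)
        if len(days) < 2:
            raise ValueError("a time-point profile needs at least 2 days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"days must be strictly increasing, got {days}")

    @property
    def days(self) -> list[int]:
        return [int(d) for d in self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class GeneSetOverlap:
    """Partition of the union of two expressed-gene sets.

    ``percentages`` are (only_a, only_b, shared) over the union, in percent.
    """

    only_a: frozenset
    only_b: frozenset
    shared: frozenset
    percentages: tuple[float, float, float]

    def __post_init__(self) -> None:
        assert not (self.only_a & self.only_b)
        assert not (self.only_a & self.shared)
        assert not (self.only_b & self.shared)


def read_expression_table(path: str | Path, meta_path: str | Path) -> ExpressionSeries:
    """Read a gene-by-sample FPKM TSV and its sample-metadata TSV.

    Gene order is preserved from the file.  Every sample column must be
    present in the metadata (matched by sample ID); extra metadata rows
    are ignored.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionSeries(values=values, sample_meta=meta)


def collapse_replicates(series: ExpressionSeries, variety: str, tissue: str) -> TimePointProfile:
    """Average replicate pools per sampling day for one variety/tissue.

    Each day's column is the arithmetic mean over that day's pools; days
    are sorted ascending.  Raises if no samples match.
    """
    meta = series.samples_for(variety, tissue)
    if meta.empty:
        raise ValueError(f"no samples for variety={variety!r} tissue={tissue!r}")
    sub = series.values[meta.index]
    collapsed = sub.T.groupby(meta["day"].astype(int)).mean().T
    collapsed = collapsed[sorted(collapsed.columns)]
    return TimePointProfile(values=collapsed, variety=variety, tissue=tissue)


def classify_expressed(
    profile: TimePointProfile, threshold: float = EXPRESSION_THRESHOLD
) -> pd.Series:
    """Boolean per gene: max FPKM across the time series >= threshold.

    The boundary is inclusive: a gene peaking at exactly the threshold
    counts as expressed.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return profile.values.max(axis=1) >= threshold


def expressed_set(profile: TimePointProfile, threshold: float = EXPRESSION_THRESHOLD) -> frozenset:
    """Convenience: the set of expressed gene IDs of a profile."""
    flags = classify_expressed(profile, threshold)
    return frozenset(flags.index[flags])


def som_prefilter(
    profile: TimePointProfile,
    homology: Mapping[str, str] | Iterable[str],
    detection_floor: float = 0.0,
    threshold: float = EXPRESSION_THRESHOLD,
) -> tuple[list[str], dict[str, int]]:
    """Three-stage gene filter applied before SOM clustering, in order:

    1. keep genes detected (FPKM strictly above ``detection_floor``) in at
       least half of the time points;
    2. keep genes expressed (max >= ``threshold``) at one or more time
       points;
    3. keep genes with a model-organism homologue (present in ``homology``).

    Returns the surviving gene list (input order) and per-stage survivor
    counts, which are non-increasing by construction.
    """
    vals = profile.values
    n_days = vals.shape[1]
    counts: dict[str, int] = {"input": int(vals.shape[0])}

    detected = (vals > detection_floor).sum(axis=1) >= n_days / 2.0
    stage1 = vals[detected]
    counts["detected_half"] = int(stage1.shape[0])

    expressed = stage1.max(axis=1) >= threshold
    stage2 = stage1[expressed]
    counts["expressed"] = int(stage2.shape[0])

    homologous = set(homology.keys() if isinstance(homology, Mapping) else homology)
    survivors = [g for g in stage2.index if g in homologous]
    counts["homologous"] = len(survivors)
    return survivors, counts


def variety_specific_sets(
    profile_a: TimePointProfile,
    profile_b: TimePointProfile,
    gene_subset: Sequence[str] | None = None,
    threshold: float = EXPRESSION_THRESHOLD,
) -> GeneSetOverlap:
    """Partition expressed genes into variety-A-only / variety-B-only / shared.

    Both profiles must overlap in gene universe; the comparison runs over
    the shared universe (optionally restricted to ``gene_subset``).
    Percentages are computed over the union of expressed sets.
    """
    common = profile_a.values.index.intersection(profile_b.values.index)
    if len(common) == 0:
        raise ValueError("profiles have disjoint gene universes")
    if gene_subset is not None:
        missing = sorted(set(gene_subset) - set(common))
        if missing:
            raise ValueError(f"subset genes absent from both profiles: {missing[:10]}")
        common = common.intersection(pd.Index(gene_subset))

    in_a = frozenset(
        g for g in common if profile_a.values.loc[g].max() >= threshold
    )
    in_b = frozenset(
        g for g in common if profile_b.values.loc[g].max() >= threshold
    )
    only_a = in_a - in_b
    only_b = in_b - in_a
    shared = in_a & in_b
    union = in_a | in_b
    if union:
        pct = tuple(100.0 * len(s) / len(union) for s in (only_a, only_b, shared))
    else:
        pct = (0.0, 0.0, 0.0)
    return GeneSetOverlap(only_a=only_a, only_b=only_b, shared=shared, percentages=pct)
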