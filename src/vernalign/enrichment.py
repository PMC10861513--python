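"""Cluster and term enrichment: one-sided Fisher tests with BH-FDR control.

Tests whether a "special" gene set (typically variety-specific genes) is
over-represented in each SOM cluster relative to all genes mapped to the
map, and provides the same one-sided hypergeometric machinery for generic
term enrichment against an annotation table.  P-values within one family
of tests are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .som import ClusterAssignment


def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) hypergeometric p for the 2x2 table
    [[a, b], [c, d]]: P(X >= a) with X ~ Hypergeom(N, a+b, a+c)."""
    N = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, N, a + b, a + c))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fdr_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    assignment: ClusterAssignment,
    special: set[str] | frozenset,
    background: set[str] | frozenset | None = None,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-cluster 2x2 Fisher test of special-gene over-representation.

    The background defaults to all genes mapped to the SOM.  For each
    cluster the table is (special in / special out / non-special in /
    non-special out); the p-value is one-sided (greater) by default, and
    q-values are BH-adjusted across the clusters of this map.
    """
    mapped = set(assignment.gene_unit.index)
    if background is None:
        background = mapped
    offenders = sorted(set(special) - set(background))
    if offenders:
        raise ValueError(f"special genes outside the background: {offenders[:10]}")
    genes = assignment.gene_unit[assignment.gene_unit.index.isin(background)]
    n_total = len(genes)
    n_special = int(genes.index.isin(list(special)).sum())
    rows = []
    for unit in range(assignment.n_units):
        members = genes[genes == unit].index
        a = int(members.isin(list(special)).sum())
        c = len(members) - a
        b = n_special - a
        d = n_total - a - b - c
        if alternative == "greater":
            p = _fisher_greater(a, b, c, d)
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])
        rows.append(
            {"cluster": unit, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": _odds_ratio(a, b, c, d), "p_value": p}
        )
    table = pd.DataFrame(rows).set_index("cluster")
    table["q_value"] = fdr_adjust(table["p_value"])
    return table


def top_enriched_clusters(
    table: pd.DataFrame, alpha: float = 1e-5, k: int = 3
) -> list[int]:
    """Clusters with q below alpha, ascending by q (ties by cluster index),
    truncated to the top k.  May be empty."""
    hits = table[table["q_value"] < alpha]
    order = sorted(hits.index, key=lambda c: (hits.loc[c, "q_value"], c))
    return [int(c) for c in order[:k]]


def term_enrichment(
    gene_set: set[str] | frozenset,
    background: set[str] | frozenset,
    annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment of ``gene_set`` against
    ``background`` using a gene -> term-set annotation.

    Only terms annotating at least one background gene are tested; BH
    adjustment runs across those terms.
    """
    offenders = sorted(set(gene_set) - set(background))
    if offenders:
        raise ValueError(f"gene_set members outside the background: {offenders[:10]}")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    if not term_genes:
        return pd.DataFrame(
            columns=["a", "b", "c", "d", "odds_ratio", "p_value", "q_value"]
        ).rename_axis("term")
    N = len(background)
    K = len(gene_set)
    rows = []
    for term in sorted(term_genes):
        ann = term_genes[term]
        a = len(ann & set(gene_set))
        c = len(set(gene_set)) - a
        b = len(ann) - a
        d = N - a - b - c
        # table: rows = in/out of the term, cols = in/out of the gene set
        rows.append(
            {"term": term, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": _odds_ratio(a, b, c, d),
             "p_value": _fisher_greater(a, b, c, d)}
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q_value"] = fdr_adjust(table["p_value"])
    return table
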