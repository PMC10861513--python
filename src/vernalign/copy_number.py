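"""Homologue-family copy-number expression bias.

Crop genes are grouped into homologue families by their best-scoring hit
to a model-organism gene.  For each family the number of expressed copies
is counted per variety; the copy-number expression bias is the absolute
difference of the two counts.  A family with equal counts achieved
through different, variety-specific members shows compensatory orthologue
expression.  Directional bias across families is tested with an exact
two-sided binomial test (minimum-likelihood convention, as in R's
``binom.test``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HomologueFamilyTable:
    """Model-organism gene -> list of crop gene copies."""

    families: dict[str, list[str]]
    provenance: str = "best blastn hit"

    @property
    def gene_to_family(self) -> dict[str, str]:
        return {g: fam for fam, genes in self.families.items() for g in genes}


@dataclass
class FamilyBiasRecord:
    family_id: str
    n_expressed_a: int
    n_expressed_b: int
    compensatory: bool

    @property
    def bias(self) -> int:
        return abs(self.n_expressed_a - self.n_expressed_b)

    @property
    def direction(self) -> str:
        if self.n_expressed_a > self.n_expressed_b:
            return "a"
        if self.n_expressed_b > self.n_expressed_a:
            return "b"
        return "none"


def build_families(homology: pd.DataFrame) -> HomologueFamilyTable:
    """Group crop genes into families keyed by their best model-gene hit.

    ``homology`` has columns ``crop_gene``, ``model_gene``, ``bitscore``.
    Per crop gene the highest-bitscore hit wins; ties break towards the
    lexicographically smallest model-gene ID.  Exact duplicate rows
    collapse silently.
    """
    required = {"crop_gene", "model_gene", "bitscore"}
    missing = required - set(homology.columns)
    if missing:
        raise ValueError(f"homology table lacks columns: {sorted(missing)}")
    families: dict[str, list[str]] = {}
    if len(homology):
        best = (
            homology.sort_values(
                ["crop_gene", "bitscore", "model_gene"],
                ascending=[True, False, True],
                kind="mergesort",
            )
            .drop_duplicates("crop_gene", keep="first")
        )
        for crop, model in zip(best["crop_gene"], best["model_gene"]):
            families.setdefault(model, []).append(crop)
    return HomologueFamilyTable(families=families)


def family_expression_counts(
    families: HomologueFamilyTable,
    expressed_a: set[str] | frozenset,
    expressed_b: set[str] | frozenset,
) -> list[FamilyBiasRecord]:
    """Count expressed copies per family in each variety.

    A family is compensatory when both counts are equal and each variety
    expresses at least one member the other does not.
    """
    records = []
    for fam, genes in families.families.items():
        members = set(genes)
        in_a = members & set(expressed_a)
        in_b = members & set(expressed_b)
        compensatory = len(in_a) == len(in_b) and bool(in_a - in_b) and bool(in_b - in_a)
        records.append(
            FamilyBiasRecord(
                family_id=fam,
                n_expressed_a=len(in_a),
                n_expressed_b=len(in_b),
                compensatory=compensatory,
            )
        )
    return records


def bias_summary(records: list[FamilyBiasRecord]) -> dict:
    """Aggregate family bias records.

    Returns a dict with the (n_a, n_b) count grid, a per-direction bias
    histogram, and the percentages of families biased towards each
    variety and compensatory.  Percentages are over families with at
    least one expressed copy in either variety.
    """
    grid = Counter((r.n_expressed_a, r.n_expressed_b) for r in records)
    hist: dict[str, Counter] = {"a": Counter(), "b": Counter(), "none": Counter()}
    for r in records:
        hist[r.direction][r.bias] += 1
    active = [r for r in records if r.n_expressed_a + r.n_expressed_b > 0]
    n_active = len(active)
    if n_active:
        pct_a = 100.0 * sum(r.direction == "a" for r in active) / n_active
        pct_b = 100.0 * sum(r.direction == "b" for r in active) / n_active
        pct_comp = 100.0 * sum(r.compensatory for r in active) / n_active
    else:
        pct_a = pct_b = pct_comp = 0.0
    return {
        "grid": dict(grid),
        "bias_histogram": {k: dict(v) for k, v in hist.items()},
        "pct_biased_a": pct_a,
        "pct_biased_b": pct_b,
        "pct_compensatory": pct_comp,
        "n_families": len(records),
        "n_active": n_active,
    }


def bias_binomial_test(records: list[FamilyBiasRecord]) -> tuple[int, int, float]:
    """Exact two-sided binomial test of directional bias.

    Among families with non-zero bias, tests whether the number biased
    towards variety A departs from a fair 50:50 split.  The two-sided
    p-value sums the probabilities of all outcomes no more likely than
    the observed one (minimum-likelihood convention).
    """
    k_a = sum(1 for r in records if r.direction == "a")
    k_b = sum(1 for r in records if r.direction == "b")
    n = k_a + k_b
    if n == 0:
        raise ValueError("no biased families")
    p = stats.binomtest(k_a, n, 0.5, alternative="two-sided").pvalue
    return n, k_a, float(p)


def records_table(records: list[FamilyBiasRecord]) -> pd.DataFrame:
    """Flat per-family table (family, n_a, n_b, bias, direction, compensatory)."""
    return pd.DataFrame(
        [
            {
                "family": r.family_id,
                "n_expressed_a": r.n_expressed_a,
                "n_expressed_b": r.n_expressed_b,
                "bias": r.bias,
                "direction": r.direction,
                "compensatory": r.compensatory,
            }
            for r in records
        ]
    )
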