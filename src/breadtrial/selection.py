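"""Tie-inclusive top-k selection sets and indirect-selection overlap.

A breeder "selecting the top 10" by a trait keeps every line whose value
ties or beats the 10th-ranked distinct value, so the selected set can
exceed 10 members when lines share values (rank depth over distinct
values).  Overlap between two selection sets is reported relative to the
selecting (first) set: percentage = 100 * |A intersect B| / |A|, rounded
half-up to an integer -- the arithmetic used to quantify how often
selecting on a proxy trait in one year recovers the top lines for the
target trait in the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import entry_means
from .io import PhenotypeTable


@dataclass
class SelectionSet:
    trait: str
    environment: str
    k: int
    members: set = field(default_factory=set)
    universe: set = field(default_factory=set)
    higher_is_better: bool = True
    threshold: float = float("nan")


def top_k(values: pd.Series, k: int, higher_is_better: bool = True,
          trait: str = "", environment: str = "") -> SelectionSet:
    """Genotypes within the top-k distinct-value ranks, boundary ties included."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = values.dropna()
    if vals.empty:
        raise ValueError("all values missing")
    distinct = np.sort(vals.unique())
    if higher_is_better:
        distinct = distinct[::-1]
    threshold = distinct[min(k, len(distinct)) - 1]
    if higher_is_better:
        members = set(vals.index[vals >= threshold])
    else:
        members = set(vals.index[vals <= threshold])
    return SelectionSet(trait=trait, environment=environment, k=k,
                        members=members, universe=set(vals.index),
                        higher_is_better=higher_is_better,
                        threshold=float(threshold))


@dataclass
class OverlapReport:
    size_a: int
    size_b: int
    intersection: int
    percentage: int  # 100 * |A n B| / |A|, rounded half-up

    @classmethod
    def from_counts(cls, size_a: int, size_b: int,
                    intersection: int) -> "OverlapReport":
        pct = int(math.floor(100.0 * intersection / size_a + 0.5))
        return cls(size_a, size_b, intersection, pct)


def overlap(a: SelectionSet, b: SelectionSet) -> OverlapReport:
    """Intersection of two selection sets, relative to the first (selecting) set."""
    if a.universe and b.universe and not (a.universe & b.universe):
        raise ValueError("selection sets share no genotypes (disjoint namespaces)")
    inter = len(a.members & b.members)
    return OverlapReport.from_counts(len(a.members), len(b.members), inter)


def indirect_selection_report(pheno: PhenotypeTable,
                              proxy_trait: str,
                              target_trait: str,
                              years: tuple[str, str] | None = None,
                              k: int = 10,
                              higher_is_better: bool = True) -> pd.DataFrame:
    """Cross-year / cross-trait top-k coincidence table.

    Emits four comparisons: proxy(year1) -> target(year2), proxy(avg) ->
    target(avg), target(year1) -> target(year2) and proxy(year1) ->
    proxy(year2), each with set sizes, intersection and percentage
    relative to the selecting set.  A comparison whose year is absent for
    either trait is skipped with its reason recorded.
    """
    em_proxy = entry_means(pheno, proxy_trait)
    em_target = entry_means(pheno, target_trait)
    if years is None:
        shared = [y for y in pheno.years if y in em_proxy.columns
                  and y in em_target.columns]
        if len(shared) < 2:
            raise ValueError("need two shared years (or pass `years`)")
        years = (shared[0], shared[1])
    y1, y2 = years

    def sel(em: pd.DataFrame, trait: str, col: str) -> SelectionSet | None:
        if col not in em.columns:
            return None
        return top_k(em[col], k, higher_is_better, trait=trait,
                     environment=col)

    comparisons = [
        ("proxy_y1_vs_target_y2", sel(em_proxy, proxy_trait, y1),
         sel(em_target, target_trait, y2)),
        ("proxy_avg_vs_target_avg", sel(em_proxy, proxy_trait, "mean"),
         sel(em_target, target_trait, "mean")),
        ("target_y1_vs_target_y2", sel(em_target, target_trait, y1),
         sel(em_target, target_trait, y2)),
        ("proxy_y1_vs_proxy_y2", sel(em_proxy, proxy_trait, y1),
         sel(em_proxy, proxy_trait, y2)),
    ]
    rows = []
    for name, a, b in comparisons:
        if a is None or b is None:
            rows.append({"comparison": name, "skipped": "missing year"})
            continue
        rep = overlap(a, b)
        rows.append({
            "comparison": name,
            "select_trait": a.trait, "select_env": a.environment,
            "outcome_trait": b.trait, "outcome_env": b.environment,
            "k": k, "size_a": rep.size_a, "size_b": rep.size_b,
            "intersection": rep.intersection, "percentage": rep.percentage,
            "skipped": "",
        })
    return pd.DataFrame(rows)
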