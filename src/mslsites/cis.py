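"""Overlap of non-DC binding sites with cis-regulatory annotations.

Elements (promoters, enhancers, insulators) are assigned to a binding site
either when the element's center/summit falls inside the site
(center_within, the default) or when the shared region covers at least
half of either the site or the element (half_overlap). A site may hit
several categories; category counts are redundant, the per-site total is
deduplicated. All inputs must share one coordinate system — chromosome
name intersection is validated up front.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from fractions import Fraction

from .intervals import Interval, overlap_length
from .turnover import Peak

__all__ = ["CisElement", "assign_cis", "cis_overlap_table", "read_cis_elements"]

CATEGORIES = ("promoter", "enhancer", "insulator")


@dataclass(frozen=True)
class CisElement:
    interval: Interval
    center: int
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown cis-element category {self.category!r}")
        if not self.interval.contains_point(self.center):
            raise ValueError(f"center {self.center} outside {self.interval}")


def _elements_hit(peak: Peak, elements_tree: IntervalTree | None, rule: str) -> set[str]:
    hits: set[str] = set()
    if elements_tree is None:
        return hits
    iv = peak.interval
    for h in elements_tree.overlap(iv.start, iv.end):
        el: CisElement = h.data
        if rule == "center_within":
            if iv.contains_point(el.center):
                hits.add(el.category)
        else:  # half_overlap: >= half of either the site or the element
            ov = overlap_length(iv, el.interval)
            if ov >= Fraction(iv.length, 2) or ov >= Fraction(el.interval.length, 2):
                hits.add(el.category)
    return hits


def assign_cis(
    peaks: Sequence[Peak],
    elements: Sequence[CisElement],
    rule: str = "center_within",
) -> tuple[list[set[str]], dict[str, int]]:
    """Per-peak category hits plus per-category counts.

    Returns (hits_per_peak, counts) where counts has one entry per
    category (a peak spanning two categories counts in both) plus
    ``total``: the number of distinct peaks hitting any element.
    """
    if rule not in ("center_within", "half_overlap"):
        raise ValueError(f"unknown cis overlap rule {rule!r}")
    trees: dict[str, IntervalTree] = {}
    for el in elements:
        trees.setdefault(el.interval.chrom, IntervalTree()).addi(
            el.interval.start, el.interval.end, el
        )
    per_peak = [_elements_hit(p, trees.get(p.interval.chrom), rule) for p in peaks]
    counts = {cat: sum(1 for h in per_peak if cat in h) for cat in CATEGORIES}
    counts["total"] = sum(1 for h in per_peak if h)
    return per_peak, counts


def cis_overlap_table(
    peaks_by_group: Mapping[str, Sequence[Peak]],
    elements: Sequence[CisElement],
    rule: str = "center_within",
) -> pd.DataFrame:
    """Counts shaped like the published overlap table: one row per group
    (e.g. TE-derived / non-TE-derived per protein) plus a summed row, with
    redundant per-category counts and a deduplicated total."""
    rows = []
    sums = {cat: 0 for cat in CATEGORIES} | {"total": 0, "n_sites": 0}
    for group, peaks in peaks_by_group.items():
        _, counts = assign_cis(peaks, elements, rule)
        row = {"group": group, "n_sites": len(peaks), **counts}
        rows.append(row)
        for k in sums:
            sums[k] += row[k]
    rows.append({"group": "sum", **sums})
    return pd.DataFrame(rows)


def read_cis_elements(path) -> list[CisElement]:
    """Read the element dialect: chrom, start, end, category, center."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "category", "center"], dtype={"chrom": str},
    )
    return [
        CisElement(
            Interval(str(r.chrom), int(r.start), int(r.end)), int(r.center), str(r.category)
        )
        for r in df.itertuples(index=False)
    ]


def validate_chromosomes(
    peaks: Sequence[Peak], elements: Sequence[CisElement]
) -> list[str]:
    """Problems when peak and element chromosome names do not intersect —
    the usual symptom of mixed genome assemblies."""
    pc = {p.interval.chrom for p in peaks}
    ec = {e.interval.chrom for e in elements}
    if pc and ec and not (pc & ec):
        return [
            f"no shared chromosome names between peaks ({sorted(pc)[:3]}...) "
            f"and cis-elements ({sorted(ec)[:3]}...)"
        ]
    return []
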