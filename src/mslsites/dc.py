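"""DC / non-DC classification of MOF and MSL1 binding sites.

A MOF or MSL1 site is a dosage-compensation (DC) site when it overlaps an
MSL2-bound region under the reciprocal-half rule (shared region larger than
half of each site); otherwise it is non-DC and a candidate for an
MSL2-independent regulatory function. Peak lists are merged within protein
before classification so many-to-one overlaps count once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import Interval, OverlapRule, satisfies
from .turnover import Peak

__all__ = [
    "SiteLabel",
    "classify_dc",
    "overlap_partition",
    "chromosome_distribution",
    "X_CHROMS",
    "AUTOSOMES",
]

# chr4 and unplaced scaffolds are "other": excluded from autosomes.
X_CHROMS = frozenset({"X", "chrX"})
AUTOSOMES = frozenset({"2L", "2R", "3L", "3R", "chr2L", "chr2R", "chr3L", "chr3R"})


def chromosome_class(
    chrom: str,
    x_chroms: frozenset[str] = X_CHROMS,
    autosomes: frozenset[str] = AUTOSOMES,
    warn_unknown: bool = False,
) -> str:
    if chrom in x_chroms:
        return "X"
    if chrom in autosomes:
        return "autosome"
    if warn_unknown and chrom not in ("4", "chr4"):
        warnings.warn(f"unknown chromosome {chrom!r} classed as 'other'", stacklevel=2)
    return "other"


@dataclass(frozen=True)
class SiteLabel:
    peak: Peak
    dc_status: str  # DC | nonDC
    chromosome_class: str  # X | autosome | other


def _tree(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def classify_dc(
    target_peaks: Sequence[Peak],
    msl2_peaks: Sequence[Peak],
    x_chroms: frozenset[str] = X_CHROMS,
    autosomes: frozenset[str] = AUTOSOMES,
) -> list[SiteLabel]:
    """Label each MOF/MSL1 peak DC iff it reciprocal-half-overlaps any MSL2 peak."""
    bad = {p.protein for p in target_peaks} - {"MOF", "MSL1"}
    if bad:
        raise ValueError(f"target peaks must be MOF or MSL1, got {bad}")
    bad2 = {p.protein for p in msl2_peaks} - {"MSL2"}
    if bad2:
        raise ValueError(f"msl2_peaks must be MSL2, got {bad2}")
    trees = _tree(p.interval for p in msl2_peaks)
    labels: list[SiteLabel] = []
    for peak in target_peaks:
        iv = peak.interval
        hits = trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        is_dc = any(
            satisfies(iv, h.data, OverlapRule.RECIPROCAL_HALF) for h in hits
        )
        labels.append(
            SiteLabel(
                peak,
                "DC" if is_dc else "nonDC",
                chromosome_class(iv.chrom, x_chroms, autosomes),
            )
        )
    return labels


_CLASSES = (
    "MOF_only", "MSL1_only", "MSL2_only",
    "MOF_MSL1", "MOF_MSL2", "MSL1_MSL2", "MOF_MSL1_MSL2",
)


def overlap_partition(
    mof: Sequence[Interval],
    msl1: Sequence[Interval],
    msl2: Sequence[Interval],
) -> dict[str, int]:
    """Three-way membership counts of merged regions (7-region partition).

    Regions from the three (pre-merged) lists are linked whenever a
    cross-protein pair satisfies the reciprocal-half rule; each connected
    group of linked regions counts once, under the membership class given
    by the set of proteins it contains (Venn-diagram semantics: three
    identical intervals contribute a single triple-overlap region).
    """
    nodes: list[tuple[str, Interval]] = (
        [("MOF", iv) for iv in mof]
        + [("MSL1", iv) for iv in msl1]
        + [("MSL2", iv) for iv in msl2]
    )
    parent = list(range(len(nodes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    trees: dict[str, IntervalTree] = {}
    for idx, (_, iv) in enumerate(nodes):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, idx)
    for idx, (protein, iv) in enumerate(nodes):
        for hit in trees[iv.chrom].overlap(iv.start, iv.end):
            jdx = hit.data
            if jdx <= idx or nodes[jdx][0] == protein:
                continue
            if satisfies(iv, nodes[jdx][1], OverlapRule.RECIPROCAL_HALF):
                union(idx, jdx)

    groups: dict[int, set[str]] = {}
    for idx, (protein, _) in enumerate(nodes):
        groups.setdefault(find(idx), set()).add(protein)
    counts = {c: 0 for c in _CLASSES}
    for proteins in groups.values():
        key = "_".join(p for p in ("MOF", "MSL1", "MSL2") if p in proteins)
        if len(proteins) == 1:
            key = f"{key}_only"
        counts[key] += 1
    return counts


def chromosome_distribution(labels: Sequence[SiteLabel]) -> pd.DataFrame:
    """Per-protein fraction of sites on X, autosomes and elsewhere."""
    if not labels:
        return pd.DataFrame(columns=["protein", "X", "autosome", "other", "n"])
    df = pd.DataFrame(
        {
            "protein": [l.peak.protein for l in labels],
            "cls": [l.chromosome_class for l in labels],
        }
    )
    out = []
    for protein, grp in df.groupby("protein"):
        n = len(grp)
        frac = grp["cls"].value_counts(normalize=True)
        out.append(
            {
                "protein": protein,
                "X": float(frac.get("X", 0.0)),
                "autosome": float(frac.get("autosome", 0.0)),
                "other": float(frac.get("other", 0.0)),
                "n": n,
            }
        )
    return pd.DataFrame(out)


def labels_to_frame(labels: Sequence[SiteLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [l.peak.name for l in labels],
            "chrom": [l.peak.interval.chrom for l in labels],
            "start": [l.peak.interval.start for l in labels],
            "end": [l.peak.interval.end for l in labels],
            "protein": [l.peak.protein for l in labels],
            "species": [l.peak.species for l in labels],
            "dc_status": [l.dc_status for l in labels],
            "chromosome_class": [l.chromosome_class for l in labels],
        }
    )
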