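"""Genomic interval algebra: the three half-overlap criteria and peak merging.

All coordinates are 0-based half-open (BED convention). Readers convert on
ingest, writers convert back, so every in-memory position follows one rule.

Three distinct overlap criteria recur throughout the pipeline:

* ``reciprocal_half`` — the shared region must exceed half the length of
  *each* interval (used to call a MOF/MSL1 site MSL2-overlapping, i.e. DC).
* ``either_half`` — the shared region must exceed half the length of at
  least *one* interval (used when merging adjacent peaks).
* ``one_sided_half`` — at least half of the *first* interval is covered
  (used for cross-species conservation of a binding site; non-strict).
* ``center_within`` — the partner's center/summit lies inside the interval
  (used for cis-regulatory element assignment).

"larger than half" is strict (>); "at least half" is non-strict (>=). For
odd lengths half-length is the exact rational len/2 compared against the
integer overlap, which avoids any off-by-one asymmetry between the two
members of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Interval",
    "OverlapRule",
    "overlap_length",
    "satisfies",
    "merge_peaks",
    "extend",
    "read_bed6",
    "write_bed6",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


class OverlapRule(str, Enum):
    RECIPROCAL_HALF = "reciprocal_half"
    EITHER_HALF = "either_half"
    ONE_SIDED_HALF = "one_sided_half"
    CENTER_WITHIN = "center_within"


def overlap_length(a: Interval, b: Interval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def satisfies(
    a: Interval,
    b: Interval,
    rule: OverlapRule | str,
    center_of_b: int | None = None,
) -> bool:
    """Test an overlap criterion between ``a`` and ``b``.

    For ``center_within``, ``center_of_b`` (the partner's summit/center)
    must be supplied and the test is containment of that point in ``a``.
    """
    rule = OverlapRule(rule)
    if rule is OverlapRule.CENTER_WITHIN:
        if center_of_b is None:
            raise ValueError("center_within rule requires center_of_b")
        return a.chrom == b.chrom and a.contains_point(center_of_b)

    ov = overlap_length(a, b)
    half_a = Fraction(a.length, 2)
    half_b = Fraction(b.length, 2)
    if rule is OverlapRule.RECIPROCAL_HALF:
        return ov > half_a and ov > half_b
    if rule is OverlapRule.EITHER_HALF:
        return ov > half_a or ov > half_b
    # one_sided_half: "at least half of its binding region" -> non-strict,
    # judged on `a` only.
    return ov >= half_a


@dataclass
class MergedInterval:
    """A merged interval plus the indices of the inputs it absorbed."""

    interval: Interval
    sources: list[int] = field(default_factory=list)


def merge_peaks(peaks: Sequence[Interval]) -> list[MergedInterval]:
    """Merge adjacent peaks whose shared region exceeds half of either peak.

    Peaks are sorted by (chrom, start, end); a single left-to-right pass
    compares the running merged interval against the next peak under the
    either_half rule and unions them when it holds. Merging is transitive
    within the pass. Provenance (input indices) is recorded per output.
    """
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start, peaks[i].end, i))
    merged: list[MergedInterval] = []
    for idx in order:
        p = peaks[idx]
        if merged:
            cur = merged[-1].interval
            if cur.chrom == p.chrom and satisfies(cur, p, OverlapRule.EITHER_HALF):
                merged[-1].interval = Interval(cur.chrom, min(cur.start, p.start), max(cur.end, p.end))
                merged[-1].sources.append(idx)
                continue
        merged.append(MergedInterval(p, [idx]))
    return merged


def extend(a: Interval, factor: float = 0.5, chrom_length: int | None = None) -> Interval:
    """Extend an interval by ``factor``·length on each side, clamped to the
    chromosome. ``factor=0.5`` is the half-length extension used when
    searching the partner species' signal around an orthologous region."""
    if factor < 0:
        raise ValueError("extension factor must be >= 0")
    pad = int(round(factor * a.length))
    start = max(0, a.start - pad)
    end = a.end + pad
    if chrom_length is not None:
        end = min(chrom_length, end)
    return Interval(a.chrom, start, end)


# ---------------------------------------------------------------------------
# BED6 I/O

_BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a frame with the canonical six columns.

    Missing name/score/strand are filled with ".", 0, ".".
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns, got {df.shape[1]}")
    df = df.iloc[:, :6]
    defaults = {3: ".", 4: 0, 5: "."}
    for col in range(df.shape[1], 6):
        df[col] = defaults[col]
    df.columns = _BED6_COLS
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}: empty/inverted interval at record {bad}")
    return df


def write_bed6(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _BED6_COLS:
        if col not in out.columns:
            out[col] = "." if col in ("name", "strand") else 0
    out[_BED6_COLS].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_frame(df: pd.DataFrame) -> list[Interval]:
    """Build Interval objects from any frame with chrom/start/end columns."""
    return [Interval(str(c), int(s), int(e)) for c, s, e in zip(df["chrom"], df["start"], df["end"])]


def total_length(intervals: Iterable[Interval]) -> int:
    """Total bp covered by a set of intervals after collapsing overlaps."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    tot = 0
    for spans in by_chrom.values():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                tot += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        tot += cur_e - cur_s
    return tot
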