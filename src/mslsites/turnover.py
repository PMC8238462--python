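"""Cross-species binding-site turnover and conservation calls.

Two complementary questions are asked of every peak:

* presence/absence — is the orthologous region still bound at all? The
  highest linear fold-enrichment (ChIP/input) is looked up in the peak's
  own species and, after projecting through the ortholog map and extending
  the orthologous region by half its length on each side, in the partner
  species. A peak is called absent in the partner when the partner's best
  signal is reduced 10-fold or more (other <= own/10, boundary inclusive).

* conservation — is the orthologous region bound by the *same* protein in
  the partner species? The peak is projected into partner coordinates and
  called conserved when at least half of the projected region overlaps the
  union of the partner's same-protein peaks (one-sided, non-strict).
  Unmappable peaks are unconserved but reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval, OverlapRule, extend, overlap_length, satisfies
from .orthomap import OrthologMap

__all__ = [
    "Peak",
    "SignalTrack",
    "TurnoverCall",
    "ConservationCall",
    "max_signal",
    "call_turnover",
    "call_conservation",
    "turnover_summary",
    "read_peaks",
    "read_bedgraph",
]

PROTEINS = ("MOF", "MSL1", "MSL2")
ABSENCE_FOLD = 10.0


@dataclass(frozen=True)
class Peak:
    """A protein-bound region with summit position and linear fold-enrichment."""

    interval: Interval
    summit: int
    protein: str
    species: str
    fold_enrichment: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not self.interval.contains_point(self.summit):
            raise ValueError(f"summit {self.summit} outside {self.interval}")
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")


class SignalTrack:
    """Stepwise per-base linear fold-enrichment (bedGraph semantics).

    Segments are stored per chromosome as sorted (start, end, value)
    arrays; uncovered positions have value 0.
    """

    def __init__(self, segments: Iterable[tuple[str, int, int, float]] = ()):
        staged: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in segments:
            if value < 0:
                raise ValueError("signal values must be >= 0")
            if start >= end:
                raise ValueError(f"empty segment {chrom}:{start}-{end}")
            staged.setdefault(str(chrom), []).append((int(start), int(end), float(value)))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in staged.items():
            segs.sort()
            starts = np.array([s for s, _, _ in segs])
            ends = np.array([e for _, e, _ in segs])
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"overlapping signal segments on {chrom} near {starts[i + 1]}"
                )
            self._chroms[chrom] = (starts, ends, np.array([v for _, _, v in segs]))

    def max_in(self, region: Interval) -> float:
        arr = self._chroms.get(region.chrom)
        if arr is None:
            return 0.0
        starts, ends, values = arr
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi <= lo:
            return 0.0
        return float(values[lo:hi].max())


def max_signal(track: SignalTrack, region: Interval) -> float:
    """Highest step value over positions intersecting ``region`` (0 if none)."""
    return track.max_in(region)


@dataclass(frozen=True)
class TurnoverCall:
    peak: Peak
    status: str  # present_in_other | absent_in_other | unmappable
    own_signal: float
    other_signal: float
    ortholog: Interval | None = None


@dataclass(frozen=True)
class ConservationCall:
    peak: Peak
    status: str  # conserved | unconserved
    mappable: bool
    overlap_fraction: float


def call_turnover(
    peak: Peak,
    own_track: SignalTrack,
    ortho_map: OrthologMap,
    other_track: SignalTrack,
    other_chrom_lengths: dict[str, int] | None = None,
    fold: float = ABSENCE_FOLD,
) -> TurnoverCall:
    """Presence/absence of a peak's orthologous region in the partner species."""
    own = max_signal(own_track, peak.interval)
    ortho = ortho_map.project(peak.interval)
    if ortho is None:
        return TurnoverCall(peak, "unmappable", own, 0.0, None)
    chrom_len = (other_chrom_lengths or {}).get(ortho.chrom)
    search = extend(ortho, 0.5, chrom_len)
    other = max_signal(other_track, search)
    if own == 0:
        # A zero own-signal makes the 10-fold rule vacuous; never call absent.
        warnings.warn(
            f"peak {peak.name} at {peak.interval} has zero own signal; "
            "presence call is degenerate",
            stacklevel=2,
        )
        return TurnoverCall(peak, "present_in_other", own, other, ortho)
    status = "absent_in_other" if other <= own / fold else "present_in_other"
    return TurnoverCall(peak, status, own, other, ortho)


def call_conservation(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    map_a_to_b: OrthologMap,
) -> list[ConservationCall]:
    """Conservation of species-A peaks against same-protein species-B peaks.

    Each A peak is projected into B coordinates; it is conserved when at
    least half of the projected region overlaps the union of B's peaks
    for the same protein. Unmappable peaks are unconserved.
    """
    proteins_a = {p.protein for p in peaks_a}
    proteins_b = {p.protein for p in peaks_b}
    if len(proteins_a | proteins_b) > 1:
        raise ValueError(
            f"conservation compares one protein at a time, got {proteins_a | proteins_b}"
        )
    b_by_chrom: dict[str, list[Interval]] = {}
    for p in peaks_b:
        b_by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    calls: list[ConservationCall] = []
    for peak in peaks_a:
        proj = map_a_to_b.project(peak.interval)
        if proj is None:
            calls.append(ConservationCall(peak, "unconserved", False, 0.0))
            continue
        covered = _union_overlap(proj, b_by_chrom.get(proj.chrom, ()))
        frac = covered / proj.length
        status = "conserved" if covered >= proj.length / 2 else "unconserved"
        calls.append(ConservationCall(peak, status, True, frac))
    return calls


def _union_overlap(region: Interval, others: Iterable[Interval]) -> int:
    """bp of ``region`` covered by the union of ``others`` (same chromosome)."""
    spans = sorted(
        (max(region.start, o.start), min(region.end, o.end))
        for o in others
        if o.end > region.start and o.start < region.end
    )
    covered = 0
    cur_end = region.start
    for s, e in spans:
        s = max(s, cur_end)
        if e > s:
            covered += e - s
            cur_end = e
    return covered


def turnover_summary(calls: Iterable[TurnoverCall | ConservationCall]) -> pd.DataFrame:
    """Counts by species, protein and status; statuses sum to the input size."""
    rows = [
        {"species": c.peak.species, "protein": c.peak.protein, "status": c.status}
        for c in calls
    ]
    if not rows:
        return pd.DataFrame(columns=["species", "protein", "status", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["species", "protein", "status"]).size().rename("count").reset_index()
    )


# ---------------------------------------------------------------------------
# Readers


def read_peaks(path, protein: str, species: str) -> list[Peak]:
    """Read peaks from narrowPeak (10 cols, summit offset in col 10) or BED.

    narrowPeak's signalValue column carries the fold enrichment; plain BED
    peaks get summit = interval midpoint and fold enrichment 0.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    peaks: list[Peak] = []
    for row in df.itertuples(index=False):
        iv = Interval(str(row[0]), int(row[1]), int(row[2]))
        name = str(row[3]) if len(row) > 3 else "."
        fe = float(row[6]) if len(row) >= 10 else 0.0
        if len(row) >= 10 and int(row[9]) >= 0:
            summit = iv.start + int(row[9])
        else:
            summit = iv.midpoint
        peaks.append(Peak(iv, summit, protein, species, fe, name))
    return peaks


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    return SignalTrack(df.itertuples(index=False, name=None))


def write_calls(calls: Sequence[TurnoverCall | ConservationCall], path) -> None:
    rows = []
    for c in calls:
        row = {
            "name": c.peak.name,
            "chrom": c.peak.interval.chrom,
            "start": c.peak.interval.start,
            "end": c.peak.interval.end,
            "protein": c.peak.protein,
            "species": c.peak.species,
            "status": c.status,
        }
        if isinstance(c, TurnoverCall):
            row["own_signal"] = c.own_signal
            row["other_signal"] = c.other_signal
        else:
            row["mappable"] = c.mappable
            row["overlap_fraction"] = round(c.overlap_fraction, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
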