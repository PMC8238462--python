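"""Transposable-element annotation cleaning, TE-derived site calling and
family enrichment.

Raw repeat-masker hits are cleaned in four steps: (1) hits overlapping
microsatellites are dropped, (2) overlapping hits from the same family are
union-merged, (3) overlaps *across* families are resolved by prioritising
the longest insertion and iteratively truncating shorter ones (when a
truncation splits an insertion, the longest surviving fragment is kept),
and (4) anything shorter than 100 bp is discarded. After cleaning no two
insertions of different families overlap.

A binding peak is TE-derived either when at least half of it lies inside a
single insertion (half_overlap, the default) or when its summit falls
inside an insertion (center_in_te); both rules are in circulation and
reports name the one used.

Family enrichment uses a log2 odds ratio comparing non-DC-site density
within the family's annotated length to the genome-wide density:

    LOR = log2( (n_family / L_family) / (n_genome / G) )

with families at LOR >= 1.5 (roughly a 3-fold excess) called enriched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import Interval, overlap_length
from .turnover import Peak

__all__ = [
    "TEInsertion",
    "TEFamilyEnrichment",
    "clean_te_annotation",
    "te_derived_flag",
    "lor_enrichment",
    "motif_count",
    "read_repeatmasker_tsv",
]

MIN_INSERTION_LEN = 100
LOR_THRESHOLD = 1.5
TE_CLASSES = ("LTR", "Non-LTR", "DNA", "Unclassified")


@dataclass(frozen=True)
class TEInsertion:
    interval: Interval
    family: str
    te_class: str = "Unclassified"


def clean_te_annotation(
    raw_hits: Sequence[tuple[Interval, str, str]],
    microsatellites: Sequence[Interval] = (),
    min_len: int = MIN_INSERTION_LEN,
) -> list[TEInsertion]:
    """Apply the microsatellite / merge / truncate / length filters."""
    ms_trees: dict[str, IntervalTree] = {}
    for iv in microsatellites:
        ms_trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def touches_ms(iv: Interval) -> bool:
        t = ms_trees.get(iv.chrom)
        return bool(t and t.overlap(iv.start, iv.end))

    survivors = [(iv, fam, cls) for iv, fam, cls in raw_hits if not touches_ms(iv)]

    # Union-merge within (family, chromosome).
    merged: list[tuple[Interval, str, str]] = []
    by_key: dict[tuple[str, str], list[tuple[Interval, str]]] = {}
    for iv, fam, cls in survivors:
        by_key.setdefault((fam, iv.chrom), []).append((iv, cls))
    for (fam, chrom), items in by_key.items():
        items.sort(key=lambda t: (t[0].start, t[0].end))
        cur_s, cur_e = items[0][0].start, items[0][0].end
        cls = items[0][1]
        for iv, c in items[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append((Interval(chrom, cur_s, cur_e), fam, cls))
                cur_s, cur_e, cls = iv.start, iv.end, c
        merged.append((Interval(chrom, cur_s, cur_e), fam, cls))

    # Longest-first cross-family truncation. Accepted regions per chromosome
    # mask later (shorter) insertions; a split keeps the longest fragment.
    merged.sort(key=lambda t: (-t[0].length, t[0].chrom, t[0].start, t[1]))
    accepted: list[TEInsertion] = []
    occupied: dict[str, IntervalTree] = {}
    for iv, fam, cls in merged:
        tree = occupied.setdefault(iv.chrom, IntervalTree())
        holes = sorted(
            (max(iv.start, h.begin), min(iv.end, h.end))
            for h in tree.overlap(iv.start, iv.end)
        )
        fragments: list[tuple[int, int]] = []
        cursor = iv.start
        for hs, he in holes:
            if hs > cursor:
                fragments.append((cursor, hs))
            cursor = max(cursor, he)
        if cursor < iv.end:
            fragments.append((cursor, iv.end))
        if not fragments:
            continue
        fs, fe = max(fragments, key=lambda f: (f[1] - f[0], -f[0]))
        kept = Interval(iv.chrom, fs, fe)
        tree.addi(kept.start, kept.end)
        if kept.length >= min_len:
            accepted.append(TEInsertion(kept, fam, cls))
    accepted.sort(key=lambda t: (t.interval.chrom, t.interval.start))
    return accepted


def te_derived_flag(
    peak: Peak,
    insertions: Sequence[TEInsertion],
    rule: str = "half_overlap",
) -> tuple[bool, str | None]:
    """Is the peak TE-derived, and by which family?

    half_overlap: overlap with a *single* insertion covers >= half the
    peak. center_in_te: the peak summit (midpoint if no summit) lies in an
    insertion. Ties on overlap go to the largest overlap, then family name.
    """
    if rule not in ("half_overlap", "center_in_te"):
        raise ValueError(f"unknown TE-derived rule {rule!r}")
    best: tuple[int, str] | None = None
    for ins in insertions:
        if ins.interval.chrom != peak.interval.chrom:
            continue
        if rule == "half_overlap":
            ov = overlap_length(peak.interval, ins.interval)
            if ov * 2 >= peak.interval.length:
                if best is None or (ov, ins.family) > (best[0], best[1]):
                    best = (ov, ins.family)
        else:
            if ins.interval.contains_point(peak.summit):
                ov = overlap_length(peak.interval, ins.interval)
                if best is None or (ov, ins.family) > (best[0], best[1]):
                    best = (ov, ins.family)
    if best is None:
        return False, None
    return True, best[1]


@dataclass(frozen=True)
class TEFamilyEnrichment:
    family: str
    n_sites: int
    family_length: int
    lor: float
    enriched: bool


def lor_enrichment(
    n_sites_in_family: int,
    family_length_bp: int,
    n_sites_genome: int,
    genome_size_bp: int,
    family: str = "",
    threshold: float = LOR_THRESHOLD,
) -> TEFamilyEnrichment:
    """Log2 odds ratio of non-DC site density in a family vs genome-wide."""
    if genome_size_bp <= 0 or n_sites_genome <= 0:
        raise ValueError("genome density must be positive")
    if family_length_bp <= 0:
        return TEFamilyEnrichment(family, n_sites_in_family, family_length_bp, math.nan, False)
    if n_sites_in_family == 0:
        return TEFamilyEnrichment(family, 0, family_length_bp, -math.inf, False)
    lor = math.log2(
        (n_sites_in_family / family_length_bp) / (n_sites_genome / genome_size_bp)
    )
    return TEFamilyEnrichment(
        family, n_sites_in_family, family_length_bp, lor, lor >= threshold
    )


def family_enrichment_table(
    peaks: Sequence[Peak],
    insertions: Sequence[TEInsertion],
    genome_size_bp: int,
    rule: str = "half_overlap",
    threshold: float = LOR_THRESHOLD,
) -> pd.DataFrame:
    """Per-family enrichment of (non-DC) peaks, computed from the cleaned
    annotation: family lengths from the annotation itself, site counts from
    the TE-derived rule."""
    fam_len: dict[str, int] = {}
    fam_class: dict[str, str] = {}
    for ins in insertions:
        fam_len[ins.family] = fam_len.get(ins.family, 0) + ins.interval.length
        fam_class.setdefault(ins.family, ins.te_class)
    fam_sites: dict[str, int] = {f: 0 for f in fam_len}
    for peak in peaks:
        hit, fam = te_derived_flag(peak, insertions, rule)
        if hit:
            fam_sites[fam] += 1
    rows = []
    for fam in sorted(fam_len):
        enr = lor_enrichment(
            fam_sites[fam], fam_len[fam], len(peaks), genome_size_bp, fam, threshold
        )
        rows.append(
            {
                "family": fam,
                "te_class": fam_class[fam],
                "n_sites": enr.n_sites,
                "family_length": enr.family_length,
                "lor": enr.lor,
                "enriched": enr.enriched,
            }
        )
    return pd.DataFrame(rows).sort_values("lor", ascending=False).reset_index(drop=True)


def motif_count(consensus_sequence: str, motifs: Sequence[str]) -> dict[str, int]:
    """Exact, overlapping motif occurrences on forward plus reverse-
    complement strands, deduplicated per position.

    A simplified occurrence counter standing in for a p-value-based motif
    scanner: palindromic hits are not double-counted because matches are
    keyed by forward-strand position.
    """
    seq = consensus_sequence.upper()
    out: dict[str, int] = {}
    for motif in motifs:
        m = motif.upper()
        rc = m.translate(_RC)[::-1]
        hits: set[int] = set()
        for pat in {m, rc}:
            start = 0
            while True:
                i = seq.find(pat, start)
                if i < 0:
                    break
                hits.add(i)
                start = i + 1
        out[motif] = len(hits)
    return out


_RC = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# I/O

_RM_COLS = ["chrom", "start", "end", "family", "te_class"]


def read_repeatmasker_tsv(path) -> list[tuple[Interval, str, str]]:
    """Read the cleaned-down repeat annotation dialect
    (chrom, start, end, family, class)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_RM_COLS, dtype={"chrom": str})
    return [
        (Interval(str(r.chrom), int(r.start), int(r.end)), str(r.family), str(r.te_class))
        for r in df.itertuples(index=False)
    ]


def write_insertions_bed(insertions: Sequence[TEInsertion], path) -> None:
    with open(path, "w") as fh:
        for ins in insertions:
            fh.write(
                f"{ins.interval.chrom}\t{ins.interval.start}\t{ins.interval.end}"
                f"\t{ins.family}\t0\t.\n"
            )
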