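"""Extended McDonald–Kreitman selection inference for binding-site classes.

The MK framework contrasts between-species divergence (D) with within-
species polymorphism (P) in a putatively selected site class against a
neutral reference — genome-wide four-fold degenerate third codon
positions. An excess of divergence in the selected class signals adaptive
fixation; the fraction of adaptive fixations is

    alpha = 1 - (D_neutral * P_selected) / (D_selected * P_neutral)

with singleton polymorphisms (minor allele count exactly 1) excluded from
both P terms to limit the downward bias from segregating weakly
deleterious variants. alpha <= 1 always; negative values indicate an
excess of polymorphism relative to divergence (weakly deleterious
segregation or, for bottlenecked populations, excess intermediate-
frequency variants). X-linked site classes are paired with X-linked
four-fold sites and autosomal classes with autosomal four-fold sites,
because the two chromosome classes experience different effective
population sizes and selective regimes.

Per-gene MK tests contrast non-synonymous/synonymous divergence and
polymorphism in a 2x2 Fisher's exact test with Benjamini-Hochberg
correction across genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import Interval, total_length

__all__ = [
    "VariantSite",
    "SiteClassCounts",
    "MKResult",
    "GeneMKRecord",
    "classify_variant",
    "tabulate",
    "dp_ratio",
    "mk_alpha",
    "mk_fisher",
    "mk_test",
    "gene_mk",
    "fourfold_sites",
    "read_variant_table",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantSite:
    """One genomic site: ingroup allele counts plus the outgroup base."""

    chrom: str
    pos: int  # 0-based
    ingroup_alleles: Mapping[str, int]
    outgroup_allele: str | None = None

    def __post_init__(self) -> None:
        if not self.ingroup_alleles or sum(self.ingroup_alleles.values()) <= 0:
            raise ValueError("ingroup sample must be non-empty")
        bad = set(self.ingroup_alleles) - _BASES
        if bad:
            raise ValueError(f"non-ACGT ingroup alleles {bad}")


def classify_variant(site: VariantSite) -> str:
    """Classify a site for MK accounting.

    Returns one of ``monomorphic_identical``, ``divergent``,
    ``polymorphic``, ``polymorphic_singleton``, ``unusable``.
    A site is divergent only when fixed in the ingroup and different from
    the outgroup (D and P stay disjoint); a singleton is a polymorphic
    site whose minor allele is carried by exactly one sampled chromosome.
    """
    if site.outgroup_allele is None or site.outgroup_allele not in _BASES:
        return "unusable"
    alleles = {a: n for a, n in site.ingroup_alleles.items() if n > 0}
    if len(alleles) == 1:
        (allele,) = alleles
        return "monomorphic_identical" if allele == site.outgroup_allele else "divergent"
    if len(alleles) > 2:
        warnings.warn(
            f"{site.chrom}:{site.pos} has {len(alleles)} ingroup alleles; "
            "counted once as polymorphic",
            stacklevel=2,
        )
        return "polymorphic"
    minor = min(alleles.values())
    return "polymorphic_singleton" if minor == 1 else "polymorphic"


@dataclass
class SiteClassCounts:
    """The MK test's entire input for one site class."""

    label: str
    L: int  # class length in bp
    D: int = 0  # divergent sites
    P: int = 0  # polymorphic sites incl. singletons
    P_nosingleton: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("class length must be > 0")
        if not (0 <= self.P_nosingleton <= self.P):
            raise ValueError("need 0 <= P_nosingleton <= P")
        if self.D < 0:
            raise ValueError("D must be >= 0")


def tabulate(
    sites: Iterable[VariantSite],
    class_intervals: Mapping[str, Sequence[Interval]],
) -> dict[str, SiteClassCounts]:
    """Count divergent/polymorphic/singleton sites per labelled class.

    ``class_intervals`` maps a label to its (within-label disjoint)
    interval set; L is the total bp of the class. A site falling in no
    class is ignored; a site may belong to several labels (classes such
    as "all sites" and "X-linked sites" legitimately nest).
    """
    trees: dict[str, dict[str, IntervalTree]] = {}
    counts: dict[str, SiteClassCounts] = {}
    for label, ivs in class_intervals.items():
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in per_chrom.items():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"class {label!r} has overlapping intervals on {chrom}"
                    )
        trees[label] = {
            chrom: IntervalTree.from_tuples(spans) for chrom, spans in per_chrom.items()
        }
        counts[label] = SiteClassCounts(label, L=total_length(ivs))

    for site in sites:
        kind = classify_variant(site)
        if kind in ("unusable", "monomorphic_identical"):
            continue
        for label, per_chrom in trees.items():
            tree = per_chrom.get(site.chrom)
            if tree is None or not tree.overlaps_point(site.pos):
                continue
            c = counts[label]
            if kind == "divergent":
                c.D += 1
            elif kind == "polymorphic":
                c.P += 1
                c.P_nosingleton += 1
            else:  # polymorphic_singleton
                c.P += 1
    return counts


def dp_ratio(c: SiteClassCounts) -> float:
    """D / P(-singleton); infinite when the class has divergence but no
    retained polymorphism, NaN when both are zero."""
    if c.P_nosingleton == 0:
        return math.nan if c.D == 0 else math.inf
    return c.D / c.P_nosingleton


def mk_alpha(selected: SiteClassCounts, neutral: SiteClassCounts) -> float:
    """Fraction of adaptive fixations in the selected class.

    alpha = 1 - (D_neut * P_sel) / (D_sel * P_neut), singleton-excluded
    polymorphism counts on both sides. NaN when any required count is 0.
    """
    if min(selected.D, selected.P_nosingleton, neutral.D, neutral.P_nosingleton) <= 0:
        return math.nan
    return 1.0 - (neutral.D * selected.P_nosingleton) / (
        selected.D * neutral.P_nosingleton
    )


def mk_fisher(
    selected: SiteClassCounts,
    neutral: SiteClassCounts,
    use_singletons: bool = False,
) -> float:
    """Two-sided Fisher's exact p on [[D_sel, P_sel], [D_neut, P_neut]]."""
    p_sel = selected.P if use_singletons else selected.P_nosingleton
    p_neut = neutral.P if use_singletons else neutral.P_nosingleton
    table = [[selected.D, p_sel], [neutral.D, p_neut]]
    if sum(selected_row := table[0]) + sum(table[1]) == 0:
        return math.nan
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class MKResult:
    label: str
    dp_ratio: float
    alpha: float
    fisher_p: float


def mk_test(selected: SiteClassCounts, neutral: SiteClassCounts) -> MKResult:
    """Bundle D/P ratio, alpha and the Fisher p-value for one class pair."""
    return MKResult(
        selected.label,
        dp_ratio(selected),
        mk_alpha(selected, neutral),
        mk_fisher(selected, neutral),
    )


# ---------------------------------------------------------------------------
# Per-gene MK with Benjamini-Hochberg correction


@dataclass(frozen=True)
class GeneMKRecord:
    gene: str
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    fisher_p: float
    bh_q: float
    excess: bool  # non-synonymous divergence excess at the BH threshold


def gene_mk(
    records: Mapping[str, tuple[int, int, int, int]],
    q_threshold: float = 0.05,
) -> list[GeneMKRecord]:
    """Per-gene MK tests: Fisher on [[Dn, Pn], [Ds, Ps]] per gene, BH across
    genes, and an excess flag when Dn/Ds exceeds Pn/Ps at q below threshold.

    ``records`` maps gene id -> (Dn, Ds, Pn, Ps). All-zero genes get NaN
    p and q and never flag.
    """
    genes = list(records)
    pvals: list[float] = []
    testable: list[bool] = []
    for g in genes:
        dn, ds, pn, ps = records[g]
        if min(dn, ds, pn, ps) < 0:
            raise ValueError(f"negative count for gene {g}")
        if dn + ds + pn + ps == 0:
            pvals.append(math.nan)
            testable.append(False)
        else:
            pvals.append(float(stats.fisher_exact([[dn, pn], [ds, ps]])[1]))
            testable.append(True)
    qvals = [math.nan] * len(genes)
    idx = [i for i, t in enumerate(testable) if t]
    if idx:
        _, q, _, _ = multipletests([pvals[i] for i in idx], method="fdr_bh")
        for i, qi in zip(idx, q):
            qvals[i] = float(qi)
    out: list[GeneMKRecord] = []
    for i, g in enumerate(genes):
        dn, ds, pn, ps = records[g]
        excess = False
        if testable[i] and qvals[i] < q_threshold and ds > 0 and ps > 0:
            excess = (dn / ds) > (pn / ps)
        out.append(GeneMKRecord(g, dn, ds, pn, ps, pvals[i], qvals[i], excess))
    return out


# ---------------------------------------------------------------------------
# Four-fold degenerate site extraction

# Codon prefixes whose third position is fully degenerate under the
# standard nuclear code (verified against Bio.Data.CodonTable in tests).
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def fourfold_sites(
    gene_models: Iterable["GeneModel"],
    genome: Mapping[str, str],
) -> set[tuple[str, int]]:
    """Genome coordinates of four-fold degenerate third codon positions.

    ``gene_models`` supply strand-aware CDS segments; codons are read in
    transcript order (reverse-complemented on minus-strand genes). Genes
    whose CDS length is not a multiple of 3 are skipped with a warning;
    codons containing ambiguity codes are skipped.
    """
    result: set[tuple[str, int]] = set()
    for gene in gene_models:
        segs = sorted(gene.cds, key=lambda iv: iv.start)
        cds_len = sum(iv.length for iv in segs)
        if cds_len % 3 != 0:
            warnings.warn(
                f"gene {gene.gene_id}: CDS length {cds_len} not divisible by 3; skipped",
                stacklevel=2,
            )
            continue
        # Genome positions in transcript (5'->3') order.
        positions: list[tuple[str, int]] = []
        for iv in segs:
            positions.extend((iv.chrom, p) for p in range(iv.start, iv.end))
        seq = "".join(genome[c][p].upper() for c, p in positions)
        if gene.strand == "-":
            positions = positions[::-1]
            seq = seq[::-1].translate(_COMPLEMENT)
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if any(b not in "ACGT" for b in codon):
                continue
            if codon[:2] in FOURFOLD_PREFIXES:
                result.add(positions[i + 2])
    return result


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: strand plus CDS segments (genome coordinates)."""

    gene_id: str
    strand: str
    cds: tuple[Interval, ...]
    span: Interval | None = None  # whole transcript span incl. UTRs/introns

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3: one gene per ``gene`` feature, CDS rows
    attached by the Parent/ID hierarchy flattened to the gene id."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs"]
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=cols, dtype={"seqid": str}
    )

    def attr(s: str, key: str) -> str | None:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return None

    genes: dict[str, dict] = {}
    parent_of: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.type == "gene":
            gid = attr(row.attrs, "ID")
            genes[gid] = {
                "strand": row.strand,
                "span": Interval(row.seqid, int(row.start) - 1, int(row.end)),
                "cds": [],
            }
        elif row.type in ("mRNA", "transcript"):
            parent_of[attr(row.attrs, "ID")] = attr(row.attrs, "Parent")
    for row in df.itertuples(index=False):
        if row.type != "CDS":
            continue
        parent = attr(row.attrs, "Parent")
        gid = parent_of.get(parent, parent)
        if gid in genes:
            genes[gid]["cds"].append(Interval(row.seqid, int(row.start) - 1, int(row.end)))
    return [
        GeneModel(gid, g["strand"], tuple(g["cds"]), g["span"])
        for gid, g in genes.items()
    ]


# ---------------------------------------------------------------------------
# Variant table I/O (VCF-like TSV dialect)

_VARIANT_COLS = ["chrom", "pos", "allele_counts", "outgroup"]


def read_variant_table(path) -> list[VariantSite]:
    """Read the artifact's variant dialect: chrom, 0-based pos, ingroup
    allele counts as ``A:12,C:3``, outgroup base ('.' for missing)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=_VARIANT_COLS,
                     dtype={"chrom": str, "outgroup": str})
    sites: list[VariantSite] = []
    for row in df.itertuples(index=False):
        alleles = {}
        for part in str(row.allele_counts).split(","):
            base, n = part.split(":")
            alleles[base] = int(n)
        out = None if row.outgroup in (".", "", None) or pd.isna(row.outgroup) else str(row.outgroup)
        sites.append(VariantSite(str(row.chrom), int(row.pos), alleles, out))
    return sites


def write_variant_table(sites: Sequence[VariantSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tallele_counts\toutgroup\n")
        for s in sites:
            counts = ",".join(f"{a}:{n}" for a, n in sorted(s.ingroup_alleles.items()))
            fh.write(f"{s.chrom}\t{s.pos}\t{counts}\t{s.outgroup_allele or '.'}\n")


def mk_report(
    pairs: Sequence[tuple[SiteClassCounts, SiteClassCounts]],
) -> pd.DataFrame:
    """Table-style report: one row per (selected, neutral) class pair."""
    rows = []
    for sel, neut in pairs:
        res = mk_test(sel, neut)
        rows.append(
            {
                "class": sel.label,
                "neutral": neut.label,
                "L": sel.L,
                "D": sel.D,
                "P": sel.P,
                "P_nosingleton": sel.P_nosingleton,
                "dp_ratio": round(res.dp_ratio, 3) if math.isfinite(res.dp_ratio) else res.dp_ratio,
                "alpha": round(res.alpha, 3) if math.isfinite(res.alpha) else res.alpha,
                "fisher_p": res.fisher_p,
            }
        )
    return pd.DataFrame(rows)
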