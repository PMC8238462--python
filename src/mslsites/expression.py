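"""Gene grouping by binding-site/TE status and expression divergence.

Genes are grouped by whether a non-DC MOF/MSL1 binding site lies within
2 kb upstream of the transcription start or anywhere in the gene body
(BS+ split into conserved/unconserved by the site's cross-species
conservation call; otherwise BS-), and independently by TE presence in
the same window (TE+/TE-). Expression divergence of a group is

    1 - rho,  rho = Spearman rank correlation between the two species'
              replicate-averaged TPM vectors over the group's genes,

in [0, 2]; its sampling distribution is estimated by bootstrap over genes
(default 1,000 draws) and groups are compared by a two-sided Mann-Whitney
U on the bootstrap distributions. Bootstrap draws are not independent
observations, so these p-values describe separation of the resampling
distributions rather than a calibrated test — the procedure is kept
because it is the one in common use for this statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Interval, overlap_length
from .te import TEInsertion
from .turnover import ConservationCall

__all__ = [
    "GeneGroup",
    "DivergenceEstimate",
    "average_tpm",
    "normalize_z",
    "group_genes",
    "divergence",
    "compare_groups",
    "read_expression_table",
]

UPSTREAM_WINDOW = 2000
DEFAULT_BOOTSTRAP = 1000


def average_tpm(records: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per gene x species x sex across biological replicates.

    Expects columns gene, species, sex, tpm (one row per replicate).
    Genes absent from one species are excluded from the orthologous set.
    """
    need = {"gene", "species", "sex", "tpm"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    if (records["tpm"] < 0).any():
        raise ValueError("TPM must be >= 0")
    mean = (
        records.groupby(["gene", "species", "sex"])["tpm"].mean().rename("tpm").reset_index()
    )
    n_species = records["species"].nunique()
    per_gene = mean.groupby("gene")["species"].nunique()
    incomplete = per_gene.index[per_gene < n_species]
    if len(incomplete):
        import warnings

        warnings.warn(
            f"{len(incomplete)} genes missing from one species; excluded",
            stacklevel=2,
        )
        mean = mean[~mean["gene"].isin(incomplete)]
    return mean


def normalize_z(tpm_vector: np.ndarray, ddof: int = 1) -> np.ndarray:
    """(x - mean)/sd over the within-species gene vector (sample sd)."""
    x = np.asarray(tpm_vector, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 genes to normalize")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("zero standard deviation: constant expression vector")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class GeneGroup:
    gene: str
    bs_status: str  # BSminus | conservedBSplus | unconservedBSplus
    te_status: str  # TEplus | TEminus


def gene_window(span: Interval, strand: str, upstream: int = UPSTREAM_WINDOW) -> Interval:
    """Gene body plus ``upstream`` bp on the 5' side (strand-aware)."""
    if strand == "+":
        return Interval(span.chrom, max(0, span.start - upstream), span.end)
    if strand == "-":
        return Interval(span.chrom, span.start, span.end + upstream)
    raise ValueError(f"gene window needs a strand, got {strand!r}")


def group_genes(
    genes: Mapping[str, tuple[Interval, str]],
    nondc_calls: Sequence[ConservationCall],
    insertions: Sequence[TEInsertion] = (),
    upstream: int = UPSTREAM_WINDOW,
) -> list[GeneGroup]:
    """Assign BS/TE status per gene.

    ``genes`` maps gene id -> (transcript span, strand). A gene is
    unconservedBSplus if any unconserved non-DC site overlaps its window
    by >= 1 bp (any overlap; the criterion is presence, not an overlap
    fraction), else conservedBSplus if a conserved site does, else
    BSminus. TEplus iff any cleaned insertion overlaps the window.
    """
    out: list[GeneGroup] = []
    for gene, (span, strand) in genes.items():
        win = gene_window(span, strand, upstream)
        bs = "BSminus"
        conserved_hit = False
        for call in nondc_calls:
            if overlap_length(win, call.peak.interval) > 0:
                if call.status == "unconserved":
                    bs = "unconservedBSplus"
                    break
                conserved_hit = True
        if bs == "BSminus" and conserved_hit:
            bs = "conservedBSplus"
        te = "TEminus"
        for ins in insertions:
            if overlap_length(win, ins.interval) > 0:
                te = "TEplus"
                break
        out.append(GeneGroup(gene, bs, te))
    return out


@dataclass
class DivergenceEstimate:
    group: str
    point: float  # 1 - Spearman rho
    bootstrap: np.ndarray
    n_genes: int


def _one_minus_rho(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return 1.0 - float(rho)


def divergence(
    tpm_a: np.ndarray,
    tpm_b: np.ndarray,
    group: str = "",
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    rng: np.random.Generator | int | None = None,
) -> DivergenceEstimate | None:
    """1 - Spearman rho between two species' mean-TPM vectors over a gene
    group, with a bootstrap-over-genes distribution. None for groups of
    fewer than 3 genes."""
    x = np.asarray(tpm_a, dtype=float)
    y = np.asarray(tpm_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("species TPM vectors must align gene-for-gene")
    n = x.size
    if n < 3:
        return None
    point = _one_minus_rho(x, y)
    gen = np.random.default_rng(rng)
    idx = gen.integers(0, n, size=(n_bootstrap, n))
    bx, by = x[idx], y[idx]
    # Vectorised Spearman: rank within each draw, then Pearson on ranks.
    rx = stats.rankdata(bx, axis=1)
    ry = stats.rankdata(by, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=1) / denom
    boot = 1.0 - rho
    return DivergenceEstimate(group, point, boot, n)


def compare_groups(a: DivergenceEstimate, b: DivergenceEstimate) -> float:
    """Two-sided Mann-Whitney U p-value on two bootstrap distributions."""
    return float(stats.mannwhitneyu(a.bootstrap, b.bootstrap, alternative="two-sided")[1])


def read_expression_table(path) -> pd.DataFrame:
    """Read the expression dialect: gene, species, sex, replicate, tpm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene", "species", "sex", "replicate", "tpm"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
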