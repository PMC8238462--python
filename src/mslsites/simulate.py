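"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the shape of the study system — two closely related
fly genomes linked by collinear one-to-one ortholog blocks, ChIP
fold-enrichment peaks for three MSL proteins with MSL2 concentrated on the
X, a fraction of species-specific peak gains, repeat families with
controlled binding-site enrichment, per-site polymorphism/divergence
classes with a chosen true fraction of adaptive fixations, and
replicate-level expression tables with group-wise divergence effects. It
makes no attempt at sequence-level realism (no coalescent, no indels, no
motif content); what it guarantees is that every file parses through the
package readers and that every planted label is recoverable, so estimator
behaviour can be checked against truth.

Randomness: one integer seed drives named substreams (one per generator),
so adding a generator never perturbs the draws of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Interval
from .mk import SiteClassCounts, VariantSite, write_variant_table
from .orthomap import OrthologBlock, OrthologMap, write_map
from .te import TEInsertion
from .turnover import Peak, SignalTrack

__all__ = [
    "SimConfig",
    "substream",
    "simulate_genomes",
    "simulate_peaks_and_signal",
    "simulate_variants",
    "simulate_mk_counts",
    "simulate_expression",
    "write_dataset",
]

# Per-class variant densities matching the scale of genome-wide fly data:
# divergence ~0.16/bp to the outgroup, singleton-excluded polymorphism
# ~0.087/bp, singletons ~0.022/bp in a ~200-line sample.
NEUTRAL_D_DENSITY = 0.161
NEUTRAL_P_DENSITY = 0.087
SINGLETON_DENSITY = 0.022


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named substream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(name.encode())])
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic two-species system."""

    seed: int = 0
    chrom_names: tuple[str, ...] = ("X", "2L", "2R", "3L", "3R")
    chrom_length: int = 1_000_000
    map_coverage: float = 0.9  # fraction of each chromosome in ortholog blocks
    block_length: int = 20_000
    n_peaks: dict[str, int] = field(
        default_factory=lambda: {"MOF": 800, "MSL1": 800, "MSL2": 400}
    )
    gain_fraction: float = 0.10  # species-specific peaks in the focal species
    msl2_x_fraction: float = 0.97
    dc_fraction: float = 0.3  # MOF/MSL1 peaks planted on MSL2 regions
    peak_length: tuple[int, int] = (200, 800)
    signal_range: tuple[float, float] = (5.0, 50.0)
    te_n_families: int = 10
    te_insertions_per_family: int = 40
    te_insertion_length: tuple[int, int] = (300, 3000)
    te_enriched_family: str = "FAM_ENRICHED"
    te_enrichment_factor: float = 8.0
    variant_sample_size: int = 197
    singleton_density: float = SINGLETON_DENSITY
    n_genes: int = 1500
    n_replicates: int = 2
    group_rank_sd: dict[str, float] = field(
        default_factory=lambda: {
            "unconservedBSplus": 0.8,
            "BSminus": 0.4,
            "conservedBSplus": 0.15,
        }
    )
    replicate_sd: float = 0.1


# ---------------------------------------------------------------------------
# Genomes and ortholog map


@dataclass
class GenomePair:
    chrom_lengths_a: dict[str, int]
    chrom_lengths_b: dict[str, int]
    sequences_a: dict[str, str]
    sequences_b: dict[str, str]
    ortho_map: OrthologMap  # A -> B


def simulate_genomes(cfg: SimConfig, with_sequence: bool = True) -> GenomePair:
    """Two collinear coordinate systems joined by alternating ortholog
    blocks covering ``map_coverage`` of each chromosome."""
    rng = substream(cfg.seed, "genomes")
    blocks: list[OrthologBlock] = []
    len_a = {c: cfg.chrom_length for c in cfg.chrom_names}
    len_b = {c: cfg.chrom_length for c in cfg.chrom_names}
    for chrom in cfg.chrom_names:
        if cfg.map_coverage <= 0:
            continue
        period = int(cfg.block_length / cfg.map_coverage)
        pos = 0
        while pos + cfg.block_length <= cfg.chrom_length:
            src = Interval(chrom, pos, pos + cfg.block_length)
            dst = Interval(chrom, pos, pos + cfg.block_length)
            blocks.append(OrthologBlock(src, dst, "+"))
            pos += max(period, cfg.block_length)

    seqs_a: dict[str, str] = {}
    seqs_b: dict[str, str] = {}
    if with_sequence:
        bases = np.array(list("ACGT"))
        for chrom in cfg.chrom_names:
            seqs_a[chrom] = "".join(bases[rng.integers(0, 4, size=len_a[chrom])])
            seqs_b[chrom] = "".join(bases[rng.integers(0, 4, size=len_b[chrom])])
    return GenomePair(len_a, len_b, seqs_a, seqs_b, OrthologMap(blocks))


# ---------------------------------------------------------------------------
# Peaks and signal tracks


@dataclass
class PeakSim:
    peaks_a: dict[str, list[Peak]]  # protein -> peaks in species A
    peaks_b: dict[str, list[Peak]]
    tracks_a: dict[str, SignalTrack]  # protein -> fold-enrichment track
    tracks_b: dict[str, SignalTrack]
    truth: pd.DataFrame  # name, protein, species, conserved, dc, chrom


def _mappable_starts(genomes: GenomePair, chrom: str, length: int) -> list[tuple[int, OrthologBlock]]:
    out = []
    for blk in genomes.ortho_map.blocks:
        if blk.src.chrom == chrom and blk.src.length >= length:
            out.append((blk.src.start, blk))
    return out


def simulate_peaks_and_signal(cfg: SimConfig, genomes: GenomePair) -> PeakSim:
    """Plant peaks with known conservation/DC labels and matching signal.

    Shared peaks appear in both species (partner signal well above the
    10-fold absence boundary); species-specific gains appear only in the
    focal species A with partner signal strictly below own/10. MSL2 peaks
    concentrate on the X; a configured fraction of MOF/MSL1 peaks is
    planted on top of MSL2 regions (DC truth), the rest away from them.
    """
    rng = substream(cfg.seed, "peaks")
    lo_len, hi_len = cfg.peak_length
    lo_fe, hi_fe = cfg.signal_range
    peaks_a: dict[str, list[Peak]] = {p: [] for p in cfg.n_peaks}
    peaks_b: dict[str, list[Peak]] = {p: [] for p in cfg.n_peaks}
    segs_a: dict[str, list[tuple[str, int, int, float]]] = {p: [] for p in cfg.n_peaks}
    segs_b: dict[str, list[tuple[str, int, int, float]]] = {p: [] for p in cfg.n_peaks}
    truth_rows = []
    msl2_regions: list[Interval] = []

    # Lay peaks on a coarse grid inside ortholog blocks so they never
    # collide; grid pitch leaves room for the half-length search window.
    pitch = 4 * hi_len
    slots: dict[str, list[tuple[Interval, OrthologBlock]]] = {c: [] for c in cfg.chrom_names}
    for blk in genomes.ortho_map.blocks:
        start = blk.src.start + hi_len
        while start + hi_len < blk.src.end - hi_len:
            slots[blk.src.chrom].append((Interval(blk.src.chrom, start, start + hi_len), blk))
            start += pitch
    for c in slots:
        rng.shuffle(slots[c])

    def take_slot(chrom: str) -> tuple[Interval, OrthologBlock] | None:
        return slots[chrom].pop() if slots[chrom] else None

    order = ["MSL2"] + [p for p in cfg.n_peaks if p != "MSL2"]
    for protein in order:
        n = cfg.n_peaks[protein]
        for i in range(n):
            if protein == "MSL2":
                on_x = rng.random() < cfg.msl2_x_fraction
                x_name = "X" if "X" in cfg.chrom_names else cfg.chrom_names[0]
                autosome_names = [c for c in cfg.chrom_names if c != x_name] or [x_name]
                chrom = x_name if on_x else str(rng.choice(autosome_names))
            else:
                chrom = str(rng.choice(cfg.chrom_names))
            is_dc = protein != "MSL2" and rng.random() < cfg.dc_fraction and msl2_regions
            if is_dc:
                # Reuse an MSL2 region so the reciprocal-half test holds.
                base = msl2_regions[int(rng.integers(0, len(msl2_regions)))]
                iv = base
                blk = None
                for b in genomes.ortho_map.blocks:
                    if b.src.chrom == iv.chrom and b.src.start <= iv.start and iv.end <= b.src.end:
                        blk = b
                        break
                if blk is None:
                    continue
            else:
                slot = take_slot(chrom)
                if slot is None:
                    continue
                anchor, blk = slot
                length = int(rng.integers(lo_len, hi_len + 1))
                iv = Interval(anchor.chrom, anchor.start, anchor.start + length)
            own_fe = float(rng.uniform(lo_fe, hi_fe))
            gained = protein != "MSL2" and rng.random() < cfg.gain_fraction and not is_dc
            name = f"{protein}_A_{i}"
            summit = iv.midpoint
            peaks_a[protein].append(Peak(iv, summit, protein, "A", own_fe, name))
            segs_a[protein].append((iv.chrom, iv.start, iv.end, own_fe))
            dst = blk.map_interval(iv.start, iv.end)
            if gained:
                other_fe = float(rng.uniform(0.0, own_fe / 10 * 0.5))
                if other_fe > 0:
                    segs_b[protein].append((dst.chrom, dst.start, dst.end, other_fe))
            else:
                other_fe = float(rng.uniform(own_fe / 10 * 2.0, hi_fe * 1.2))
                segs_b[protein].append((dst.chrom, dst.start, dst.end, other_fe))
                peaks_b[protein].append(
                    Peak(dst, dst.midpoint, protein, "B", other_fe, f"{protein}_B_{i}")
                )
            if protein == "MSL2" and not gained:
                msl2_regions.append(iv)
            truth_rows.append(
                {
                    "name": name,
                    "protein": protein,
                    "species": "A",
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "gained": gained,
                    "conserved": not gained,
                    "dc": bool(is_dc),
                }
            )
    tracks_a = {p: SignalTrack(_merge_segments(segs_a[p])) for p in segs_a}
    tracks_b = {p: SignalTrack(_merge_segments(segs_b[p])) for p in segs_b}
    return PeakSim(peaks_a, peaks_b, tracks_a, tracks_b, pd.DataFrame(truth_rows))


def _merge_segments(
    segs: list[tuple[str, int, int, float]]
) -> list[tuple[str, int, int, float]]:
    """Resolve accidental overlaps (DC peaks share MSL2 coordinates) by
    keeping the maximum value on the shared span."""
    out: list[tuple[str, int, int, float]] = []
    for chrom in sorted({s[0] for s in segs}):
        rows = sorted(s for s in segs if s[0] == chrom)
        cur = None
        for _, s, e, v in rows:
            if cur is None:
                cur = [s, e, v]
            elif s < cur[1]:
                cur[1] = max(cur[1], e)
                cur[2] = max(cur[2], v)
            else:
                out.append((chrom, cur[0], cur[1], cur[2]))
                cur = [s, e, v]
        if cur is not None:
            out.append((chrom, cur[0], cur[1], cur[2]))
    return out


# ---------------------------------------------------------------------------
# Variant sites with a chosen true alpha


def expected_selected_d(
    true_alpha: float,
    expected_p_sel: float,
    d_neut_density: float = NEUTRAL_D_DENSITY,
    p_neut_density: float = NEUTRAL_P_DENSITY,
) -> float:
    """Selected-class divergence mean that realises ``true_alpha``:
    D_sel = (D_neut/P_neut) * P_sel / (1 - alpha)."""
    if true_alpha >= 1:
        raise ValueError("true alpha must be < 1")
    return (d_neut_density / p_neut_density) * expected_p_sel / (1.0 - true_alpha)


def simulate_mk_counts(
    rng: np.random.Generator,
    true_alpha: float,
    l_selected: int,
    l_neutral: int,
    d_neut_density: float = NEUTRAL_D_DENSITY,
    p_neut_density: float = NEUTRAL_P_DENSITY,
    p_sel_density: float | None = None,
    singleton_density: float = SINGLETON_DENSITY,
    label: str = "selected",
) -> tuple[SiteClassCounts, SiteClassCounts]:
    """Poisson per-class counts at a chosen true alpha (no per-site records).

    The fast path for replicated estimator-recovery studies at realistic
    class lengths; `simulate_variants` emits the equivalent explicit site
    stream for end-to-end runs at smaller scale.
    """
    p_sel_density = p_neut_density if p_sel_density is None else p_sel_density
    p_sel = int(rng.poisson(p_sel_density * l_selected))
    d_sel = int(rng.poisson(expected_selected_d(true_alpha, p_sel_density * l_selected,
                                                d_neut_density, p_neut_density)))
    p_neut = int(rng.poisson(p_neut_density * l_neutral))
    d_neut = int(rng.poisson(d_neut_density * l_neutral))
    s_sel = int(rng.poisson(singleton_density * l_selected))
    s_neut = int(rng.poisson(singleton_density * l_neutral))
    sel = SiteClassCounts(label, l_selected, d_sel, p_sel + s_sel, p_sel)
    neut = SiteClassCounts("neutral", l_neutral, d_neut, p_neut + s_neut, p_neut)
    return sel, neut


def simulate_variants(
    cfg: SimConfig,
    class_intervals: Mapping[str, Sequence[Interval]],
    true_alpha: Mapping[str, float],
    neutral_label: str = "neutral",
    d_neut_density: float = NEUTRAL_D_DENSITY,
    p_neut_density: float = NEUTRAL_P_DENSITY,
) -> list[VariantSite]:
    """Explicit variant-site stream with a planted alpha per selected class.

    Classes must be disjoint across labels here (each site carries one
    truth class). The neutral class uses the configured densities; each
    selected class gets the same polymorphism density and a divergence
    density solving the alpha identity.
    """
    rng = substream(cfg.seed, "variants")
    n_sample = cfg.variant_sample_size
    sites: list[VariantSite] = []
    for label, ivs in class_intervals.items():
        length = sum(iv.length for iv in ivs)
        if label == neutral_label:
            d_mean = d_neut_density * length
        else:
            alpha = true_alpha[label]
            d_mean = expected_selected_d(
                alpha, p_neut_density * length, d_neut_density, p_neut_density
            )
        n_d = int(rng.poisson(d_mean))
        n_p = int(rng.poisson(p_neut_density * length))
        n_s = int(rng.poisson(cfg.singleton_density * length))
        total = n_d + n_p + n_s
        if total == 0:
            continue
        offsets = rng.choice(length, size=min(total, length), replace=False)
        positions = _offsets_to_positions(ivs, offsets)
        kinds = ["D"] * n_d + ["P"] * n_p + ["S"] * n_s
        for (chrom, pos), kind in zip(positions, kinds):
            b1, b2 = rng.choice(4, size=2, replace=False)
            base1, base2 = "ACGT"[b1], "ACGT"[b2]
            if kind == "D":
                sites.append(VariantSite(chrom, pos, {base1: n_sample}, base2))
            elif kind == "P":
                minor = int(rng.integers(2, max(3, n_sample // 2)))
                sites.append(
                    VariantSite(chrom, pos, {base1: n_sample - minor, base2: minor}, base1)
                )
            else:
                sites.append(
                    VariantSite(chrom, pos, {base1: n_sample - 1, base2: 1}, base1)
                )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


def _offsets_to_positions(
    ivs: Sequence[Interval], offsets: np.ndarray
) -> list[tuple[str, int]]:
    bounds = np.cumsum([iv.length for iv in ivs])
    out = []
    for off in offsets:
        k = int(np.searchsorted(bounds, off, side="right"))
        prev = 0 if k == 0 else int(bounds[k - 1])
        out.append((ivs[k].chrom, ivs[k].start + int(off) - prev))
    return out


# ---------------------------------------------------------------------------
# Repeat annotation with a planted enriched family


@dataclass
class TESim:
    insertions: list[TEInsertion]
    truth_enriched: str


def simulate_te_annotation(cfg: SimConfig, genomes: GenomePair) -> TESim:
    """Non-overlapping insertions for ``te_n_families`` families (already
    clean); one designated family is the enrichment target for peak
    planting elsewhere."""
    rng = substream(cfg.seed, "te")
    lo, hi = cfg.te_insertion_length
    families = [cfg.te_enriched_family] + [f"FAM{i}" for i in range(1, cfg.te_n_families)]
    classes = ["LTR", "Non-LTR", "DNA", "Unclassified"]
    insertions: list[TEInsertion] = []
    cursor = {c: 1000 for c in cfg.chrom_names}
    for fam_i, fam in enumerate(families):
        cls = classes[fam_i % len(classes)]
        for _ in range(cfg.te_insertions_per_family):
            chrom = str(rng.choice(cfg.chrom_names))
            length = int(rng.integers(lo, hi + 1))
            start = cursor[chrom]
            if start + length + 200 > cfg.chrom_length:
                continue
            insertions.append(TEInsertion(Interval(chrom, start, start + length), fam, cls))
            cursor[chrom] = start + length + int(rng.integers(200, 2000))
    return TESim(insertions, cfg.te_enriched_family)


# ---------------------------------------------------------------------------
# Expression tables


def simulate_expression(
    cfg: SimConfig,
    gene_groups: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Replicate-level TPM tables for two species x two sexes.

    ``gene_groups`` maps gene id -> BS group. Both species share a
    log-normal baseline per gene; species B adds group-scaled rank noise
    so between-species Spearman correlation drops with the group's sd;
    replicates add small i.i.d. noise.
    """
    rng = substream(cfg.seed, "expression")
    genes = np.array(list(gene_groups))
    sd = np.array([cfg.group_rank_sd.get(gene_groups[g], 0.4) for g in genes])
    n = genes.size
    frames = []
    for sex in ("male", "female"):
        base = rng.normal(2.0, 1.5, size=n)
        mu = {"A": base, "B": base + rng.normal(0.0, 1.0, size=n) * sd}
        for species in ("A", "B"):
            for rep in range(1, cfg.n_replicates + 1):
                tpm = np.exp(mu[species] + rng.normal(0.0, cfg.replicate_sd, size=n))
                frames.append(
                    pd.DataFrame(
                        {
                            "gene": genes,
                            "species": species,
                            "sex": sex,
                            "replicate": rep,
                            "tpm": tpm,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True), dict(gene_groups)


# ---------------------------------------------------------------------------
# Whole-dataset writer (the file dialects the pipeline reads)


def write_dataset(cfg: SimConfig, outdir) -> dict[str, str]:
    """Generate and write a full synthetic dataset; returns path map.

    Emits narrowPeak peaks and bedGraph tracks per species/protein, the
    ortholog block TSV, a repeat-annotation TSV, a variant TSV per class
    layout, expression TSV and a truth.json with every planted label.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = simulate_genomes(cfg, with_sequence=False)
    sim = simulate_peaks_and_signal(cfg, genomes)
    tes = simulate_te_annotation(cfg, genomes)
    paths: dict[str, str] = {}

    write_map(genomes.ortho_map, out / "ortholog_map.tsv")
    paths["ortholog_map"] = str(out / "ortholog_map.tsv")

    for species, peaks, tracks in (
        ("A", sim.peaks_a, sim.tracks_a),
        ("B", sim.peaks_b, sim.tracks_b),
    ):
        for protein in peaks:
            pk = out / f"peaks_{species}_{protein}.narrowPeak"
            with open(pk, "w") as fh:
                for p in peaks[protein]:
                    fh.write(
                        f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                        f"{p.name}\t0\t.\t{p.fold_enrichment}\t-1\t-1\t"
                        f"{p.summit - p.interval.start}\n"
                    )
            paths[f"peaks_{species}_{protein}"] = str(pk)
            bg = out / f"signal_{species}_{protein}.bedGraph"
            track = tracks[protein]
            with open(bg, "w") as fh:
                for chrom, (starts, ends, values) in sorted(track._chroms.items()):
                    for s, e, v in zip(starts, ends, values):
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
            paths[f"signal_{species}_{protein}"] = str(bg)

    rm = out / "repeats.tsv"
    with open(rm, "w") as fh:
        fh.write("#chrom\tstart\tend\tfamily\tte_class\n")
        for ins in tes.insertions:
            fh.write(
                f"{ins.interval.chrom}\t{ins.interval.start}\t{ins.interval.end}\t"
                f"{ins.family}\t{ins.te_class}\n"
            )
    paths["repeats"] = str(rm)

    # Variant stream over two toy classes on chromosome 2L.
    class_intervals = {
        "selected": [Interval("2L", 0, cfg.chrom_length // 2)],
        "neutral": [Interval("2L", cfg.chrom_length // 2, cfg.chrom_length)],
    }
    sites = simulate_variants(cfg, class_intervals, {"selected": 0.5})
    write_variant_table(sites, out / "variants.tsv")
    paths["variants"] = str(out / "variants.tsv")

    groups = {}
    rng = substream(cfg.seed, "groups")
    names = ["BSminus", "conservedBSplus", "unconservedBSplus"]
    for i in range(cfg.n_genes):
        groups[f"g{i:05d}"] = names[int(rng.integers(0, 3))]
    expr, _ = simulate_expression(cfg, groups)
    expr.to_csv(out / "expression.tsv", sep="\t", index=False)
    paths["expression"] = str(out / "expression.tsv")

    truth = {
        "seed": cfg.seed,
        "gain_fraction": cfg.gain_fraction,
        "peaks": sim.truth.to_dict(orient="records"),
        "te_enriched_family": tes.truth_enriched,
        "variant_true_alpha": {"selected": 0.5},
        "gene_groups": groups,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)
    paths["truth"] = str(out / "truth.json")
    return paths
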