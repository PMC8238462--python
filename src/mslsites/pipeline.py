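"""End-to-end orchestration from a declarative YAML config.

Stages run in dependency order (turnover -> classify -> te -> cis -> mk ->
expression); a stage is skipped when its inputs are absent from the
config. Every report is a TSV or JSON file in the output directory, plus
a run manifest recording the config hash, package version, seed and the
record counts in/out of each stage so headline numbers are auditable.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cis import cis_overlap_table, read_cis_elements, validate_chromosomes
from .dc import chromosome_distribution, classify_dc, labels_to_frame, overlap_partition
from .expression import average_tpm, divergence, read_expression_table
from .intervals import Interval, intervals_from_frame, merge_peaks
from .mk import mk_report, read_variant_table, tabulate
from .orthomap import load_map, reverse_map
from .te import clean_te_annotation, family_enrichment_table, read_repeatmasker_tsv, te_derived_flag, write_insertions_bed
from .turnover import call_conservation, call_turnover, read_bedgraph, read_peaks, turnover_summary, write_calls

__all__ = ["run", "validate", "load_config"]

STAGES = ("turnover", "classify", "te", "cis", "mk", "expression")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("thresholds", {})
    cfg.setdefault("rules", {})
    return cfg


def validate(cfg: dict) -> list[str]:
    """Static checks; an empty list means the config is runnable."""
    problems: list[str] = []
    inputs = cfg.get("inputs", {})
    for key, value in inputs.items():
        paths = value.values() if isinstance(value, dict) else [value]
        for p in paths:
            if isinstance(p, str) and not Path(p).exists():
                problems.append(f"input {key}: file not found: {p}")
    thr = cfg.get("thresholds", {})
    for name, default in (("absence_fold", 10.0), ("lor", 1.5), ("bh_q", 0.05)):
        v = thr.get(name, default)
        if not (isinstance(v, (int, float)) and v > 0):
            problems.append(f"threshold {name} must be positive, got {v!r}")
    if "out" not in cfg:
        problems.append("config needs an 'out' output directory")
    return problems


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run(cfg: dict, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages; returns the manifest dict."""
    problems = validate(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg.get("inputs", {})
    rules = cfg.get("rules", {})
    thr = cfg.get("thresholds", {})
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "version": __version__,
        "seed": cfg.get("seed", 0),
        "stages": {},
    }

    peaks = {}
    for key, spec in inputs.get("peaks", {}).items():
        species, protein = key.split("_", 1)
        peaks[(species, protein)] = read_peaks(spec, protein, species)
    tracks = {}
    for key, spec in inputs.get("signal", {}).items():
        species, protein = key.split("_", 1)
        tracks[(species, protein)] = read_bedgraph(spec)
    ortho = load_map(inputs["ortholog_map"]) if "ortholog_map" in inputs else None

    conservation_by_protein: dict[str, list] = {}
    if "turnover" in stages and ortho is not None and peaks:
        rows = []
        for (species, protein), plist in peaks.items():
            other = "B" if species == "A" else "A"
            own_track = tracks.get((species, protein))
            other_track = tracks.get((other, protein))
            the_map = ortho if species == "A" else reverse_map(ortho)
            if own_track is None or other_track is None:
                continue
            calls = [
                call_turnover(p, own_track, the_map, other_track,
                              fold=thr.get("absence_fold", 10.0))
                for p in plist
            ]
            write_calls(calls, out / f"turnover_{species}_{protein}.tsv")
            rows.append(turnover_summary(calls))
            partner = peaks.get((other, protein), [])
            cons = call_conservation(plist, partner, the_map)
            write_calls(cons, out / f"conservation_{species}_{protein}.tsv")
            rows.append(turnover_summary(cons))
            if species == "A":
                conservation_by_protein[protein] = cons
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(
                out / "turnover_summary.tsv", sep="\t", index=False
            )
        manifest["stages"]["turnover"] = {"peaks_in": sum(map(len, peaks.values()))}

    labels = {}
    if "classify" in stages and peaks:
        for species in sorted({s for s, _ in peaks}):
            msl2 = peaks.get((species, "MSL2"), [])
            merged = {}
            for protein in ("MOF", "MSL1", "MSL2"):
                plist = peaks.get((species, protein), [])
                merged[protein] = [m.interval for m in merge_peaks([p.interval for p in plist])]
            for protein in ("MOF", "MSL1"):
                plist = peaks.get((species, protein), [])
                if not plist:
                    continue
                lab = classify_dc(plist, msl2)
                labels[(species, protein)] = lab
                labels_to_frame(lab).to_csv(
                    out / f"dc_labels_{species}_{protein}.tsv", sep="\t", index=False
                )
            counts = overlap_partition(merged["MOF"], merged["MSL1"], merged["MSL2"])
            with open(out / f"overlap_partition_{species}.json", "w") as fh:
                json.dump(counts, fh, indent=1)
            all_labels = [l for (s, _), ls in labels.items() if s == species for l in ls]
            if all_labels:
                chromosome_distribution(all_labels).to_csv(
                    out / f"chromosome_distribution_{species}.tsv", sep="\t", index=False
                )
        manifest["stages"]["classify"] = {
            "labelled": sum(len(v) for v in labels.values())
        }

    insertions = []
    if "te" in stages and "repeats" in inputs:
        raw = read_repeatmasker_tsv(inputs["repeats"])
        ms = []
        if "microsatellites" in inputs:
            from .intervals import read_bed6

            ms = intervals_from_frame(read_bed6(inputs["microsatellites"]))
        insertions = clean_te_annotation(raw, ms)
        write_insertions_bed(insertions, out / "te_insertions_clean.bed")
        nondc = _nondc_peaks(labels, "A")
        if nondc:
            genome_size = cfg.get("genome_size") or _genome_size_from_peaks(peaks)
            table = family_enrichment_table(
                nondc, insertions, genome_size,
                rule=rules.get("te_derived", "half_overlap"),
                threshold=thr.get("lor", 1.5),
            )
            table.insert(0, "rule", rules.get("te_derived", "half_overlap"))
            table.to_csv(out / "te_family_enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["te"] = {
            "raw_hits": len(raw), "clean_insertions": len(insertions)
        }

    if "cis" in stages and "cis_elements" in inputs:
        elements = read_cis_elements(inputs["cis_elements"])
        nondc = _nondc_peaks(labels, "A")
        problems = validate_chromosomes(nondc, elements)
        if problems:
            raise ValueError("; ".join(problems))
        by_group = {}
        rule = rules.get("cis", "center_within")
        for protein in ("MOF", "MSL1"):
            sel = [l.peak for l in labels.get(("A", protein), []) if l.dc_status == "nonDC"]
            if not sel:
                continue
            flags = [te_derived_flag(p, insertions, rules.get("te_derived", "half_overlap"))[0] for p in sel]
            by_group[f"{protein}_TE-derived"] = [p for p, f in zip(sel, flags) if f]
            by_group[f"{protein}_non-TE-derived"] = [p for p, f in zip(sel, flags) if not f]
        if by_group:
            table = cis_overlap_table(by_group, elements, rule)
            table.insert(0, "rule", rule)
            table.to_csv(out / "cis_overlap.tsv", sep="\t", index=False)
            manifest["stages"]["cis"] = {"elements": len(elements)}

    if "mk" in stages and "variants" in inputs:
        sites = read_variant_table(inputs["variants"])
        class_intervals = {
            label: [Interval(c, int(s), int(e)) for c, s, e in spans]
            for label, spans in cfg.get("mk_classes", {}).items()
        }
        if class_intervals:
            counts = tabulate(sites, class_intervals)
            neutral_label = cfg.get("mk_neutral_label", "neutral")
            neutral = counts[neutral_label]
            pairs = [(c, neutral) for lab, c in counts.items() if lab != neutral_label]
            mk_report(pairs).to_csv(out / "mk_report.tsv", sep="\t", index=False)
            manifest["stages"]["mk"] = {
                "sites": len(sites), "classes": len(class_intervals)
            }

    if "expression" in stages and "expression" in inputs:
        expr = read_expression_table(inputs["expression"])
        mean = average_tpm(expr)
        groups_path = inputs.get("gene_groups")
        rows = []
        if groups_path:
            with open(groups_path) as fh:
                gene_groups = json.load(fh)
            species = sorted(mean["species"].unique())
            for sex in sorted(mean["sex"].unique()):
                sub = mean[mean.sex == sex].pivot(index="gene", columns="species", values="tpm")
                sub = sub.dropna()
                for group in sorted(set(gene_groups.values())):
                    genes = [g for g in sub.index if gene_groups.get(g) == group]
                    est = divergence(
                        sub.loc[genes, species[0]].to_numpy(),
                        sub.loc[genes, species[1]].to_numpy(),
                        group=group,
                        n_bootstrap=cfg.get("n_bootstrap", 1000),
                        rng=cfg.get("seed", 0),
                    )
                    if est is None:
                        rows.append({"sex": sex, "group": group, "n_genes": len(genes),
                                     "divergence": math.nan, "boot_lo": math.nan, "boot_hi": math.nan})
                    else:
                        lo, hi = (float(x) for x in
                                  pd.Series(est.bootstrap).quantile([0.025, 0.975]))
                        rows.append({"sex": sex, "group": group, "n_genes": est.n_genes,
                                     "divergence": est.point, "boot_lo": lo, "boot_hi": hi})
        if rows:
            pd.DataFrame(rows).to_csv(out / "expression_divergence.tsv", sep="\t", index=False)
            manifest["stages"]["expression"] = {"genes": int(mean["gene"].nunique())}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _nondc_peaks(labels: dict, species: str) -> list:
    return [
        l.peak
        for (s, _), ls in labels.items()
        if s == species
        for l in ls
        if l.dc_status == "nonDC"
    ]


def _genome_size_from_peaks(peaks: dict) -> int:
    hi: dict[str, int] = {}
    for plist in peaks.values():
        for p in plist:
            hi[p.interval.chrom] = max(hi.get(p.interval.chrom, 0), p.interval.end)
    return sum(hi.values()) or 1
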