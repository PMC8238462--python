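"""Synthetic-data generator: determinism, planted-truth recovery, file dialects."""

import json

import numpy as np
import pytest

from mslsites.intervals import Interval
from mslsites.mk import mk_alpha, read_variant_table, tabulate
from mslsites.orthomap import load_map
from mslsites.simulate import (
    SimConfig,
    simulate_genomes,
    simulate_mk_counts,
    simulate_peaks_and_signal,
    simulate_variants,
    substream,
    write_dataset,
)
from mslsites.te import read_repeatmasker_tsv
from mslsites.turnover import call_turnover, read_bedgraph, read_peaks
from mslsites.expression import read_expression_table, average_tpm

SMALL = SimConfig(
    seed=7,
    chrom_names=("X", "2L"),
    chrom_length=200_000,
    n_peaks={"MOF": 60, "MSL1": 40, "MSL2": 30},
    te_insertions_per_family=8,
    n_genes=30,
)


class TestGenomes:
    def test_full_coverage_every_position_mappable(self):
        cfg = SimConfig(seed=1, chrom_names=("2L",), chrom_length=100_000,
                        map_coverage=1.0, block_length=100_000)
        g = simulate_genomes(cfg, with_sequence=False)
        assert g.ortho_map.project(Interval("2L", 0, 100_000)) is not None
        assert g.ortho_map.project(Interval("2L", 99_000, 100_000)) is not None

    def test_zero_coverage_unmappable(self):
        cfg = SimConfig(seed=1, chrom_names=("2L",), chrom_length=50_000, map_coverage=0.0)
        g = simulate_genomes(cfg, with_sequence=False)
        assert g.ortho_map.project(Interval("2L", 0, 1000)) is None

    def test_seed_determinism(self):
        a = simulate_genomes(SMALL)
        b = simulate_genomes(SMALL)
        assert a.sequences_a == b.sequences_a
        assert len(a.ortho_map) == len(b.ortho_map)

    def test_substreams_independent(self):
        r1 = substream(3, "genomes").integers(0, 1000, 5)
        r2 = substream(3, "peaks").integers(0, 1000, 5)
        r1b = substream(3, "genomes").integers(0, 1000, 5)
        assert np.array_equal(r1, r1b)
        assert not np.array_equal(r1, r2)


class TestPeaks:
    def test_truth_labels_recovered_by_turnover(self):
        cfg = SimConfig(seed=11, chrom_names=("X", "2L"), chrom_length=400_000,
                        n_peaks={"MOF": 120, "MSL2": 20}, dc_fraction=0.0)
        g = simulate_genomes(cfg, with_sequence=False)
        sim = simulate_peaks_and_signal(cfg, g)
        truth = sim.truth.set_index("name")
        for p in sim.peaks_a["MOF"]:
            call = call_turnover(p, sim.tracks_a["MOF"], g.ortho_map, sim.tracks_b["MOF"])
            expected = "absent_in_other" if truth.loc[p.name, "gained"] else "present_in_other"
            assert call.status == expected, p.name

    def test_gain_fraction_within_binomial_error(self):
        cfg = SimConfig(seed=5, chrom_names=("X", "2L", "2R"), chrom_length=500_000,
                        n_peaks={"MOF": 300, "MSL2": 10}, dc_fraction=0.0,
                        gain_fraction=0.10)
        g = simulate_genomes(cfg, with_sequence=False)
        sim = simulate_peaks_and_signal(cfg, g)
        mof = sim.truth[sim.truth.protein == "MOF"]
        frac = mof["gained"].mean()
        n = len(mof)
        assert abs(frac - 0.10) < 4 * np.sqrt(0.1 * 0.9 / n)

    def test_msl2_concentrates_on_x(self):
        cfg = SimConfig(seed=9, chrom_names=("X", "2L", "2R", "3L"),
                        chrom_length=400_000, n_peaks={"MSL2": 200},
                        msl2_x_fraction=0.97)
        g = simulate_genomes(cfg, with_sequence=False)
        sim = simulate_peaks_and_signal(cfg, g)
        msl2 = sim.truth[sim.truth.protein == "MSL2"]
        assert (msl2.chrom == "X").mean() > 0.9

    def test_zero_gain_all_conserved(self):
        cfg = SimConfig(seed=2, chrom_names=("2L",), chrom_length=300_000,
                        n_peaks={"MOF": 50, "MSL2": 5}, gain_fraction=0.0)
        g = simulate_genomes(cfg, with_sequence=False)
        sim = simulate_peaks_and_signal(cfg, g)
        assert sim.truth["conserved"].all()


class TestVariants:
    def test_alpha_zero_matches_neutral_ratio_in_expectation(self):
        rng = np.random.default_rng(0)
        alphas = []
        for _ in range(50):
            sel, neut = simulate_mk_counts(rng, 0.0, 2_000_000, 2_000_000)
            alphas.append(mk_alpha(sel, neut))
        assert np.mean(alphas) == pytest.approx(0.0, abs=0.02)

    def test_explicit_stream_recovers_alpha(self):
        cfg = SimConfig(seed=13)
        classes = {
            "selected": [Interval("2L", 0, 400_000)],
            "neutral": [Interval("2L", 400_000, 1_000_000)],
        }
        sites = simulate_variants(cfg, classes, {"selected": 0.5})
        counts = tabulate(sites, classes)
        est = mk_alpha(counts["selected"], counts["neutral"])
        assert est == pytest.approx(0.5, abs=0.05)

    def test_singleton_rate_zero(self):
        cfg = SimConfig(seed=4, singleton_density=0.0)
        classes = {"neutral": [Interval("2L", 0, 100_000)]}
        sites = simulate_variants(cfg, classes, {})
        counts = tabulate(sites, classes)["neutral"]
        assert counts.P == counts.P_nosingleton

    def test_invalid_alpha_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="alpha"):
            simulate_mk_counts(rng, 1.0, 1000, 1000)


def test_write_dataset_parses_through_readers(tmp_path):
    """Every emitted file must load cleanly through the package readers."""
    paths = write_dataset(SMALL, tmp_path)
    m = load_map(paths["ortholog_map"])
    assert len(m) > 0
    peaks = read_peaks(paths["peaks_A_MOF"], "MOF", "A")
    assert peaks
    track = read_bedgraph(paths["signal_A_MOF"])
    assert track.max_in(peaks[0].interval) > 0
    assert read_repeatmasker_tsv(paths["repeats"])
    sites = read_variant_table(paths["variants"])
    assert sites
    expr = read_expression_table(paths["expression"])
    assert not average_tpm(expr).empty
    truth = json.loads((tmp_path / "truth.json").read_text())
    assert truth["seed"] == SMALL.seed
    assert {p["name"] for p in truth["peaks"]} >= {p.name for p in peaks}


def test_write_dataset_deterministic(tmp_path):
    p1 = write_dataset(SMALL, tmp_path / "a")
    p2 = write_dataset(SMALL, tmp_path / "b")
    for key in p1:
        with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
            assert f1.read() == f2.read(), key
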