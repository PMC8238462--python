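"""TE annotation cleaning, TE-derived site calling, LOR enrichment, motifs."""

import math

import pytest

from mslsites.intervals import Interval, overlap_length
from mslsites.te import (
    TEInsertion,
    clean_te_annotation,
    family_enrichment_table,
    lor_enrichment,
    motif_count,
    read_repeatmasker_tsv,
    te_derived_flag,
)
from mslsites.turnover import Peak


def hit(s, e, fam="A", cls="LTR", chrom="c"):
    return (Interval(chrom, s, e), fam, cls)


def peak(s, e, summit=None, chrom="c"):
    iv = Interval(chrom, s, e)
    return Peak(iv, summit if summit is not None else iv.midpoint, "MOF", "A")


class TestCleanTE:
    def test_same_family_union_merge(self):
        out = clean_te_annotation([hit(0, 200), hit(150, 400)])
        assert len(out) == 1
        assert out[0].interval == Interval("c", 0, 400)

    def test_cross_family_longest_first_truncation(self):
        # the longer insertion (B, 1100 bp) keeps its full span; the shorter
        # overlapping one is truncated back to the non-shared region
        out = clean_te_annotation([hit(0, 1000, "A"), hit(500, 1600, "B")])
        by_fam = {i.family: i.interval for i in out}
        assert by_fam["B"] == Interval("c", 500, 1600)
        assert by_fam["A"] == Interval("c", 0, 500)

    def test_short_insertions_excluded(self):
        out = clean_te_annotation([hit(0, 80)])
        assert out == []

    def test_truncation_below_minimum_drops(self):
        # B survives truncation with only 60 bp -> dropped
        out = clean_te_annotation([hit(0, 1000, "A"), hit(940, 1060, "B")])
        assert [i.family for i in out] == ["A"]

    def test_fully_covered_shorter_insertion_dropped(self):
        # B (2500 bp) wins; A lies entirely inside it and vanishes
        out = clean_te_annotation([hit(300, 2000, "A"), hit(0, 2500, "B")])
        assert [i.family for i in out] == ["B"]
        assert out[0].interval == Interval("c", 0, 2500)

    def test_truncation_keeps_longest_surviving_fragment(self):
        # two accepted 1000 bp insertions flank C, which keeps only its
        # longest uncovered fragment [1000, 1300)
        out = clean_te_annotation(
            [hit(0, 1000, "A"), hit(1300, 2300, "B"), hit(800, 1500, "C")]
        )
        by_fam = {i.family: i.interval for i in out}
        assert by_fam["C"] == Interval("c", 1000, 1300)

    def test_microsatellite_overlap_removed(self):
        out = clean_te_annotation(
            [hit(0, 500, "A"), hit(1000, 1500, "B")],
            microsatellites=[Interval("c", 100, 120)],
        )
        assert [i.family for i in out] == ["B"]

    def test_no_cross_family_overlap_after_cleaning(self, rng):
        raw = []
        fams = ["A", "B", "C", "D"]
        for _ in range(200):
            s = int(rng.integers(0, 50_000))
            raw.append(hit(s, s + int(rng.integers(100, 2000)), str(rng.choice(fams))))
        out = clean_te_annotation(raw)
        for i, a in enumerate(out):
            for b in out[i + 1:]:
                if a.family != b.family:
                    assert overlap_length(a.interval, b.interval) == 0


class TestTEDerivedFlag:
    def test_half_overlap_boundary(self):
        ins = [TEInsertion(Interval("c", 0, 50), "FAM")]
        assert te_derived_flag(peak(0, 100), ins, "half_overlap") == (True, "FAM")
        ins2 = [TEInsertion(Interval("c", 0, 49), "FAM")]
        assert te_derived_flag(peak(0, 100), ins2, "half_overlap") == (False, None)

    def test_center_in_te(self):
        ins = [TEInsertion(Interval("c", 70, 300), "FAM")]
        assert te_derived_flag(peak(0, 100, summit=75), ins, "center_in_te") == (True, "FAM")
        assert te_derived_flag(peak(0, 100, summit=60), ins, "center_in_te") == (False, None)

    def test_no_insertions(self):
        assert te_derived_flag(peak(0, 100), [], "half_overlap") == (False, None)

    def test_largest_overlap_wins_tie(self):
        ins = [
            TEInsertion(Interval("c", 0, 60), "SMALL"),
            TEInsertion(Interval("c", 0, 100), "BIG"),
        ]
        assert te_derived_flag(peak(0, 100), ins)[1] == "BIG"

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            te_derived_flag(peak(0, 100), [], "bogus")

    def test_half_overlap_single_insertion_not_summed(self):
        # two insertions covering 30+30=60 bp but neither alone >= 50
        ins = [
            TEInsertion(Interval("c", 0, 30), "A"),
            TEInsertion(Interval("c", 40, 70), "B"),
        ]
        assert te_derived_flag(peak(0, 100), ins) == (False, None)


class TestLOR:
    def test_equal_density_zero(self):
        enr = lor_enrichment(10, 10_000, 1000, 1_000_000)
        assert enr.lor == pytest.approx(0.0)
        assert not enr.enriched

    def test_eightfold_density(self):
        enr = lor_enrichment(8, 10_000, 1000, 10_000_000)
        assert enr.lor == pytest.approx(3.0)
        assert enr.enriched

    def test_depleted_family(self):
        enr = lor_enrichment(1, 100_000, 1000, 10_000_000)
        assert enr.lor == pytest.approx(math.log2(0.1))
        assert not enr.enriched

    def test_zero_sites_neg_inf(self):
        enr = lor_enrichment(0, 10_000, 1000, 1_000_000)
        assert enr.lor == -math.inf and not enr.enriched

    def test_zero_family_length_nan(self):
        assert math.isnan(lor_enrichment(5, 0, 1000, 1_000_000).lor)

    def test_density_rescaling_invariance(self):
        a = lor_enrichment(8, 10_000, 1000, 10_000_000)
        b = lor_enrichment(16, 20_000, 3000, 30_000_000)
        assert a.lor == pytest.approx(b.lor)


def test_family_enrichment_table_planted(rng):
    """One family at 8x background site density is the only one past 1.5."""
    genome = 10_000_000
    insertions = []
    pos = 0
    for fam_i in range(5):
        fam = "HOT" if fam_i == 0 else f"BG{fam_i}"
        for _ in range(20):
            insertions.append(TEInsertion(Interval("c", pos, pos + 5000), fam, "LTR"))
            pos += 6000
    peaks = []
    background_rate, n_sites = 1 / 10_000, 0
    for ins in insertions:
        lam = background_rate * ins.interval.length * (8 if ins.family == "HOT" else 1)
        for _ in range(rng.poisson(lam)):
            s = int(rng.integers(ins.interval.start, ins.interval.end - 100))
            peaks.append(peak(s, s + 100))
    # background peaks outside TEs so the genome-wide density is ~1/10kb
    while len(peaks) < genome * background_rate:
        s = int(rng.integers(pos + 1000, genome - 100))
        peaks.append(peak(s, s + 100))
    table = family_enrichment_table(peaks, insertions, genome)
    hot = table[table.family == "HOT"].iloc[0]
    assert hot["enriched"]
    assert hot["lor"] == pytest.approx(3.0, abs=0.6)
    assert not table[table.family != "HOT"]["enriched"].any()


class TestMotifCount:
    @pytest.mark.parametrize(
        "seq, motif, expected",
        [
            ("GAGAGA", "GAGA", 2),  # overlapping matches at 0 and 2
            ("", "GAGA", 0),
            ("GCAGCA", "GCA", 2),
            ("TTTT", "GAGA", 0),
        ],
    )
    def test_forward_examples(self, seq, motif, expected):
        assert motif_count(seq, [motif])[motif] == expected

    def test_reverse_complement_counted(self):
        # TGC is the reverse complement of GCA
        assert motif_count("TTGCTT", ["GCA"])["GCA"] == 1

    def test_palindromic_positions_not_double_counted(self):
        # CACA's reverse complement is TGTG; a CACA occurrence counts once
        assert motif_count("CACA", ["CACA"])["CACA"] == 1

    def test_case_insensitive(self):
        assert motif_count("gagaga", ["GAGA"])["GAGA"] == 2


def test_repeatmasker_tsv_reader(tmp_path):
    p = tmp_path / "rm.tsv"
    p.write_text("#chrom\tstart\tend\tfamily\tte_class\n2L\t100\t600\tROO\tLTR\n")
    hits = read_repeatmasker_tsv(p)
    assert hits[0][0] == Interval("2L", 100, 600)
    assert hits[0][1:] == ("ROO", "LTR")
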