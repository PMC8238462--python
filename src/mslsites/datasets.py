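"""Published reference inputs bundled with the package.

``load_mk_counts`` returns the published site-class count table for the
MSL binding-site MK analysis in D. melanogaster and D. simulans: per
species, protein, chromosome class and site type, the class length (bp),
divergent-site count D, polymorphic-site count P and the
singleton-excluded polymorphism count. These printed counts are the input
from which D/P ratios and the fraction of adaptive fixations are
recomputed (see :func:`mslsites.mk.mk_alpha`); derived statistics are not
stored here.

``HEADLINE_COUNTS`` carries the study's genome-scale bookkeeping numbers
(peak totals, MSL2-independent fractions, X-linked fractions) used only
for arithmetic cross-checks — they are not reproducible from synthetic
data at desk scale.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_mk_counts", "mk_class_pairs", "HEADLINE_COUNTS"]

# species, protein, chrom class, site type, L, D, P, P_nosingleton
_MK_ROWS = [
    ("mel", "MOF", "A+X", "4-fold", 3_455_307, 555_391, 374_706, 299_171),
    ("mel", "MOF", "A+X", "Total", 4_199_054, 164_454, 80_282, 59_102),
    ("mel", "MOF", "A", "4-fold", 2_835_156, 458_286, 303_736, 243_823),
    ("mel", "MOF", "A", "Non-DC", 2_251_825, 23_903, 1_520, 1_285),
    ("mel", "MOF", "X", "4-fold", 620_151, 97_105, 70_970, 55_348),
    ("mel", "MOF", "X", "Non-DC", 1_263_250, 77_324, 43_833, 32_152),
    ("mel", "MOF", "X", "DC", 683_979, 63_227, 34_929, 25_665),
    ("mel", "MSL1", "A+X", "4-fold", 3_455_307, 555_391, 374_706, 299_171),
    ("mel", "MSL1", "A+X", "Total", 4_139_270, 240_542, 91_477, 72_545),
    ("mel", "MSL1", "A", "4-fold", 2_835_156, 458_286, 303_736, 243_823),
    ("mel", "MSL1", "A", "Non-DC", 3_325_728, 187_235, 66_297, 53_497),
    ("mel", "MSL1", "X", "4-fold", 620_151, 97_105, 70_970, 55_348),
    ("mel", "MSL1", "X", "Non-DC", 689_191, 41_493, 18_484, 14_096),
    ("mel", "MSL1", "X", "DC", 124_351, 11_814, 6_696, 4_952),
    ("mel", "MSL2", "X", "4-fold", 620_151, 97_105, 70_970, 55_348),
    ("mel", "MSL2", "X", "DC", 177_823, 17_469, 9_191, 7_329),
    ("sim", "MOF", "A+X", "4-fold", 3_396_349, 580_321, 161_318, 115_418),
    ("sim", "MOF", "A+X", "Total", 123_565, 13_057, 5_007, 3_119),
    ("sim", "MOF", "A", "4-fold", 2_812_623, 483_206, 138_081, 101_660),
    ("sim", "MOF", "A", "Non-DC", 10_110, 1_559, 532, 430),
    ("sim", "MOF", "X", "4-fold", 583_726, 97_115, 23_237, 13_758),
    ("sim", "MOF", "X", "Non-DC", 66_219, 6_675, 2_740, 1_623),
    ("sim", "MOF", "X", "DC", 47_236, 4_823, 1_735, 1_066),
    ("sim", "MSL1", "A+X", "4-fold", 3_396_349, 580_321, 161_318, 115_418),
    ("sim", "MSL1", "A+X", "Total", 1_433_280, 152_204, 61_039, 39_435),
    ("sim", "MSL1", "A", "4-fold", 2_812_623, 483_206, 138_081, 101_660),
    ("sim", "MSL1", "A", "Non-DC", 323_127, 41_098, 16_173, 12_205),
    ("sim", "MSL1", "X", "4-fold", 583_726, 97_115, 23_237, 13_758),
    ("sim", "MSL1", "X", "Non-DC", 975_417, 99_200, 40_092, 24_221),
    ("sim", "MSL1", "X", "DC", 134_736, 11_906, 4_774, 3_009),
    ("sim", "MSL2", "X", "4-fold", 583_726, 97_115, 23_237, 13_758),
    ("sim", "MSL2", "X", "DC", 22_543, 2_442, 751, 470),
]


def load_mk_counts() -> pd.DataFrame:
    """The published MK site-class counts (see module docstring)."""
    return pd.DataFrame(
        _MK_ROWS,
        columns=["species", "protein", "chrom", "site_type", "L", "D", "P", "P_nosingleton"],
    )


def mk_class_pairs() -> list[tuple[dict, dict]]:
    """(selected, neutral) row pairs: every non-4-fold row paired with the
    4-fold control of the same species/protein/chromosome class."""
    df = load_mk_counts()
    pairs = []
    for (_, sel) in df[df.site_type != "4-fold"].iterrows():
        neut = df[
            (df.species == sel.species)
            & (df.protein == sel.protein)
            & (df.chrom == sel.chrom)
            & (df.site_type == "4-fold")
        ].iloc[0]
        pairs.append((sel.to_dict(), neut.to_dict()))
    return pairs


# Genome-scale peak bookkeeping from the study (counts of called and merged
# binding sites); used for arithmetic consistency checks only.
HEADLINE_COUNTS = {
    "mel": {
        "MOF_sites": 4436,
        "MSL1_sites": 4424,
        "MSL2_sites": 413,
        "MOF_merged": 3724,
        "MOF_nonDC": 3502,
        "MSL1_merged": 4414,
        "MSL1_nonDC": 4285,
        "MSL2_autosomal": 10,
        "triple_shared": 125,
        "MOF_x_fraction_pct": 42.0,
        "MSL1_x_fraction_pct": 21.6,
        "MSL2_x_fraction_pct": 97.6,
    },
    "sim": {
        "MOF_sites": 318,
        "MSL1_sites": 2677,
        "MSL2_sites": 82,
        "MOF_merged": 221,
        "MOF_nonDC": 167,
        "MSL1_merged": 2677,
        "MSL1_nonDC": 2611,
        "MSL2_autosomal": 8,
        "triple_shared": 54,
        "MOF_x_fraction_pct": 88.7,
        "MSL1_x_fraction_pct": 58.2,
        "MSL2_x_fraction_pct": 90.2,
    },
}
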