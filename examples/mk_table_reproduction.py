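"""Recompute the published selection estimates from the bundled counts.

Feeds each site class's printed (L, D, P, P-singleton) counts and its
4-fold degenerate neutral control through the extended-MK estimator and
prints D/P(-singleton) and alpha, the fraction of adaptive fixations.
Positive alpha means an excess of divergence over polymorphism relative
to the neutral control (adaptive fixation); negative alpha means excess
polymorphism (segregating weakly deleterious variation).
"""

from mslsites.datasets import mk_class_pairs
from mslsites.mk import SiteClassCounts, dp_ratio, mk_alpha

print(f"{'class':32s} {'D/P-s':>8s} {'alpha':>8s}")
for sel, neut in mk_class_pairs():
    s = SiteClassCounts("s", sel["L"], sel["D"], sel["P"], sel["P_nosingleton"])
    n = SiteClassCounts("n", neut["L"], neut["D"], neut["P"], neut["P_nosingleton"])
    label = f"{sel['species']} {sel['protein']} {sel['chrom']} {sel['site_type']}"
    print(f"{label:32s} {dp_ratio(s):8.3f} {mk_alpha(s, n):8.3f}")
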