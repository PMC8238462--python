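"""Log2 odds-ratio enrichment of binding sites in repeat families.

Plants one repeat family at 8x the genome-wide non-DC binding-site
density (expected LOR = log2 8 = 3) against nine background families and
computes each family's LOR = log2((n_family/L_family)/(n_genome/G)).
Families at LOR >= 1.5 (about a 3-fold excess) are called enriched; only
the planted family should pass.
"""

from mslsites.simulate import substream
from mslsites.te import lor_enrichment

GENOME, FAM_LEN, BACKGROUND = 100_000_000, 1_000_000, 1e-4
rng = substream(1, "example-te")

per_family = {
    f"FAM{i}": int(rng.poisson(BACKGROUND * FAM_LEN * (8 if i == 0 else 1)))
    for i in range(10)
}
outside = int(rng.poisson(BACKGROUND * (GENOME - 10 * FAM_LEN)))
n_total = outside + sum(per_family.values())

print(f"{'family':8s} {'sites':>6s} {'LOR':>7s}  enriched")
for fam, n in per_family.items():
    e = lor_enrichment(n, FAM_LEN, n_total, GENOME, fam)
    print(f"{fam:8s} {n:6d} {e.lor:7.2f}  {e.enriched}")
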