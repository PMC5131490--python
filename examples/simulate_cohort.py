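"""Simulate a carrier-informed mapping cohort and inspect its ground truth.

Builds the default study design — 2 affected calves, 14 obligate-carrier
parents, 27 controls genotyped at 5 x 600 SNPs, plus a 168-animal healthy
sequence panel — with a recessive disease haplotype descending from one
founder sire, and prints what the generator guarantees about it.
"""

import numpy as np

from recmap import SimulationConfig, simulate_population

cfg = SimulationConfig(seed=1)
haps, genotypes, markers, samples, truth = simulate_population(cfg)

print(f"cohort: {genotypes.n_samples} genotyped animals, "
      f"{len(samples)} total (incl. sequence-only panel)")
print(f"markers: {len(markers)} SNPs on {len(markers.chromosomes())} chromosomes")
print(f"carrier haplotype: chromosome {truth.carrier_chrom}, "
      f"{truth.carrier_region_bp[0]:,}-{truth.carrier_region_bp[1]:,} bp, "
      f"{len(truth.carrier_haplotype)} SNPs")

copies = truth.copy_counts
for status in ("affected", "obligate_carrier", "control"):
    ids = samples.ids(status)
    print(f"{status:17s} n={len(ids):2d}  carrier copies: "
          f"{sorted(copies[s] for s in ids)}")

missing = float((genotypes.dosages == -1).mean())
print(f"genotyping missingness: {missing:.3f} (phased haplotypes are complete)")
# Affected animals carry 2 copies of the founder haplotype (the recessive
# genotype), obligate carriers exactly 1, controls 0 — the 2/1/0 response
# the association model regresses on.
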