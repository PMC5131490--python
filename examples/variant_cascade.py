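"""Recessive-compatibility variant filtering in the mapped candidate region.

Runs the four-step cascade over simulated sequence-level variants: restrict
to the region, require hom-alt in affecteds and het in obligate carriers,
drop anything homozygous-alt in the healthy panel, and keep coding/splice
consequences — then validates the surviving candidate against the haplotype.
"""

from recmap import (SimulationConfig, haplotype_variant_concordance,
                    run_cascade, simulate_population, simulate_region_variants)

cfg = SimulationConfig(seed=1)
haps, genotypes, markers, samples, truth = simulate_population(cfg)
variants = simulate_region_variants(cfg, truth, samples)

lo, hi = truth.carrier_region_bp
candidates, report = run_cascade(
    variants, (truth.carrier_chrom, lo, hi),
    case_ids=samples.ids("affected"),
    carrier_ids=samples.ids("obligate_carrier"),
    panel_ids=samples.ids("panel_healthy"))

print(f"cascade over {truth.carrier_chrom}:{lo:,}-{hi:,}")
for step, count in report.steps:
    print(f"  {step:24s} {count:4d} surviving")
print("candidates:", [f"{v.variant_id} ({v.consequence})" for v in candidates])
print("causal variant recovered:",
      any(v.variant_id == truth.causal_variant_id for v in candidates))

causal = next(v for v in variants if v.variant_id == truth.causal_variant_id)
cohort = samples.ids("affected", "obligate_carrier", "control")
conc = haplotype_variant_concordance(
    [truth.copy_counts[s] for s in cohort],
    [causal.genotypes[s] for s in cohort])
print(f"haplotype-genotype concordance complete: {conc.complete} "
      f"(copy-count vs genotype table diagonal = {conc.table.diagonal().tolist()})")
# Each cascade step only removes variants; the causal stop-gained variant is
# never excluded and is in complete linkage with the disease haplotype.
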