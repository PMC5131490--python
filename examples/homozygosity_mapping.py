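"""Homozygosity mapping: shared autozygosity in affecteds, minus controls.

A recessive mutation from a recent common ancestor sits inside a long run of
homozygosity shared — with identical alleles — by all affected animals, and
absent in the homozygous state from unaffected animals. This narrows the
locus to a candidate interval without any regression.
"""

from recmap import (SimulationConfig, exclude_control_homozygotes, find_roh,
                    segment_length_mb, shared_autozygosity, simulate_population)

cfg = SimulationConfig(seed=1)
haps, genotypes, markers, samples, truth = simulate_population(cfg)

affected = samples.ids("affected")
for sid in affected:
    rohs = find_roh(genotypes.dosages[genotypes.sample_index(sid)], markers,
                    min_snps=20, sample_id=sid)
    longest = max(rohs, key=lambda r: r.end_bp - r.start_bp)
    print(f"{sid}: {len(rohs)} ROH; longest {longest.chrom}:"
          f"{longest.start_bp:,}-{longest.end_bp:,} "
          f"({segment_length_mb(longest.start_bp, longest.end_bp)} Mb)")

shared = shared_autozygosity(genotypes, affected, min_snps=20)
unaffected = samples.ids("control", "obligate_carrier")
surviving = exclude_control_homozygotes(shared, genotypes, unaffected)
print(f"shared autozygous segments in affecteds: {len(shared)}; "
      f"{len(surviving)} remain after excluding segments homozygous in "
      f"{len(unaffected)} unaffected animals")
for seg in surviving:
    has_causal = seg.contains_bp(truth.carrier_chrom, truth.causal_position_bp)
    print(f"  {seg.chrom}:{seg.start_bp:,}-{seg.end_bp:,} "
          f"({segment_length_mb(seg.start_bp, seg.end_bp)} Mb, {seg.n_snps} SNPs)"
          f"{'  <- contains the causal variant' if has_causal else ''}")
# The surviving segment on the carrier chromosome is the candidate interval
# that the variant-filter cascade will search.
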