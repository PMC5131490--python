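# Methods

## The mapping problem

`recmap` targets the situation where a severe autosomal-recessive condition
appears in a closed, pedigreed population and only a small number of affected
individuals can be genotyped, but the parents of affected individuals are
available and are, by Mendelian necessity, heterozygous carriers. The package
combines three lines of evidence that each exploit this structure: a
haplotype-dosage regression with a carrier-informed response, homozygosity
mapping across the affected individuals, and a genotype-compatibility filter
over sequence variants in the mapped interval.

## Association model

The response is *y* ∈ {2, 1, 0} for affected, obligate-carrier and control
samples — the expected number of copies of the (unknown) disease haplotype
under recessive inheritance. For each catalogued window haplotype the model

y = µ + Σ_{j=1..k} a_j PC_j + b·HT + e,   e ~ N(0, σ²)

is fitted by ordinary least squares, with HT ∈ {0, 1, 2} the sample's copy
count of that haplotype and PC_j the top k (default 10) principal components
of the genomic relationship matrix. The response is treated as a quantitative
trait — the model is a linear regression with a normal residual, not a
logistic one — because y is an expected dosage, not a binary outcome. The
two-sided p-value for b uses a t distribution with n − k − 2 degrees of
freedom (intercept + k PCs + haplotype).

Numerical choices:

* **Exact fits.** A noiseless 2/1/0 response can be reproduced exactly by a
  haplotype dosage (this happens by construction at the causal locus of the
  simulator). The residual sum of squares is then zero up to roundoff and the
  t statistic diverges; any result whose RSS is below 1e−16 · max(yᵀy, 1) is
  assigned the floor p-value 1e−300, keeping p in (0, 1] and making all
  exactly-fitting windows *tie* rather than rank on floating-point noise.
* **Ties and the top signal.** Because exact fits tie, "the" top window is
  ill-defined; `ScanResult.top_signal()` returns every result tied at the
  minimum p. The tied set typically spans the full IBD segment around the
  causal region — which is also how such studies report their top signal (a
  run of adjacent, equally significant haplotypes).
* **Constant dosage** (haplotype present in everyone or no one after the
  frequency floor) yields an untestable result with no p-value, not an
  exception; untestable haplotypes are counted but excluded from ranking.
* Windows are 20 SNPs wide, shifted in steps of 5; trailing partial windows
  are dropped, so chromosome ends have reduced coverage. The haplotype
  frequency floor is strict (> 0.05 among the 2n sample haplotypes).

Calibration is summarised by the genomic-control inflation factor
λ = median(χ²)/0.4549364 over the implied 1-df chi-squares of all tests, and
a Bonferroni threshold α/n_tests with α = 0.05 over the tests actually
performed. λ is computed over all tests including linked ones.

**Known limitation — λ noise at small n.** With 43 samples and ~1,200 tests
from 75%-overlapping windows on pedigree data, the effective number of
independent tests is a few dozen; the per-seed λ of a permuted-status scan
has a standard deviation near 0.35 even though its seed-average is ≈ 1.05.
Calibration claims should therefore be made on seed averages (or on the
absence of Bonferroni hits), not on a single permuted λ. On scans carrying a
true signal λ is legitimately inflated by the linked significant windows.

## Genomic relationships and PCs

The GRM entry for samples j, k is the mean over usable loci of
(x_j − 2p)(x_k − 2p)/(2p(1 − p)), with p the alt-allele frequency estimated
from the analysis samples themselves — the per-locus-standardised estimator
used by the common GREML/PCA tools. Monomorphic loci are excluded; missing
genotypes are handled by pairwise-complete loci (each pair averaged over the
loci called in both), with an optional strict complete-case mode. Because p
is estimated in-sample, GRM rows sum to zero, the matrix has rank ≤ n − 1,
and the top n − 1 components reconstruct it exactly (tested to 1e−8).
Eigenvector signs are fixed by forcing each vector's largest-magnitude
loading positive; scores are scaled by √eigenvalue. The locus subset used for
the GRM is an explicit argument, since studies often build the GRM on a
slightly different marker set than the association scan.

## Quality control

Filters run in a fixed, logged order: per-sample call rate, then per-SNP call
rate, minor allele frequency, and an exact Hardy–Weinberg test, each computed
on the data surviving the previous step. All thresholds are strict
inequalities (retain if call rate > 0.95, MAF > 0.005, HWE p > 1e−4). The
HWE test enumerates every heterozygote count consistent with the observed
allele counts via the standard stable recurrence and sums the probabilities
of configurations no more probable than the observed one; monomorphic input
returns p = 1. HWE is computed over all samples, including the affected
ones — with very few cases their HWE distortion at linked loci is negligible,
and excluding them would make the filter depend on the phenotype under
study. Order sensitivity is real (a removed low-call-rate sample can rescue
a marker's call rate) and is documented by test rather than forbidden.

## Homozygosity mapping

ROH are defined on array-density dosages by SNP count, not bp length: a
maximal interval containing at most `max_het` heterozygous calls (default 0)
and at least `min_snps` homozygous calls (default 20). Missing calls are
neutral — they neither break a run nor count toward `min_snps` — because at
≥95% call rate strict breaking would shred genuine segments. Segment bp
bounds are the positions of the first and last qualifying SNP (1-based
inclusive), not midpoints to flanking markers.

Shared autozygosity across affected samples requires every sample to be
homozygous for the *identical* allele at every called SNP of the interval;
a heterozygote or an opposite homozygote anywhere breaks the segment. The
check runs on dosages plus allele codes, so phasing is not required. Control
exclusion drops a segment when any control is homozygous for the shared
allele across the whole segment (control missing calls tolerated); a trim
mode instead subtracts each control's matching homozygous runs of at least
`min_snps` informative loci and keeps the remaining pieces of sufficient
size. The cross-population comparison runs the same computation over the
union of two affected groups and annotates group membership.

In the end-to-end pipeline the candidate region handed to the variant filter
is the surviving shared segment that **overlaps the top association
signal** — association places the locus, homozygosity mapping delimits it.
With only two affected (and inbred) individuals, chance autozygous segments
elsewhere in the genome are expected and would otherwise win on length.

## Variant filter cascade

Four steps, in order, each only removing variants: restrict to the region;
require hom-alt in every case and het in every obligate carrier; drop
variants homozygous-alt in at least one healthy-panel animal; keep
coding/splice consequence classes ({stop_gained, splice_site, missense,
synonymous} by default, from the closed label set carried in the VCF
`CSQ_CLASS` INFO field — annotation itself is an input contract, not a step
this package performs). Missing genotypes are treated asymmetrically: a
missing call in a case or carrier makes the variant incompatible (the
required evidence is absent), while a missing panel genotype never excludes.
Indels are handled identically to SNVs, as genotype states. Reported allele
frequencies use (het + 2·hom-alt)/2N and round half-up to integer percent.

## Synthetic cohorts

The generator emulates the study design that makes carrier-informed mapping
work: one founder sire carries the disease haplotype; his half-sib offspring
(by unrelated founder dams) form the obligate-carrier generation; carrier ×
carrier matings are retried until an affected calf (two intact copies of the
founder haplotype over the carrier region) is produced; controls and the
sequence-only healthy panel descend from non-carrier founders. Defaults: 2
affected, 14 obligate carriers, 27 controls (43 genotyped animals), 168
panel animals, 5 chromosomes × 600 SNPs over 100 Mb, carrier region
40–60 Mb on chromosome "5", 500 candidate-region variants, seed 1.

* Meiosis draws a Poisson crossover count (mean 1 per chromosome per
  meiosis, ≈ 1 Morgan for a ~100 Mb bovine-scale chromosome), positions
  uniform in bp, no interference.
* Founder allele frequencies are Beta(2, 2) per locus truncated to
  MAF ≥ 0.05, keeping most loci QC-survivable.
* Genotyping missingness (2%) applies to the dosage matrix only; the phased
  haplotypes are complete, mirroring an upstream phasing/imputation step.
* All carrier-haplotype copies are identical by descent, so at every region
  variant they share one allele draw; the causal variant is the single
  stop-gained variant riding the lineage in all copies and absent elsewhere.
  5% of the remaining variants are in perfect linkage with the lineage, 15%
  ride it over a low background frequency, the rest are independent — giving
  the cascade a realistic survivor profile.
* The seed feeds one hierarchical stream with fixed per-stage substreams
  (founders / pedigree / missingness / variants), so changing the number of
  region variants never perturbs the genotypes.

What the simulator does **not** model, and what passing tests therefore do
not show: linkage-disequilibrium structure in the founders (founder loci are
independent), realistic marker ascertainment and linkage maps, genotyping
*errors* (only missingness), incomplete pedigree records, phasing errors
(haplotypes are known exactly, which is why the causal windows fit the
response perfectly — real phased data would give large but finite
signals), and sex chromosomes. The IBD segment around the carrier region is
long (few meioses separate the cohort from the founder), so the top signal
typically spans an interval larger than the nominal carrier region — as it
does in real studies of this design.

## Problem sizes

The default design (above) is the unit of all multi-seed properties: the
recovery battery runs 20 seeds end to end, and null calibration permutes the
43 cohort statuses 20 times, both completing in well under a minute per
batch on one CPU. Exhaustive-oracle equivalence tests (ROH, shared segments)
run on ≤1,000-SNP instances where the O(n²) scanners are exact and fast.
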