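"""Marker and sample quality control.

Filters mirror standard SNP-array practice for small-cohort mapping studies:
per-sample call rate, per-SNP call rate, minor allele frequency, and an exact
Hardy-Weinberg equilibrium test. All thresholds are strict inequalities: a
marker is retained when its MAF is strictly above the floor, its call rate
strictly above the minimum, and its HWE p-value strictly above the floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix
from .variants import MISSING


@dataclass
class QCThresholds:
    min_maf: float = 0.005
    hwe_p_floor: float = 0.0001
    min_snp_callrate: float = 0.95
    min_sample_callrate: float = 0.95

    def __post_init__(self) -> None:
        for name in ("min_maf", "hwe_p_floor", "min_snp_callrate", "min_sample_callrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QCReport:
    """Per-criterion removal counts, in the order the filters were applied."""

    n_samples_in: int
    n_loci_in: int
    samples_removed_callrate: int = 0
    loci_removed_callrate: int = 0
    loci_removed_maf: int = 0
    loci_removed_hwe: int = 0
    n_samples_retained: int = 0
    n_loci_retained: int = 0
    sample_callrates: dict[str, float] = field(default_factory=dict)
    removed_sample_ids: list[str] = field(default_factory=list)
    removed_snp_ids: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.samples_removed_callrate + self.n_samples_retained != self.n_samples_in:
            raise ValueError("sample accounting does not close")
        removed = (self.loci_removed_callrate + self.loci_removed_maf
                   + self.loci_removed_hwe)
        if removed + self.n_loci_retained != self.n_loci_in:
            raise ValueError("locus accounting does not close")


def compute_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency over non-missing calls: min(p, 1-p) of the alt
    frequency. All-missing input is an error, distinct from MAF 0."""
    col = np.asarray(dosage_column)
    called = col[col != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p = called.sum() / (2 * called.size)
    return float(min(p, 1.0 - p))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style enumeration).

    Enumerates every heterozygote count consistent with the observed allele
    counts and sums the probabilities of all configurations no more probable
    than the observed one. Monomorphic input returns p = 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare-allele count
    if n_rare == 0:
        return 1.0

    # P(het = k | allele counts) up to a constant, via the standard recurrence:
    # P(k+2)/P(k) = 4 * hom_rare(k) * hom_common(k) / ((k+2)(k+1))
    # computed upward and downward from the mid het count, then normalised.
    parity = n_rare % 2
    probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != parity:
        mid += 1
    probs[mid] = 1.0
    k = mid
    while k >= 2:
        hom_r = (n_rare - k) // 2
        hom_c = n - k - hom_r
        probs[k - 2] = probs[k] * k * (k - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        k -= 2
    k = mid
    while k <= n_rare - 2:
        hom_r = (n_rare - k) // 2
        hom_c = n - k - hom_r
        probs[k + 2] = probs[k] * 4.0 * hom_r * hom_c / ((k + 2.0) * (k + 1.0))
        k += 2
    probs /= probs.sum()
    p_obs = probs[n_het]
    # 1e-9 relative slack absorbs roundoff when summing ties with p_obs
    p = probs[probs <= p_obs * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def _callrate(arr: np.ndarray, axis: int) -> np.ndarray:
    return (arr != MISSING).mean(axis=axis)


def apply_qc(genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
             ) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade in fixed order: sample call rate, then per-SNP
    call rate, MAF, HWE. Each step is computed on the data surviving the
    previous one; the report records per-step removals."""
    if genotypes.n_samples == 0 or genotypes.n_loci == 0:
        raise ValueError("QC requires a non-empty genotype matrix")
    th = thresholds or QCThresholds()
    report = QCReport(n_samples_in=genotypes.n_samples, n_loci_in=genotypes.n_loci)

    # 1. sample call rate (strict: retain if callrate > threshold)
    cr_sample = _callrate(genotypes.dosages, axis=1)
    report.sample_callrates = {
        sid: float(cr) for sid, cr in zip(genotypes.sample_ids, cr_sample)}
    keep_samples = cr_sample > th.min_sample_callrate
    report.removed_sample_ids = [
        s for s, k in zip(genotypes.sample_ids, keep_samples) if not k]
    report.samples_removed_callrate = int((~keep_samples).sum())
    gm = genotypes.subset_samples(
        [s for s, k in zip(genotypes.sample_ids, keep_samples) if k])

    # 2. per-SNP call rate
    cr_snp = _callrate(gm.dosages, axis=0) if gm.n_samples else np.zeros(gm.n_loci)
    keep = cr_snp > th.min_snp_callrate
    report.loci_removed_callrate = int((~keep).sum())
    report.removed_snp_ids["callrate"] = list(gm.markers.snp_id[~keep])
    gm = gm.subset_loci(np.flatnonzero(keep))

    # 3. MAF (call-rate filter has already removed all-missing loci unless the
    # threshold is 0; guard anyway)
    mafs = np.array([
        compute_maf(gm.dosages[:, j]) if (gm.dosages[:, j] != MISSING).any() else 0.0
        for j in range(gm.n_loci)])
    keep = mafs > th.min_maf
    report.loci_removed_maf = int((~keep).sum())
    report.removed_snp_ids["maf"] = list(gm.markers.snp_id[~keep])
    gm = gm.subset_loci(np.flatnonzero(keep))

    # 4. HWE exact test (retain if p > floor)
    pvals = np.empty(gm.n_loci)
    for j in range(gm.n_loci):
        col = gm.dosages[:, j]
        pvals[j] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                  int((col == 2).sum()))
    keep = pvals > th.hwe_p_floor
    report.loci_removed_hwe = int((~keep).sum())
    report.removed_snp_ids["hwe"] = list(gm.markers.snp_id[~keep])
    gm = gm.subset_loci(np.flatnonzero(keep))

    report.n_samples_retained = gm.n_samples
    report.n_loci_retained = gm.n_loci
    report.validate()
    return gm, report
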