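"""Sliding-window haplotype association scan for a recessive trait.

Phased haplotypes are cut into windows of ``window_size`` contiguous SNPs,
shifted in steps of ``step`` SNPs along each chromosome. Within a window,
every distinct haplotype with population frequency strictly above ``min_freq``
is tested one-vs-rest with an ordinary least-squares regression

    y = mu + sum_j a_j PC_j + b * HT + e

where y is the carrier-informed response (2 for affected, 1 for obligate
carriers, 0 for controls), PC_j are principal components of the genomic
relationship matrix correcting for stratification, and HT in {0, 1, 2} is the
number of copies of the tested haplotype the animal carries. The two-sided
p-value for b comes from a t distribution with n - k - 2 degrees of freedom
(intercept + k PCs + haplotype). Genome-wide calibration is summarised by the
genomic-control inflation factor and a Bonferroni threshold over the number
of tests actually performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import HaplotypeMatrix, MarkerMap, SampleTable
from .relationship import PCSet

#: Floor for p-values from numerically perfect fits, keeping p in (0, 1].
P_FLOOR = 1e-300

STATUS_CODE = {"affected": 2, "obligate_carrier": 1, "control": 0}


@dataclass
class Window:
    chrom: str
    start_index: int  # global indices into the MarkerMap, inclusive
    end_index: int
    start_bp: int
    end_bp: int
    window_id: str

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1

    def overlaps_bp(self, chrom: str, start_bp: int, end_bp: int) -> bool:
        return (self.chrom == str(chrom)
                and self.start_bp <= end_bp and start_bp <= self.end_bp)


@dataclass
class HaplotypeAllele:
    window_id: str
    alleles: str   # allele letters over the window's loci
    frequency: float


@dataclass
class AssociationResult:
    window_id: str
    chrom: str
    start_bp: int
    end_bp: int
    haplotype: str
    frequency: float
    effect: float | None
    intercept: float | None
    covariate_effects: np.ndarray | None
    p_value: float | None
    testable: bool = True


def response_vector(samples: SampleTable, sample_ids: list[str]) -> np.ndarray:
    """Carrier-informed phenotype coding: affected 2, obligate carrier 1,
    control 0. Panel-only samples have no place in the association cohort."""
    y = np.empty(len(sample_ids))
    for i, sid in enumerate(sample_ids):
        status = samples.status_of(sid)
        if status not in STATUS_CODE:
            raise ValueError(f"sample {sid} has status {status!r}, not part of "
                             "the association cohort")
        y[i] = STATUS_CODE[status]
    return y


def enumerate_windows(markers: MarkerMap, window_size: int = 20, step: int = 5
                      ) -> list[Window]:
    """Per chromosome, windows start at offsets 0, step, 2*step, ... while a
    full window fits; trailing partial windows are dropped."""
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = []
    for chrom in markers.chromosomes():
        idx = markers.chrom_indices(chrom)
        n = len(idx)
        for off in range(0, n - window_size + 1, step):
            lo, hi = idx[off], idx[off + window_size - 1]
            windows.append(Window(
                chrom=chrom, start_index=int(lo), end_index=int(hi),
                start_bp=int(markers.position_bp[lo]),
                end_bp=int(markers.position_bp[hi]),
                window_id=f"{chrom}:{off}",
            ))
    return windows


def _window_strings(window: Window, haps: HaplotypeMatrix) -> np.ndarray:
    """All 2n haplotype allele-letter strings over the window, in sample order
    (sample 0 hap 0, sample 0 hap 1, sample 1 hap 0, ...)."""
    m = haps.markers
    sl = slice(window.start_index, window.end_index + 1)
    sub = haps.alleles[:, :, sl].reshape(-1, window.n_snps)
    letters = np.where(sub == 1, m.alt_allele[sl], m.ref_allele[sl])
    return np.array(["".join(row) for row in letters], dtype=object)


def catalogue_haplotypes(window: Window, haps: HaplotypeMatrix,
                         min_freq: float = 0.05) -> list[HaplotypeAllele]:
    """Distinct haplotypes in the window with frequency strictly above
    ``min_freq`` among the 2n sample haplotypes."""
    strings = _window_strings(window, haps)
    uniq, counts = np.unique(strings, return_counts=True)
    total = len(strings)
    out = [HaplotypeAllele(window.window_id, s, c / total)
           for s, c in zip(uniq, counts) if c / total > min_freq]
    out.sort(key=lambda h: (-h.frequency, h.alleles))
    return out


def haplotype_dosage(sample_pair: tuple[str, str] | np.ndarray,
                     haplotype: HaplotypeAllele | str) -> int:
    """Number of the sample's two haplotypes exactly matching the allele string."""
    target = haplotype.alleles if isinstance(haplotype, HaplotypeAllele) else haplotype
    return sum(1 for h in sample_pair if h == target)


def window_dosages(window: Window, haps: HaplotypeMatrix,
                   haplotype: HaplotypeAllele | str) -> np.ndarray:
    """Per-sample dosage vector of one haplotype over all samples."""
    target = haplotype.alleles if isinstance(haplotype, HaplotypeAllele) else haplotype
    strings = _window_strings(window, haps).reshape(-1, 2)
    return (strings == target).sum(axis=1)


def test_haplotype(y: np.ndarray, pcs: PCSet | np.ndarray | None,
                   dosages: np.ndarray) -> AssociationResult:
    """OLS of y on intercept, PCs and haplotype dosage; two-sided t test on
    the dosage coefficient. A constant dosage vector yields an untestable
    result (no p-value) rather than an exception.

    Returns a bare AssociationResult; window/haplotype metadata is filled in
    by the scan driver (fields default to empty strings here).
    """
    y = np.asarray(y, dtype=float)
    ht = np.asarray(dosages, dtype=float)
    if pcs is None:
        P = np.empty((len(y), 0))
    elif isinstance(pcs, PCSet):
        P = pcs.scores
    else:
        P = np.asarray(pcs, dtype=float)
    n, k = len(y), P.shape[1]
    if len(ht) != n or P.shape[0] != n:
        raise ValueError("response, PCs and dosages must be sample-aligned")

    blank = dict(window_id="", chrom="", start_bp=0, end_bp=0, haplotype="",
                 frequency=float("nan"))
    if np.ptp(ht) == 0:
        return AssociationResult(**blank, effect=None, intercept=None,
                                 covariate_effects=None, p_value=None,
                                 testable=False)
    df = n - k - 2
    if df < 1:
        raise ValueError(f"not enough samples ({n}) for {k} PCs")

    X = np.column_stack([np.ones(n), P, ht])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    # an exact fit up to roundoff gets the floor p directly, so that windows
    # fitting the response perfectly tie instead of ranking on noise
    exact = rss <= 1e-16 * max(float(y @ y), 1.0)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se_b = np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0))
    b = float(beta[-1])
    if exact or se_b == 0.0 or rank < X.shape[1]:
        p = P_FLOOR if (exact or se_b == 0.0) and abs(b) > 0 else 1.0
    else:
        t = b / se_b
        p = max(2.0 * stats.t.sf(abs(t), df), P_FLOOR)
    return AssociationResult(**blank, effect=b, intercept=float(beta[0]),
                             covariate_effects=beta[1:-1].copy(),
                             p_value=float(p), testable=True)


def genomic_inflation(p_values: np.ndarray | list[float]) -> float:
    """Genomic-control lambda: median implied 1-df chi-square statistic over
    the null median 0.4549364."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class ScanSummary:
    n_windows: int
    n_tests: int
    n_untestable: int
    inflation_factor: float
    bonferroni: float
    n_significant: int


@dataclass
class ScanResult:
    results: list[AssociationResult]  # testable results, sorted by p
    summary: ScanSummary
    qq: pd.DataFrame                  # expected vs observed -log10 p
    windows: list[Window] = field(default_factory=list)

    @property
    def top(self) -> AssociationResult:
        return self.results[0]

    def top_signal(self) -> list[AssociationResult]:
        """All results tied at the minimum p-value.

        With a noiseless recessive response the best windows often fit the
        model exactly and tie; the top *signal* is then the whole tied set of
        adjacent windows, not an arbitrary single member.
        """
        p_min = self.results[0].p_value
        return [r for r in self.results if r.p_value <= p_min]

    def significant(self) -> list[AssociationResult]:
        return [r for r in self.results if r.p_value < self.summary.bonferroni]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"window_id": r.window_id, "chrom": r.chrom, "start_bp": r.start_bp,
             "end_bp": r.end_bp, "haplotype": r.haplotype, "freq": r.frequency,
             "beta": r.effect, "p": r.p_value}
            for r in self.results])


def run_association_scan(haps: HaplotypeMatrix, samples: SampleTable,
                         pcs: PCSet | None, window_size: int = 20,
                         step: int = 5, min_freq: float = 0.05,
                         alpha: float = 0.05) -> ScanResult:
    """Test every catalogued haplotype in every window; rank by p-value.

    Raises before any testing if the PC scores are not aligned with the
    haplotype samples or a haplotype sample is missing from the sample table.
    """
    sample_ids = haps.sample_ids
    if pcs is not None and pcs.sample_ids != sample_ids:
        raise ValueError("PC set sample ids are not aligned with the haplotypes")
    y = response_vector(samples, sample_ids)  # raises on unknown/panel samples

    windows = enumerate_windows(haps.markers, window_size, step)
    results: list[AssociationResult] = []
    n_untestable = 0
    for w in windows:
        strings = _window_strings(w, haps)
        uniq, inverse, counts = np.unique(strings, return_inverse=True,
                                          return_counts=True)
        freqs = counts / len(strings)
        pair_codes = inverse.reshape(-1, 2)
        for h in range(len(uniq)):
            if freqs[h] <= min_freq:
                continue
            ht = (pair_codes == h).sum(axis=1)
            res = test_haplotype(y, pcs, ht)
            res.window_id = w.window_id
            res.chrom = w.chrom
            res.start_bp = w.start_bp
            res.end_bp = w.end_bp
            res.haplotype = str(uniq[h])
            res.frequency = float(freqs[h])
            if res.testable:
                results.append(res)
            else:
                n_untestable += 1

    results.sort(key=lambda r: (r.p_value, r.chrom, r.start_bp, r.haplotype))
    n_tests = len(results)
    if n_tests == 0:
        raise ValueError("no testable haplotypes in any window")
    pvals = np.array([r.p_value for r in results])
    lam = genomic_inflation(pvals)
    thr = bonferroni_threshold(n_tests, alpha)
    expected = -np.log10((np.arange(1, n_tests + 1) - 0.5) / n_tests)
    observed = -np.log10(np.sort(pvals))
    qq = pd.DataFrame({"expected_neglog10_p": expected,
                       "observed_neglog10_p": observed})
    summary = ScanSummary(
        n_windows=len(windows), n_tests=n_tests, n_untestable=n_untestable,
        inflation_factor=lam, bonferroni=thr,
        n_significant=int((pvals < thr).sum()))
    return ScanResult(results=results, summary=summary, qq=qq, windows=windows)
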