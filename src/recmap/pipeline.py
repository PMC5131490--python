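"""End-to-end orchestration: simulate (or load) a cohort, QC, scan, map, filter.

``run_end_to_end`` wires the stages together exactly as a mapping study runs
them: marker QC on the dosage matrix, GRM + principal components for
stratification control, the sliding-window haplotype scan, shared-autozygosity
mapping in the affected samples with control exclusion, and the recessive
variant-filter cascade over the candidate region. It returns a summary that
ties every stage's output back to the simulation truth, which is what the
recovery battery and the example scripts consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import assoc, homozygosity, qc, relationship, variants as vf
from .io import GenotypeMatrix, HaplotypeMatrix, SampleTable
from .sim import SimulationConfig, SimulationTruth, simulate_population, \
    simulate_region_variants


@dataclass
class EndToEndResult:
    scan: assoc.ScanResult
    qc_report: qc.QCReport
    shared_segments: list[homozygosity.SharedSegment]
    surviving_segments: list[homozygosity.SharedSegment]
    candidates: list[vf.VariantRecord]
    cascade: vf.CascadeReport
    truth: SimulationTruth | None

    # truth-referenced recovery flags (None when no truth was supplied)
    top_window_overlaps_truth: bool | None = None
    segment_contains_causal: bool | None = None
    causal_survives_cascade: bool | None = None


def analyse(haps: HaplotypeMatrix, genotypes: GenotypeMatrix,
            samples: SampleTable, region_variants: list[vf.VariantRecord],
            truth: SimulationTruth | None = None,
            n_pcs: int = 10, window_size: int = 20, step: int = 5,
            min_freq: float = 0.05, min_roh_snps: int = 20,
            thresholds: qc.QCThresholds | None = None) -> EndToEndResult:
    """Run the full mapping pipeline on an already-built cohort."""
    gm_qc, report = qc.apply_qc(genotypes, thresholds)
    keep_loci = np.flatnonzero(np.isin(genotypes.markers.snp_id, gm_qc.markers.snp_id))
    haps_qc = haps.subset_samples(gm_qc.sample_ids).subset_loci(keep_loci)

    grm = relationship.build_grm(gm_qc)
    pcs = relationship.top_principal_components(grm, k=min(n_pcs, grm.n_samples - 1))
    scan = assoc.run_association_scan(haps_qc, samples, pcs,
                                      window_size=window_size, step=step,
                                      min_freq=min_freq)

    affected = [s for s in gm_qc.sample_ids if samples.status_of(s) == "affected"]
    controls = [s for s in gm_qc.sample_ids
                if samples.status_of(s) in ("control", "obligate_carrier")]
    shared = homozygosity.shared_autozygosity(gm_qc, affected, min_snps=min_roh_snps)
    surviving = homozygosity.exclude_control_homozygotes(
        shared, gm_qc, controls, mode="drop")

    # candidate region for the cascade: the surviving shared segment at the
    # association peak — association places the locus, homozygosity mapping
    # delimits it. Chance autozygous segments elsewhere (the affecteds are
    # inbred) are ignored unless no segment overlaps the top signal, in which
    # case the longest surviving segment is used.
    top_signal = scan.top_signal()

    def _at_peak(seg):
        return any(seg.chrom == r.chrom
                   and seg.start_bp <= r.end_bp and r.start_bp <= seg.end_bp
                   for r in top_signal)

    candidates_segs = surviving or shared
    at_peak = [s for s in candidates_segs if _at_peak(s)]
    if at_peak:
        target = max(at_peak, key=lambda s: s.end_bp - s.start_bp)
        region = (target.chrom, target.start_bp, target.end_bp)
    elif candidates_segs:
        target = max(candidates_segs, key=lambda s: s.end_bp - s.start_bp)
        region = (target.chrom, target.start_bp, target.end_bp)
    else:
        chrom = genotypes.markers.chromosomes()[0]
        region = (chrom, 1, int(genotypes.markers.position_bp.max()))

    carrier_ids = samples.ids("obligate_carrier")
    panel_ids = samples.ids("panel_healthy")
    candidates, cascade = vf.run_cascade(
        region_variants, region, case_ids=samples.ids("affected"),
        carrier_ids=carrier_ids, panel_ids=panel_ids)

    result = EndToEndResult(scan=scan, qc_report=report, shared_segments=shared,
                            surviving_segments=surviving, candidates=candidates,
                            cascade=cascade, truth=truth)
    if truth is not None:
        lo, hi = truth.carrier_region_bp
        result.top_window_overlaps_truth = any(
            r.chrom == truth.carrier_chrom and r.start_bp <= hi and lo <= r.end_bp
            for r in scan.top_signal())
        result.segment_contains_causal = any(
            s.contains_bp(truth.carrier_chrom, truth.causal_position_bp)
            for s in surviving)
        result.causal_survives_cascade = any(
            v.variant_id == truth.causal_variant_id for v in candidates)
    return result


def run_end_to_end(cfg: SimulationConfig | None = None, seed: int | None = None,
                   **analyse_kwargs) -> EndToEndResult:
    """Simulate a cohort under ``cfg`` (optionally overriding its seed) and
    run the full analysis against the emitted truth."""
    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    haps, genotypes, markers, samples, truth = simulate_population(cfg)
    region_variants = simulate_region_variants(cfg, truth, samples)
    return analyse(haps, genotypes, samples, region_variants, truth,
                   **analyse_kwargs)


@dataclass
class RecoverySummary:
    n_seeds: int
    top_window_overlap_rate: float
    segment_contains_causal_rate: float
    causal_survives_cascade_rate: float
    top_hit_beats_bonferroni_rate: float
    inflation_factors: list[float]


def recovery_battery(seeds: list[int], cfg: SimulationConfig | None = None,
                     **analyse_kwargs) -> RecoverySummary:
    """Run the end-to-end recovery check over a list of seeds and aggregate
    the rates the method is judged by."""
    overlap = seg = casc = sig = 0
    lams: list[float] = []
    for s in seeds:
        res = run_end_to_end(cfg, seed=s, **analyse_kwargs)
        overlap += bool(res.top_window_overlaps_truth)
        seg += bool(res.segment_contains_causal)
        casc += bool(res.causal_survives_cascade)
        sig += res.scan.top.p_value < res.scan.summary.bonferroni
        lams.append(res.scan.summary.inflation_factor)
    n = len(seeds)
    return RecoverySummary(
        n_seeds=n,
        top_window_overlap_rate=overlap / n,
        segment_contains_causal_rate=seg / n,
        causal_survives_cascade_rate=casc / n,
        top_hit_beats_bonferroni_rate=sig / n,
        inflation_factors=lams)


def permuted_null_scan(cfg: SimulationConfig, seed: int,
                       n_pcs: int = 10) -> assoc.ScanResult:
    """Scan the simulated cohort with disease statuses permuted among the 43
    genotyped animals — the no-association null used for calibration checks."""
    import pandas as pd

    cfg = SimulationConfig(**{**cfg.__dict__, "seed": seed})
    haps, genotypes, markers, samples, truth = simulate_population(cfg)
    gm_qc, _ = qc.apply_qc(genotypes)
    keep = np.flatnonzero(np.isin(genotypes.markers.snp_id, gm_qc.markers.snp_id))
    haps_qc = haps.subset_samples(gm_qc.sample_ids).subset_loci(keep)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    tab = samples.table.copy()
    cohort = tab["status"] != "panel_healthy"
    statuses = tab.loc[cohort, "status"].to_numpy()
    tab.loc[cohort, "status"] = rng.permutation(statuses)
    permuted = SampleTable(pd.DataFrame(tab))

    grm = relationship.build_grm(gm_qc)
    pcs = relationship.top_principal_components(grm, k=min(n_pcs, grm.n_samples - 1))
    return assoc.run_association_scan(haps_qc, permuted, pcs)
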