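"""Pedigree-structured genotype simulator with a segregating recessive haplotype.

The generator emulates the study design that makes carrier-informed mapping
work in livestock: one heavily used crossbred sire carries a recessive
lethal on one chromosome, his half-sib descendants are mated to each other,
and affected calves are the offspring that inherit the founder haplotype in
two copies. The genotyped cohort mirrors such a study: a small number of
affected calves, the obligate-carrier parents of affected calves, and a set
of unrelated control animals, plus a larger panel of healthy animals that is
only observed at sequence level in the candidate region.

Model choices:

* fixed-depth half-sib pedigree — one carrier founder sire mated to founder
  dams gives the obligate-carrier generation; carrier x carrier matings give
  affected calves; controls and panel animals descend from non-carrier
  founders only;
* meiosis with a Poisson crossover count per chromosome (no interference),
  crossover positions uniform in bp;
* founder allele frequencies drawn per locus from a symmetric Beta
  distribution truncated so the minor allele frequency stays above a floor
  (keeps most loci QC-survivable);
* genotyping missingness applied to the dosage matrix only — the phased
  haplotypes are complete, mirroring a phasing/imputation step upstream;
* all carrier-haplotype copies are identical by descent, so at every
  candidate-region variant they share a single allele draw; the causal
  variant is the one stop-gained variant riding the carrier haplotype in all
  copies and absent elsewhere.

Randomness is one hierarchical stream: the seed spawns fixed per-stage
substreams (founders / pedigree / missingness / region variants), so
generating additional region variants never perturbs the genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .io import (GenotypeMatrix, HaplotypeMatrix, MarkerMap, SampleTable,
                 write_haplotypes, write_ped_map, write_sample_table, write_vcf)
import pandas as pd

from .variants import MISSING, VariantRecord


class SimulationError(RuntimeError):
    """The pedigree could not produce the demanded cohort within the retry budget."""


@dataclass
class SimulationConfig:
    n_chromosomes: int = 5
    snps_per_chromosome: int = 600
    chromosome_length_bp: int = 100_000_000
    n_founders: int = 30
    n_generations: int = 2
    n_affected: int = 2
    n_obligate_carriers: int = 14
    n_controls: int = 27
    n_panel_healthy: int = 168
    carrier_haplotype_chromosome: str = "5"
    carrier_region_bp: tuple[int, int] = (40_000_000, 60_000_000)
    recombination_rate: float = 1.0   # expected crossovers / chromosome / meiosis
    genotyping_missing_rate: float = 0.02
    founder_allele_freq_beta: tuple[float, float] = (2.0, 2.0)
    founder_maf_floor: float = 0.05
    n_region_variants: int = 500
    seed: int = 1
    retry_budget: int = 500

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "snps_per_chromosome", "chromosome_length_bp",
                     "n_founders", "n_generations", "n_affected",
                     "n_obligate_carriers", "n_controls", "n_panel_healthy",
                     "n_region_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("genotyping_missing_rate", "founder_maf_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        lo, hi = self.carrier_region_bp
        if not (1 <= lo < hi <= self.chromosome_length_bp):
            raise ValueError("carrier_region_bp must lie within chromosome bounds")
        if self.carrier_haplotype_chromosome not in self.chromosome_labels():
            raise ValueError("carrier_haplotype_chromosome is not a simulated chromosome")
        if self.n_obligate_carriers % 2 != 0:
            raise ValueError("n_obligate_carriers must be even (carriers are "
                             "mated pairwise)")
        if self.n_affected > self.n_obligate_carriers // 2:
            raise ValueError("need at least 2 obligate carriers per affected calf")
        if self.n_founders < self.n_obligate_carriers // 2 + 3:
            raise ValueError("too few founders for the half-sib design")

    def chromosome_labels(self) -> list[str]:
        return [str(c + 1) for c in range(self.n_chromosomes)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "carrier_region_bp" in raw:
            raw["carrier_region_bp"] = tuple(raw["carrier_region_bp"])
        if "founder_allele_freq_beta" in raw:
            raw["founder_allele_freq_beta"] = tuple(raw["founder_allele_freq_beta"])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the synthetic cohort."""

    causal_variant_id: str
    causal_position_bp: int
    carrier_chrom: str
    carrier_region_bp: tuple[int, int]
    carrier_haplotype: str                    # allele letters over the region SNPs
    copy_counts: dict[str, int]               # per-sample carrier copies (0/1/2)
    hap_is_carrier: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["hap_is_carrier"] = {k: list(v) for k, v in self.hap_is_carrier.items()}
        path.write_text(json.dumps(payload, indent=2))
        return path


def _distinct_positions(rng: np.random.Generator, lo: int, hi: int, n: int
                        ) -> np.ndarray:
    """n distinct sorted positions uniform on [lo, hi] without materialising
    the full range."""
    if hi - lo + 1 < n:
        raise ValueError("interval too small for the requested position count")
    pos: np.ndarray = np.unique(rng.integers(lo, hi + 1, size=2 * n))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(lo, hi + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _draw_marker_map(cfg: SimulationConfig, rng: np.random.Generator) -> MarkerMap:
    bases = np.array(list("ACGT"))
    chroms, pos, ids, ref, alt = [], [], [], [], []
    for c in cfg.chromosome_labels():
        p = _distinct_positions(rng, 1, cfg.chromosome_length_bp,
                                cfg.snps_per_chromosome)
        chroms += [c] * len(p)
        pos += list(p)
        ids += [f"chr{c}_snp{j:04d}" for j in range(len(p))]
        for _ in range(len(p)):
            r, a = rng.choice(4, size=2, replace=False)
            ref.append(bases[r])
            alt.append(bases[a])
    return MarkerMap(chroms, pos, ids, ref, alt)


def _gamete(hap_pair: np.ndarray, chrom_blocks: list[tuple[np.ndarray, np.ndarray]],
            n_loci: int, cfg: SimulationConfig,
            carrier_flags: tuple[bool, bool], rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray]:
    """One meiosis over all chromosomes.

    ``chrom_blocks`` is the cached per-chromosome (locus indices, positions).
    Returns the gamete allele vector and the per-locus flag saying whether the
    allele descends from a carrier haplotype (refined against the region
    allele string by the caller).
    """
    out = np.empty(n_loci, dtype=np.int8)
    carrier_origin = np.empty(n_loci, dtype=bool)
    flags = np.array(carrier_flags)
    for idx, pos in chrom_blocks:
        n_x = rng.poisson(cfg.recombination_rate)
        start = rng.integers(2)
        if n_x == 0:
            source = np.full(len(idx), start)
        else:
            xpos = np.sort(rng.uniform(0, cfg.chromosome_length_bp, size=n_x))
            n_before = np.searchsorted(xpos, pos)
            source = (start + n_before) % 2
        out[idx] = hap_pair[source, idx]
        carrier_origin[idx] = flags[source]
    return out, carrier_origin


@dataclass
class _Animal:
    sample_id: str
    haps: np.ndarray                 # (2, n_loci)
    carrier: tuple[bool, bool]       # per-haplotype: intact carrier copy?
    sire_id: str | None = None
    dam_id: str | None = None

    @property
    def copies(self) -> int:
        return int(self.carrier[0]) + int(self.carrier[1])


def _mate(father: _Animal, mother: _Animal, child_id: str,
          chrom_blocks: list[tuple[np.ndarray, np.ndarray]], n_loci: int,
          cfg: SimulationConfig, region_idx: np.ndarray, carrier_alleles: np.ndarray,
          rng: np.random.Generator) -> _Animal:
    child_haps = np.empty((2, n_loci), dtype=np.int8)
    flags = []
    for h, parent in enumerate((father, mother)):
        gamete, origin = _gamete(parent.haps, chrom_blocks, n_loci, cfg,
                                 parent.carrier, rng)
        child_haps[h] = gamete
        # intact copy: carrier-descended over the whole region AND allele-identical
        intact = bool(origin[region_idx].all()
                      and np.array_equal(gamete[region_idx], carrier_alleles))
        flags.append(intact)
    return _Animal(child_id, child_haps, (flags[0], flags[1]),
                   sire_id=father.sample_id, dam_id=mother.sample_id)


def simulate_population(cfg: SimulationConfig
                        ) -> tuple[HaplotypeMatrix, GenotypeMatrix, MarkerMap,
                                   SampleTable, SimulationTruth]:
    """Gene-drop a recessive carrier haplotype through a half-sib pedigree.

    Returns phased haplotypes, a dosage matrix with genotyping missingness,
    the marker map, the sample table (genotyped cohort + sequence-only panel)
    and the simulation truth. Fully reproducible from ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_founder, rng_ped, rng_miss, _rng_var = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    markers = _draw_marker_map(cfg, rng_founder)
    n_loci = len(markers)
    lo, hi = cfg.carrier_region_bp
    on_chrom = markers.chrom == cfg.carrier_haplotype_chromosome
    region_idx = np.flatnonzero(on_chrom & (markers.position_bp >= lo)
                                & (markers.position_bp <= hi))
    if len(region_idx) == 0:
        raise SimulationError("carrier region contains no SNPs")

    # founder haplotypes from per-locus Beta-truncated allele frequencies
    a, b = cfg.founder_allele_freq_beta
    freqs = rng_founder.beta(a, b, size=n_loci)
    freqs = np.clip(freqs, cfg.founder_maf_floor, 1 - cfg.founder_maf_floor)
    founder_haps = (rng_founder.random((cfg.n_founders, 2, n_loci)) < freqs
                    ).astype(np.int8)

    # founder 0 is the carrier sire; his haplotype 0 over the region is THE
    # carrier haplotype. Redraw any other founder haplotype that collides so
    # the carrier haplotype stays distinguishable.
    carrier_alleles = founder_haps[0, 0, region_idx].copy()
    for f in range(cfg.n_founders):
        for h in range(2):
            if f == 0 and h == 0:
                continue
            tries = 0
            while np.array_equal(founder_haps[f, h, region_idx], carrier_alleles):
                founder_haps[f, h, region_idx] = (
                    rng_founder.random(len(region_idx)) < freqs[region_idx])
                tries += 1
                if tries > cfg.retry_budget:
                    raise SimulationError(
                        f"could not make the carrier haplotype unique within "
                        f"{cfg.retry_budget} redraws")

    founders = [
        _Animal(f"founder_{f:02d}", founder_haps[f],
                (f == 0, False))
        for f in range(cfg.n_founders)]
    sire = founders[0]
    dams = founders[1:]

    chrom_blocks = [(idx, markers.position_bp[idx])
                    for idx in (markers.chrom_indices(c)
                                for c in markers.chromosomes())]

    def breed(father, mother, child_id):
        return _mate(father, mother, child_id, chrom_blocks, n_loci, cfg,
                     region_idx, carrier_alleles, rng_ped)

    # obligate-carrier generation: half-sib offspring of the carrier sire
    carriers: list[_Animal] = []
    tries = 0
    while len(carriers) < cfg.n_obligate_carriers:
        dam = dams[rng_ped.integers(len(dams))]
        child = breed(sire, dam, f"carrier_{len(carriers) + 1:02d}")
        tries += 1
        if child.copies == 1:
            carriers.append(child)
            tries = 0
        elif tries > cfg.retry_budget:
            raise SimulationError(
                f"could not breed {cfg.n_obligate_carriers} carriers within a "
                f"retry budget of {cfg.retry_budget} matings per carrier")

    # affected calves from carrier x carrier matings (half-sib pairs)
    affecteds: list[_Animal] = []
    for i in range(cfg.n_affected):
        father, mother = carriers[2 * i], carriers[2 * i + 1]
        tries = 0
        while True:
            child = breed(father, mother, f"affected_{i + 1:02d}")
            if child.copies == 2:
                affecteds.append(child)
                break
            tries += 1
            if tries > cfg.retry_budget:
                raise SimulationError(
                    f"no affected calf from pair {i} within a retry budget of "
                    f"{cfg.retry_budget} matings")

    # controls and sequence-only panel descend from non-carrier founders
    def healthy(child_id):
        tries = 0
        while True:
            i, j = rng_ped.choice(np.arange(1, len(founders)), size=2, replace=False)
            child = breed(founders[i], founders[j], child_id)
            if child.copies == 0:
                return child
            tries += 1
            if tries > cfg.retry_budget:
                raise SimulationError("could not breed a non-carrier animal "
                                      f"within {cfg.retry_budget} tries")

    controls = [healthy(f"control_{i + 1:02d}") for i in range(cfg.n_controls)]
    panel = [healthy(f"panel_{i + 1:03d}") for i in range(cfg.n_panel_healthy)]

    genotyped = affecteds + carriers + controls
    sample_ids = [an.sample_id for an in genotyped]
    hap_array = np.stack([an.haps for an in genotyped])
    haps = HaplotypeMatrix(hap_array, sample_ids, markers)

    dosages = hap_array.sum(axis=1).astype(np.int8)
    miss = rng_miss.random(dosages.shape) < cfg.genotyping_missing_rate
    dosages[miss] = MISSING
    genotypes = GenotypeMatrix(dosages, sample_ids, markers)

    status = (["affected"] * len(affecteds)
              + ["obligate_carrier"] * len(carriers)
              + ["control"] * len(controls)
              + ["panel_healthy"] * len(panel))
    all_animals = genotyped + panel
    samples = SampleTable(pd.DataFrame({
        "sample_id": [an.sample_id for an in all_animals],
        "status": status,
        "sire_id": [an.sire_id for an in all_animals],
        "dam_id": [an.dam_id for an in all_animals],
    }))

    letters = [markers.alt_allele[j] if al else markers.ref_allele[j]
               for j, al in zip(region_idx, carrier_alleles)]
    causal_pos = int(rng_ped.integers(lo + (hi - lo) // 4, hi - (hi - lo) // 4))
    truth = SimulationTruth(
        causal_variant_id="var_causal",
        causal_position_bp=causal_pos,
        carrier_chrom=cfg.carrier_haplotype_chromosome,
        carrier_region_bp=cfg.carrier_region_bp,
        carrier_haplotype="".join(letters),
        copy_counts={an.sample_id: an.copies for an in all_animals},
        hap_is_carrier={an.sample_id: tuple(bool(x) for x in an.carrier)
                        for an in all_animals},
    )
    return haps, genotypes, markers, samples, truth


# consequence-class mix for non-causal region variants
_CLASS_LABELS = ("intergenic", "synonymous", "missense", "splice_site", "stop_gained")
_CLASS_PROBS = (0.80, 0.08, 0.08, 0.02, 0.02)


def simulate_region_variants(cfg: SimulationConfig, truth: SimulationTruth,
                             samples: SampleTable,
                             vcf_path: str | Path | None = None
                             ) -> list[VariantRecord]:
    """Simulate sequence-level variants in the carrier region.

    Exactly one variant — the causal stop-gained one — rides the carrier
    haplotype in all its copies and nowhere else. Every other variant draws a
    single allele for the carrier lineage (all carrier copies are identical by
    descent) and independent alleles for all other haplotypes. A 5% slice of
    the non-causal variants is in perfect linkage with the carrier haplotype
    (alt on the lineage, absent elsewhere) and a further 15% rides the lineage
    over a low background frequency, emulating the linked-variant load a real
    autozygous interval carries.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])
    lo, hi = truth.carrier_region_bp
    n = cfg.n_region_variants
    all_ids = samples.ids()
    flags = {sid: truth.hap_is_carrier.get(sid, (False, False)) for sid in all_ids}

    positions = _distinct_positions(rng, lo, hi, n)
    causal_slot = int(np.argmin(np.abs(positions - truth.causal_position_bp)))
    positions[causal_slot] = truth.causal_position_bp
    if len(np.unique(positions)) != n:   # collision with a neighbour: nudge
        positions = np.unique(positions)
        while len(positions) < n:
            extra = rng.integers(lo, hi + 1)
            if extra not in positions:
                positions = np.sort(np.append(positions, extra))
        causal_slot = int(np.searchsorted(positions, truth.causal_position_bp))

    n_other = n - 1
    kinds = np.array(["independent"] * n_other, dtype=object)
    n_perfect = max(1, round(0.05 * n_other)) if n_other else 0
    n_partial = round(0.15 * n_other)
    shuffle = rng.permutation(n_other)
    kinds[shuffle[:n_perfect]] = "perfect"
    kinds[shuffle[n_perfect:n_perfect + n_partial]] = "partial"

    bases = np.array(list("ACGT"))
    records: list[VariantRecord] = []
    other_i = 0
    truth.causal_variant_id = "var_causal"
    for slot in range(n):
        pos = int(positions[slot])
        r, al = rng.choice(4, size=2, replace=False)
        if slot == causal_slot:
            vid, kind, csq = "var_causal", "causal", "stop_gained"
        else:
            vid = f"var_{slot:04d}"
            kind = kinds[other_i]
            csq = str(rng.choice(_CLASS_LABELS, p=_CLASS_PROBS))
            other_i += 1

        if kind == "causal" or kind == "perfect":
            lineage_allele, bg_freq = 1, 0.0
        elif kind == "partial":
            lineage_allele, bg_freq = 1, float(rng.uniform(0.01, 0.30))
        else:
            f = float(rng.uniform(0.05, 0.95))
            lineage_allele, bg_freq = int(rng.random() < f), f

        genotypes: dict[str, int] = {}
        for sid in all_ids:
            state = 0
            for is_carrier in flags[sid]:
                if is_carrier:
                    state += lineage_allele
                else:
                    state += int(rng.random() < bg_freq)
            genotypes[sid] = state
        records.append(VariantRecord(
            variant_id=vid, chrom=truth.carrier_chrom, position_bp=pos,
            ref=str(bases[r]), alt=str(bases[al]), genotypes=genotypes,
            consequence=csq))

    if vcf_path is not None:
        write_vcf(records, all_ids, vcf_path)
    return records


def write_fixture_set(cfg: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a full cohort and write every artefact the pipeline consumes:
    PED/MAP, phased-haplotype table, sample table, region VCF and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    haps, genos, markers, samples, truth = simulate_population(cfg)
    variants = simulate_region_variants(cfg, truth, samples,
                                        vcf_path=out / "region.vcf")
    ped, mp = write_ped_map(genos, out / "cohort", samples)
    paths = {
        "ped": ped, "map": mp,
        "haplotypes": write_haplotypes(haps, out / "cohort.haps.tsv"),
        "samples": write_sample_table(samples, out / "samples.tsv"),
        "vcf": out / "region.vcf",
        "truth": truth.to_json(out / "truth.json"),
    }
    return paths
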