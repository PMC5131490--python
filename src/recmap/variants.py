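"""Recessive-compatibility variant filtering.

Given sequence-level genotypes in a mapped candidate region, a recessive
disorder with known affected individuals and obligate carriers (parents of
affected individuals) admits a simple genotype predicate: the causal variant
must be homozygous for the alternate allele in every affected sample,
heterozygous in every obligate carrier, and never homozygous-alternate in a
large panel of healthy animals. This module implements that cascade with
per-step accounting, plus the allele-frequency and haplotype–genotype
concordance summaries used to validate a candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

# Genotype state codes shared across the package. Dosage of the alternate
# allele and genotype state deliberately coincide for biallelic sites.
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

STATE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

#: Consequence classes accepted by default: coding + splice-site, the classes
#: a candidate causal variant for a severe monogenic disorder can occupy.
CODING_CLASSES = frozenset({"stop_gained", "splice_site", "missense", "synonymous"})

#: Closed label set the simulator and the VCF reader recognise.
ALL_CLASSES = frozenset(CODING_CLASSES | {"intergenic"})


@dataclass
class VariantRecord:
    """One biallelic variant with per-sample genotype states.

    ``genotypes`` maps sample id -> state code (HOM_REF/HET/HOM_ALT/MISSING).
    ``consequence`` is a label from the closed class set, or ``None`` when the
    source carried no annotation.
    """

    variant_id: str
    chrom: str
    position_bp: int
    ref: str
    alt: str
    genotypes: dict[str, int]
    consequence: str | None = None

    def state(self, sample_id: str) -> int:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not genotyped at {self.variant_id}")

    def state_name(self, sample_id: str) -> str:
        return STATE_NAMES[self.state(sample_id)]


@dataclass
class CascadeReport:
    """Ordered per-step survivor counts of the recessive filter cascade."""

    steps: list[tuple[str, int]]
    region: str = ""
    case_ids: list[str] = field(default_factory=list)
    carrier_ids: list[str] = field(default_factory=list)
    n_panel: int = 0

    def __post_init__(self) -> None:
        counts = [c for _, c in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("cascade counts must be non-increasing")

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.steps]

    def exclusions(self) -> list[tuple[str, int]]:
        """Per-step excluded counts; exclusions + survivors == previous count."""
        counts = self.counts
        return [
            (name, prev - cur)
            for (name, cur), prev in zip(self.steps[1:], counts[:-1])
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "region": self.region,
                "steps": [{"step": s, "surviving": c} for s, c in self.steps],
                "case_ids": self.case_ids,
                "carrier_ids": self.carrier_ids,
                "n_panel": self.n_panel,
            },
            indent=2,
        )


def recessive_compatible(
    variant: VariantRecord, case_ids: list[str], carrier_ids: list[str]
) -> bool:
    """True iff every case is hom-alt and every obligate carrier is het.

    A missing genotype in either role makes the variant incompatible: the
    evidence required by the recessive model is simply absent, and a candidate
    must positively satisfy the predicate in every informative animal.
    """
    for sid in case_ids:
        if variant.state(sid) != HOM_ALT:
            return False
    for sid in carrier_ids:
        if variant.state(sid) != HET:
            return False
    return True


def exclude_hom_alt_in_panel(
    variants: list[VariantRecord], panel_ids: list[str]
) -> tuple[list[VariantRecord], int]:
    """Drop variants homozygous-alternate in at least one healthy panel sample.

    Missing panel genotypes never exclude a variant — absence of evidence in
    the panel is not evidence of incompatibility.
    """
    survivors = []
    for v in variants:
        if any(v.genotypes.get(sid, MISSING) == HOM_ALT for sid in panel_ids):
            continue
        survivors.append(v)
    return survivors, len(variants) - len(survivors)


def consequence_filter(
    variants: list[VariantRecord], allowed_classes: frozenset[str] | set[str] = CODING_CLASSES
) -> list[VariantRecord]:
    """Retain variants whose consequence class is in ``allowed_classes``.

    Every record must carry a label; annotation is an input contract, not a
    step this package performs.
    """
    for v in variants:
        if v.consequence is None:
            raise ValueError(f"variant {v.variant_id} has no consequence label")
    return [v for v in variants if v.consequence in allowed_classes]


def run_cascade(
    variants: list[VariantRecord],
    region: tuple[str, int, int],
    case_ids: list[str],
    carrier_ids: list[str],
    panel_ids: list[str],
    allowed_classes: frozenset[str] | set[str] = CODING_CLASSES,
) -> tuple[list[VariantRecord], CascadeReport]:
    """Run the four-step recessive candidate cascade with full accounting.

    Steps, in order: restrict to region -> recessive compatibility (hom-alt in
    cases, het in carriers) -> exclude variants homozygous-alternate in the
    healthy panel -> restrict to coding/splice consequence classes.

    ``region`` is (chromosome, start_bp, end_bp), 1-based inclusive.
    """
    if not case_ids or not carrier_ids:
        raise ValueError("cascade requires non-empty case and carrier groups")
    chrom, start, end = region
    if end < start:
        raise ValueError(f"invalid region bounds {start}-{end}")

    in_region = [
        v for v in variants if v.chrom == str(chrom) and start <= v.position_bp <= end
    ]
    compatible = [v for v in in_region if recessive_compatible(v, case_ids, carrier_ids)]
    not_in_panel, _ = exclude_hom_alt_in_panel(compatible, panel_ids)
    candidates = consequence_filter(not_in_panel, allowed_classes)

    report = CascadeReport(
        steps=[
            ("in_region", len(in_region)),
            ("recessive_compatible", len(compatible)),
            ("not_hom_alt_in_panel", len(not_in_panel)),
            ("coding_or_splice", len(candidates)),
        ],
        region=f"{chrom}:{start}-{end}",
        case_ids=list(case_ids),
        carrier_ids=list(carrier_ids),
        n_panel=len(panel_ids),
    )
    return candidates, report


def allele_frequency(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Alternate-allele frequency from genotype counts: (het + 2 hom_alt) / 2N."""
    total = n_hom_ref + n_het + n_hom_alt
    if total < 1:
        raise ValueError("allele frequency undefined for zero genotypes")
    return (n_het + 2 * n_hom_alt) / (2 * total)


def percent_rounded(freq: float) -> int:
    """Frequency as integer percent, rounding half up (0.0506 -> 5)."""
    return int(np.floor(freq * 100 + 0.5))


@dataclass
class ConcordanceResult:
    """3x3 cross-tabulation of haplotype copy count vs variant genotype state."""

    table: np.ndarray  # rows: copy count 0/1/2; cols: hom_ref/het/hom_alt
    n_missing: int
    complete: bool

    def n_discordant(self) -> int:
        off = self.table.sum() - np.trace(self.table)
        return int(off)


def haplotype_variant_concordance(
    copy_counts: np.ndarray | list[int], genotype_states: np.ndarray | list[int]
) -> ConcordanceResult:
    """Cross-tabulate carrier-haplotype copy count against variant genotype.

    Complete concordance (the "complete linkage disequilibrium" pattern) means
    every sample sits on the diagonal: copy 0 <-> hom_ref, 1 <-> het,
    2 <-> hom_alt. Missing genotypes are tallied separately and do not break
    completeness.
    """
    copies = np.asarray(copy_counts, dtype=int)
    states = np.asarray(genotype_states, dtype=int)
    if copies.shape != states.shape:
        raise ValueError("copy counts and genotype states must be sample-aligned")
    table = np.zeros((3, 3), dtype=int)
    n_missing = 0
    for c, s in zip(copies, states):
        if s == MISSING:
            n_missing += 1
            continue
        table[c, s] += 1
    complete = bool(table.sum() == np.trace(table))
    return ConcordanceResult(table=table, n_missing=n_missing, complete=complete)
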