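"""Core genotype data model and readers/writers for the formats the pipeline touches.

Conventions
-----------
* Coordinates are 1-based inclusive everywhere user-facing (PLINK/VCF usage).
* Genotypes are alternate-allele dosages in {0, 1, 2}, with -1 for missing.
* The model is strictly biallelic; multi-allelic VCF records are skipped and
  counted, never split.
* The MAP dialect written by this package has six columns
  (chrom, snp_id, cM, bp, ref, alt) so that dosage orientation round-trips;
  a plain 4-column PLINK MAP is accepted on read, in which case the reference
  allele is inferred as the major allele observed in the PED (ties broken
  lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variants import HET, HOM_ALT, HOM_REF, MISSING, VariantRecord

logger = logging.getLogger(__name__)

STATUSES = ("affected", "obligate_carrier", "control", "panel_healthy")


@dataclass
class MarkerMap:
    """Ordered SNP loci defining all window and segment coordinates.

    Positions are 1-based base pairs, strictly increasing within each
    chromosome; every locus is biallelic with single-character allele codes.
    """

    chrom: np.ndarray       # str labels
    position_bp: np.ndarray  # int64
    snp_id: np.ndarray       # str
    ref_allele: np.ndarray   # single chars
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n = len(self.snp_id)
        for arr in (self.chrom, self.position_bp, self.ref_allele, self.alt_allele):
            if len(arr) != n:
                raise ValueError("marker map field lengths differ")
        if len(set(self.snp_id)) != n:
            raise ValueError("snp ids must be unique")
        for c in self.chromosomes():
            pos = self.position_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        if any(r == a for r, a in zip(self.ref_allele, self.alt_allele)):
            raise ValueError("ref and alt alleles must differ at every locus")

    def __len__(self) -> int:
        return len(self.snp_id)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(
            self.chrom[idx], self.position_bp[idx], self.snp_id[idx],
            self.ref_allele[idx], self.alt_allele[idx],
        )


@dataclass
class GenotypeMatrix:
    """Samples x loci alternate-allele dosages (0/1/2, -1 missing)."""

    dosages: np.ndarray
    sample_ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosage array must be 2-D (samples x loci)")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("dosage column count must equal marker map length")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("dosage row count must equal number of sample ids")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, idx], list(self.sample_ids),
                              self.markers.subset(idx))

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in ids]
        return GenotypeMatrix(self.dosages[rows], list(ids), self.markers)


@dataclass
class HaplotypeMatrix:
    """Phased alleles, 2 haplotypes per sample, coded 0 = ref / 1 = alt.

    Shape (n_samples, 2, n_loci); no missing entries. Sample ids are aligned
    with the GenotypeMatrix the haplotypes were phased from: at every
    non-missing genotype cell, the two haplotype alleles sum to the dosage.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[1] != 2:
            raise ValueError("haplotype array must have shape (samples, 2, loci)")
        if self.alleles.shape[2] != len(self.markers):
            raise ValueError("haplotype locus count must equal marker map length")
        if self.alleles.shape[0] != len(self.sample_ids):
            raise ValueError("haplotype sample count must equal number of sample ids")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 (ref) or 1 (alt)")

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[2]

    def dosages(self) -> np.ndarray:
        """Implied dosage matrix (no missing entries)."""
        return self.alleles.sum(axis=1).astype(np.int8)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_loci(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.alleles[:, :, idx], list(self.sample_ids),
                               self.markers.subset(idx))

    def subset_samples(self, ids: list[str]) -> "HaplotypeMatrix":
        rows = [self.sample_index(s) for s in ids]
        return HaplotypeMatrix(self.alleles[rows], list(ids), self.markers)

    def consistent_with(self, genotypes: GenotypeMatrix) -> bool:
        """Check the phased/dosage consistency invariant at non-missing cells."""
        if self.sample_ids != genotypes.sample_ids:
            return False
        implied = self.dosages()
        mask = genotypes.dosages != MISSING
        return bool(np.array_equal(implied[mask], genotypes.dosages[mask]))


@dataclass
class SampleTable:
    """Sample ids, disease status and optional pedigree links.

    Status drives both the 2/1/0 response coding of the association model and
    the role assignment of the variant filter cascade.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["sample_id", "status", "sire_id", "dam_id"]))

    def __post_init__(self) -> None:
        required = {"sample_id", "status"}
        if not required.issubset(self.table.columns):
            raise ValueError("sample table needs sample_id and status columns")
        for col in ("sire_id", "dam_id"):
            if col not in self.table.columns:
                self.table[col] = None
        bad = set(self.table["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown statuses: {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")

    def ids(self, *statuses: str) -> list[str]:
        if not statuses:
            return list(self.table["sample_id"])
        return list(self.table.loc[self.table["status"].isin(statuses), "sample_id"])

    def status_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id, "status"]
        if row.empty:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return row.iloc[0]

    def __len__(self) -> int:
        return len(self.table)


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# PLINK PED/MAP


def _parse_map(map_path: Path) -> tuple[list[list[str]], bool]:
    rows = []
    extended = None
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (4, 6):
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 or 6 columns, got {len(fields)}")
            is_ext = len(fields) == 6
            if extended is None:
                extended = is_ext
            elif extended != is_ext:
                raise FormatError(f"{map_path}:{lineno}: mixed 4/6-column MAP")
            rows.append(fields)
    if not rows:
        raise FormatError(f"{map_path}: empty MAP file")
    return rows, bool(extended)


def read_ped_map(ped_path: str | Path, map_path: str | Path
                 ) -> tuple[GenotypeMatrix, "SampleTable"]:
    """Read a PED/MAP pair into a GenotypeMatrix (plus the PED's pedigree columns).

    Returns (genotypes, samples). The PED phenotype column is parsed but
    ignored: a separate SampleTable file is the single source of status truth,
    so the returned table carries every sample as 'control' with pedigree
    links preserved.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    map_rows, extended = _parse_map(map_path)
    n_loci = len(map_rows)

    sample_ids: list[str] = []
    sires: list[str | None] = []
    dams: list[str | None] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                    f"for {n_loci} loci, got {len(fields)}")
            sample_ids.append(fields[1])
            sires.append(fields[2] if fields[2] not in ("0", ".") else None)
            dams.append(fields[3] if fields[3] not in ("0", ".") else None)
            allele_rows.append(fields[6:])

    if extended:
        ref = [r[4] for r in map_rows]
        alt = [r[5] for r in map_rows]
    else:
        ref, alt = _infer_alleles(allele_rows, n_loci)

    dosages = np.full((len(sample_ids), n_loci), MISSING, dtype=np.int8)
    for i, alleles in enumerate(allele_rows):
        for j in range(n_loci):
            a1, a2 = alleles[2 * j], alleles[2 * j + 1]
            if a1 == "0" or a2 == "0":
                continue  # PLINK missing convention (half-calls treated as missing)
            d = 0
            for a in (a1, a2):
                if a == alt[j]:
                    d += 1
                elif a != ref[j]:
                    raise FormatError(
                        f"{ped_path}: sample {sample_ids[i]} locus {map_rows[j][1]}: "
                        f"allele {a!r} matches neither ref {ref[j]!r} nor alt {alt[j]!r}")
            dosages[i, j] = d

    markers = MarkerMap(
        chrom=[r[0] for r in map_rows],
        position_bp=[int(r[3]) for r in map_rows],
        snp_id=[r[1] for r in map_rows],
        ref_allele=ref,
        alt_allele=alt,
    )
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "status": ["control"] * len(sample_ids),
        "sire_id": sires,
        "dam_id": dams,
    }))
    return GenotypeMatrix(dosages, sample_ids, markers), samples


def _infer_alleles(allele_rows: list[list[str]], n_loci: int
                   ) -> tuple[list[str], list[str]]:
    """Major allele -> ref, minor -> alt; ties and monomorphic loci break
    lexicographically ('N' stands in when only one allele is ever observed)."""
    ref, alt = [], []
    for j in range(n_loci):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise FormatError(f"locus index {j}: more than two alleles observed")
        ordered = sorted(counts, key=lambda a: (-counts[a], a))
        if not ordered:
            ref.append("N"), alt.append("X")
        elif len(ordered) == 1:
            ref.append(ordered[0])
            alt.append("N" if ordered[0] != "N" else "X")
        else:
            ref.append(ordered[0]), alt.append(ordered[1])
    return ref, alt


def write_ped_map(genotypes: GenotypeMatrix, out_prefix: str | Path,
                  samples: SampleTable | None = None) -> tuple[Path, Path]:
    """Write a PED/MAP pair (6-column extended MAP) readable by read_ped_map."""
    markers = genotypes.markers
    for j, (r, a) in enumerate(zip(markers.ref_allele, markers.alt_allele)):
        if not r or not a:
            raise ValueError(f"locus {markers.snp_id[j]}: missing allele codes")
    out_prefix = Path(out_prefix)
    map_path = out_prefix.with_suffix(".map")
    ped_path = out_prefix.with_suffix(".ped")

    with open(map_path, "w") as fh:
        for j in range(len(markers)):
            fh.write(f"{markers.chrom[j]}\t{markers.snp_id[j]}\t0\t"
                     f"{markers.position_bp[j]}\t{markers.ref_allele[j]}\t"
                     f"{markers.alt_allele[j]}\n")

    ped_info = {}
    if samples is not None:
        for _, row in samples.table.iterrows():
            ped_info[row["sample_id"]] = (row.get("sire_id") or "0",
                                          row.get("dam_id") or "0")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            sire, dam = ped_info.get(sid, ("0", "0"))
            fields = [sid, sid, str(sire), str(dam), "0", "0"]
            row = genotypes.dosages[i]
            for j, d in enumerate(row):
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [markers.ref_allele[j]] * 2
                elif d == 1:
                    fields += [markers.ref_allele[j], markers.alt_allele[j]]
                else:
                    fields += [markers.alt_allele[j]] * 2
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ---------------------------------------------------------------------------
# Phased haplotype table (TSV, two rows per sample)


def write_haplotypes(haps: HaplotypeMatrix, path: str | Path) -> Path:
    """Tab-separated phased haplotypes: sample_id, hap (0/1), then one allele
    letter per locus in marker-map order."""
    path = Path(path)
    m = haps.markers
    with open(path, "w") as fh:
        fh.write("sample_id\thap\t" + "\t".join(m.snp_id) + "\n")
        for i, sid in enumerate(haps.sample_ids):
            for h in range(2):
                letters = [m.alt_allele[j] if haps.alleles[i, h, j] else m.ref_allele[j]
                           for j in range(len(m))]
                fh.write(f"{sid}\t{h}\t" + "\t".join(letters) + "\n")
    return path


def read_haplotypes(path: str | Path, markers: MarkerMap) -> HaplotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "hap"]:
        raise FormatError(f"{path}: expected sample_id/hap leading columns")
    if list(df.columns[2:]) != list(markers.snp_id):
        raise FormatError(f"{path}: locus columns do not match the marker map")
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    alleles = np.zeros((len(sample_ids), 2, len(markers)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        sub = df[df["sample_id"] == sid].sort_values("hap")
        if len(sub) != 2:
            raise FormatError(f"{path}: sample {sid} does not have exactly 2 rows")
        for h in range(2):
            letters = sub.iloc[h, 2:].to_numpy()
            is_alt = letters == markers.alt_allele
            is_ref = letters == markers.ref_allele
            if not np.all(is_alt | is_ref):
                raise FormatError(f"{path}: sample {sid} carries unknown allele codes")
            alleles[i, h] = is_alt.astype(np.int8)
    return HaplotypeMatrix(alleles, sample_ids, markers)


# ---------------------------------------------------------------------------
# Sample table TSV


def write_sample_table(samples: SampleTable, path: str | Path) -> Path:
    path = Path(path)
    out = samples.table.copy()
    out["sire_id"] = out["sire_id"].fillna(".")
    out["dam_id"] = out["dam_id"].fillna(".")
    out.to_csv(path, sep="\t", index=False)
    return path


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.replace({".": None})
    return SampleTable(df)


# ---------------------------------------------------------------------------
# VCF


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based inclusive; commas tolerated)."""
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    except ValueError as exc:
        raise FormatError(f"malformed region {region!r}") from exc
    if start < 1 or end < start:
        raise FormatError(f"invalid region bounds in {region!r}")
    return chrom, start, end


@dataclass
class RegionReadResult:
    """Records read from a VCF region plus a skip report (sequence-like)."""

    records: list[VariantRecord]
    n_multiallelic_skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def read_region_vcf(vcf_path: str | Path, region: str) -> RegionReadResult:
    """Read biallelic records with genotype states from a VCF region.

    Iterates the whole (plain-text or bgzipped) file and filters by
    coordinates, so no tabix index is needed. Multi-allelic records are
    skipped with a warning and counted in the result.
    """
    from cyvcf2 import VCF

    chrom, start, end = parse_region(region)
    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    records: list[VariantRecord] = []
    n_multi = 0
    for v in vcf:
        if v.CHROM != chrom or not (start <= v.POS <= end):
            continue
        if len(v.ALT) != 1:
            n_multi += 1
            logger.warning("skipping multi-allelic record %s:%s", v.CHROM, v.POS)
            continue
        # gts012: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        states = {sid: (MISSING if g == 3 else int(g))
                  for sid, g in zip(sample_ids, v.gt_types)}
        csq = v.INFO.get("CSQ_CLASS")
        records.append(VariantRecord(
            variant_id=v.ID or f"{v.CHROM}:{v.POS}",
            chrom=v.CHROM,
            position_bp=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            genotypes=states,
            consequence=csq,
        ))
    vcf.close()
    return RegionReadResult(records, n_multi)


def write_vcf(records: list[VariantRecord], sample_ids: list[str],
              path: str | Path) -> Path:
    """Write biallelic records as a minimal VCF v4.2 with GT and CSQ_CLASS."""
    path = Path(path)
    gt_map = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    chroms = list(dict.fromkeys(r.chrom for r in records))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CSQ_CLASS,Number=1,Type=String,'
                 'Description="Consequence class label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for r in sorted(records, key=lambda r: (chroms.index(r.chrom), r.position_bp)):
            info = f"CSQ_CLASS={r.consequence}" if r.consequence else "."
            gts = "\t".join(gt_map[r.genotypes.get(s, MISSING)] for s in sample_ids)
            fh.write(f"{r.chrom}\t{r.position_bp}\t{r.variant_id}\t{r.ref}\t{r.alt}"
                     f"\t.\tPASS\t{info}\tGT\t{gts}\n")
    return path
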