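"""Runs of homozygosity and shared-autozygosity segment detection.

A recessive mutation inherited from a recent common ancestor sits inside a
long run of homozygosity (ROH) in every affected individual, and the affected
individuals are homozygous for the *identical* allele sequence over the
shared interval (autozygosity / identity by descent). This module finds
per-sample ROH on array-density dosages, intersects them across affected
samples requiring allele identity, and removes intervals that also occur in
the homozygous state in unaffected controls.

Definitions operate on SNP counts, not bp lengths: a run must contain at
least ``min_snps`` homozygous calls and at most ``max_het`` heterozygous
calls; missing calls are neutral — they neither break a run nor count toward
``min_snps``. Segment bp bounds are the positions of the first and last
qualifying SNP, 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GenotypeMatrix, MarkerMap
from .variants import HET, MISSING


@dataclass
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int          # homozygous calls in the run
    alleles: str         # letter per locus; 'h' het, 'N' missing
    start_index: int     # global marker indices, inclusive
    end_index: int


@dataclass
class SharedSegment:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int          # loci where all members are called and concordant-homozygous
    member_ids: list[str]
    alleles: str
    start_index: int
    end_index: int
    hom_dosage: np.ndarray = field(repr=False, default=None)  # 0/2 per locus, -9 where undefined
    groups: dict[str, list[str]] | None = None

    def contains_bp(self, chrom: str, position_bp: int) -> bool:
        return self.chrom == str(chrom) and self.start_bp <= position_bp <= self.end_bp

    @property
    def length_mb_exact(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


def segment_length_mb(start_bp: int, end_bp: int) -> float:
    """Reporting length in Mb: (end - start) / 1e6, rounded to 2 decimals."""
    if end_bp < start_bp:
        raise ValueError("end_bp must be >= start_bp")
    return round((end_bp - start_bp) / 1e6, 2)


def _maximal_het_bounded_runs(is_het: np.ndarray, max_het: int
                              ) -> list[tuple[int, int]]:
    """Maximal index intervals of a chromosome containing <= max_het het calls."""
    n = len(is_het)
    het_idx = np.flatnonzero(is_het)
    m = len(het_idx)
    if m <= max_het:
        return [(0, n - 1)] if n else []
    padded = np.concatenate(([-1], het_idx, [n]))
    runs = []
    for i in range(m - max_het + 1):
        lo = padded[i] + 1            # just after the previous excluded het
        hi = padded[i + max_het + 1] - 1  # just before the next excluded het
        if lo <= hi:
            runs.append((int(lo), int(hi)))
    return runs


def find_roh(sample_dosages: np.ndarray, markers: MarkerMap,
             min_snps: int = 20, max_het: int = 0,
             sample_id: str = "") -> list[ROHSegment]:
    """Maximal runs of homozygous calls with at most ``max_het`` hets and at
    least ``min_snps`` homozygous SNPs, reported in coordinate order."""
    dosages = np.asarray(sample_dosages)
    if len(dosages) != len(markers):
        raise ValueError("dosage vector not aligned with the marker map")
    segments: list[ROHSegment] = []
    for chrom in markers.chromosomes():
        idx = markers.chrom_indices(chrom)
        d = dosages[idx]
        is_het = d == HET
        is_hom = (d == 0) | (d == 2)
        for lo, hi in _maximal_het_bounded_runs(is_het, max_het):
            hom_local = np.flatnonzero(is_hom[lo:hi + 1])
            if len(hom_local) < min_snps:
                continue
            first = lo + hom_local[0]   # trim bounds to homozygous calls
            last = lo + hom_local[-1]
            g_first, g_last = int(idx[first]), int(idx[last])
            letters = []
            for j in range(first, last + 1):
                gj = idx[j]
                if d[j] == 0:
                    letters.append(markers.ref_allele[gj])
                elif d[j] == 2:
                    letters.append(markers.alt_allele[gj])
                elif d[j] == HET:
                    letters.append("h")
                else:
                    letters.append("N")
            segments.append(ROHSegment(
                sample_id=sample_id, chrom=chrom,
                start_bp=int(markers.position_bp[g_first]),
                end_bp=int(markers.position_bp[g_last]),
                n_snps=int(len(hom_local)), alleles="".join(letters),
                start_index=g_first, end_index=g_last))
    segments.sort(key=lambda s: (markers.chromosomes().index(s.chrom), s.start_bp))
    return segments


def _locus_classes(dosage_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus classification for a set of samples.

    BAD:  any sample het, or two samples homozygous for opposite alleles.
    GOOD: >=1 sample called and all called samples homozygous, same allele.
    Otherwise neutral (all missing).
    Returns (bad, good, hom_dosage) with hom_dosage 0/2 at good loci, -9 else.
    """
    any_het = (dosage_rows == HET).any(axis=0)
    has0 = (dosage_rows == 0).any(axis=0)
    has2 = (dosage_rows == 2).any(axis=0)
    bad = any_het | (has0 & has2)
    good = ~bad & (has0 | has2)
    hom = np.full(dosage_rows.shape[1], -9, dtype=np.int8)
    hom[good & has0] = 0
    hom[good & has2] = 2
    return bad, good, hom


def shared_autozygosity(genotypes: GenotypeMatrix, sample_ids: list[str],
                        min_snps: int = 20) -> list[SharedSegment]:
    """Maximal intervals where every listed sample is homozygous for the
    identical allele at every called SNP (missing calls tolerated)."""
    if len(sample_ids) < 2:
        raise ValueError("shared autozygosity requires at least 2 samples")
    rows = np.array([genotypes.dosages[genotypes.sample_index(s)] for s in sample_ids])
    markers = genotypes.markers
    segments: list[SharedSegment] = []
    for chrom in markers.chromosomes():
        idx = markers.chrom_indices(chrom)
        bad, good, hom = _locus_classes(rows[:, idx])
        # maximal runs free of BAD loci
        boundaries = np.concatenate(([-1], np.flatnonzero(bad), [len(idx)]))
        for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
            lo, hi = b0 + 1, b1 - 1
            if lo > hi:
                continue
            good_local = np.flatnonzero(good[lo:hi + 1])
            if len(good_local) < min_snps:
                continue
            first, last = lo + good_local[0], lo + good_local[-1]
            g_first, g_last = int(idx[first]), int(idx[last])
            letters = []
            for j in range(first, last + 1):
                gj = idx[j]
                if hom[j] == 0:
                    letters.append(markers.ref_allele[gj])
                elif hom[j] == 2:
                    letters.append(markers.alt_allele[gj])
                else:
                    letters.append("N")
            segments.append(SharedSegment(
                chrom=chrom,
                start_bp=int(markers.position_bp[g_first]),
                end_bp=int(markers.position_bp[g_last]),
                n_snps=int(len(good_local)),
                member_ids=list(sample_ids),
                alleles="".join(letters),
                start_index=g_first, end_index=g_last,
                hom_dosage=hom[first:last + 1].copy()))
    return segments


def _control_matches_segment(seg: SharedSegment, control_dosages: np.ndarray) -> bool:
    """True if the control is homozygous for the segment's shared allele at
    every defined locus of the segment (its own missing calls tolerated)."""
    span = control_dosages[seg.start_index:seg.end_index + 1]
    defined = seg.hom_dosage != -9
    ok = (span == seg.hom_dosage) | (span == MISSING)
    return bool(ok[defined].all())


def exclude_control_homozygotes(segments: list[SharedSegment],
                                genotypes: GenotypeMatrix,
                                control_ids: list[str],
                                mode: str = "drop",
                                min_snps: int = 20) -> list[SharedSegment]:
    """Remove shared segments that occur in the homozygous state in controls.

    ``mode='drop'`` (default) discards a segment whenever any control is
    homozygous for the shared allele across the whole segment. ``mode='trim'``
    instead subtracts, from each segment, each control's matching homozygous
    runs of at least ``min_snps`` defined loci, and keeps the remaining pieces
    that still hold ``min_snps`` defined loci.
    """
    if mode not in ("drop", "trim"):
        raise ValueError(f"unknown mode {mode!r}")
    ctrl_rows = {c: genotypes.dosages[genotypes.sample_index(c)] for c in control_ids}
    if mode == "drop":
        return [seg for seg in segments
                if not any(_control_matches_segment(seg, row)
                           for row in ctrl_rows.values())]

    out: list[SharedSegment] = []
    markers = genotypes.markers
    for seg in segments:
        length = seg.end_index - seg.start_index + 1
        blocked = np.zeros(length, dtype=bool)
        defined = seg.hom_dosage != -9
        for row in ctrl_rows.values():
            span = row[seg.start_index:seg.end_index + 1]
            match = ((span == seg.hom_dosage) | (span == MISSING))
            # maximal matching runs with enough informative (defined+called) loci
            edges = np.concatenate(([-1], np.flatnonzero(~match), [length]))
            for e0, e1 in zip(edges[:-1], edges[1:]):
                lo, hi = e0 + 1, e1 - 1
                if lo > hi:
                    continue
                informative = int((defined[lo:hi + 1] & (span[lo:hi + 1] != MISSING)).sum())
                if informative >= min_snps:
                    blocked[lo:hi + 1] = True
        edges = np.concatenate(([-1], np.flatnonzero(blocked), [length]))
        for e0, e1 in zip(edges[:-1], edges[1:]):
            lo, hi = e0 + 1, e1 - 1
            if lo > hi:
                continue
            sub_def = np.flatnonzero(defined[lo:hi + 1])
            if len(sub_def) < min_snps:
                continue
            first = seg.start_index + lo + sub_def[0]
            last = seg.start_index + lo + sub_def[-1]
            rel0, rel1 = first - seg.start_index, last - seg.start_index
            out.append(SharedSegment(
                chrom=seg.chrom,
                start_bp=int(markers.position_bp[first]),
                end_bp=int(markers.position_bp[last]),
                n_snps=int(len(sub_def)),
                member_ids=list(seg.member_ids),
                alleles=seg.alleles[rel0:rel1 + 1],
                start_index=int(first), end_index=int(last),
                hom_dosage=seg.hom_dosage[rel0:rel1 + 1].copy()))
    return out


def cross_group_shared_haplotype(genotypes: GenotypeMatrix,
                                 group_a: list[str], group_b: list[str],
                                 min_snps: int = 20) -> list[SharedSegment]:
    """Shared autozygosity across the union of two groups of affected samples
    (e.g. cases from two breeds), annotated with group membership — evidence
    that both groups inherited the interval from a common ancestor."""
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one sample")
    union = list(dict.fromkeys(list(group_a) + list(group_b)))
    if len(union) < 2:
        # a single sample duplicated across groups: reduce to its own ROH set
        sid = union[0]
        row = genotypes.dosages[genotypes.sample_index(sid)]
        segs = []
        for r in find_roh(row, genotypes.markers, min_snps=min_snps, sample_id=sid):
            hom = np.full(r.end_index - r.start_index + 1, -9, dtype=np.int8)
            span = genotypes.dosages[genotypes.sample_index(sid),
                                     r.start_index:r.end_index + 1]
            hom[span == 0] = 0
            hom[span == 2] = 2
            segs.append(SharedSegment(
                chrom=r.chrom, start_bp=r.start_bp, end_bp=r.end_bp,
                n_snps=r.n_snps, member_ids=[sid], alleles=r.alleles,
                start_index=r.start_index, end_index=r.end_index,
                hom_dosage=hom, groups={"a": list(group_a), "b": list(group_b)}))
        return segs
    segments = shared_autozygosity(genotypes, union, min_snps=min_snps)
    for seg in segments:
        seg.groups = {"a": list(group_a), "b": list(group_b)}
    return segments
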