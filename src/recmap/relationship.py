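"""Genomic relationship matrix and principal components for stratification control.

The GRM uses per-locus standardisation: entry (j, k) is the mean over usable
loci of (x_j - 2p)(x_k - 2p) / (2p(1 - p)), with p the alt-allele frequency
estimated from the analysis samples themselves. Monomorphic loci carry no
relationship information and are excluded. Missing genotypes are handled by
pairwise-complete loci by default (each pair averaged over the loci where both
samples are called); a strict complete-case mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GenotypeMatrix
from .variants import MISSING


@dataclass
class GRM:
    values: np.ndarray
    sample_ids: list[str]
    n_loci_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("GRM dimension must match sample count")
        self.values = v

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class PCSet:
    """Principal-component scores of a GRM, scaled by sqrt(eigenvalue)."""

    scores: np.ndarray       # samples x k
    eigenvalues: np.ndarray  # k, non-increasing
    sample_ids: list[str]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def build_grm(genotypes: GenotypeMatrix, locus_subset: np.ndarray | None = None,
              complete_case: bool = False) -> GRM:
    """Build the genomic relationship matrix from dosages.

    ``locus_subset`` restricts the computation to an explicit set of locus
    indices (e.g. an autosomal subset differing from the association markers).
    With ``complete_case`` only loci called in every sample are used; the
    default divides each pairwise sum by the number of loci called in both
    members of the pair.
    """
    if genotypes.n_samples < 2:
        raise ValueError("GRM requires at least two samples")
    X = genotypes.dosages.astype(float)
    if locus_subset is not None:
        X = X[:, np.asarray(locus_subset)]
    obs = X != MISSING
    X = np.where(obs, X, np.nan)

    p = np.nanmean(X, axis=0) / 2.0
    usable = (p > 0) & (p < 1) & ~np.isnan(p)
    if complete_case:
        usable &= obs.all(axis=0)
    if not usable.any():
        raise ValueError("no usable loci after excluding monomorphic/missing loci")
    X = X[:, usable]
    p = p[usable]
    obs = obs[:, usable] if not complete_case else np.ones_like(X, dtype=bool)

    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    Z = np.where(np.isnan(Z), 0.0, Z)
    numer = Z @ Z.T
    denom = obs.astype(float) @ obs.astype(float).T
    if (denom == 0).any():
        raise ValueError("some sample pair shares no called loci")
    G = numer / denom
    G = (G + G.T) / 2.0  # exact symmetry against roundoff
    return GRM(G, list(genotypes.sample_ids), int(usable.sum()))


def top_principal_components(grm: GRM, k: int = 10) -> PCSet:
    """Eigenvectors of the GRM for the k largest eigenvalues, as scores
    scaled by sqrt(eigenvalue); eigenvector signs are fixed by forcing each
    vector's largest-magnitude loading positive."""
    if k >= grm.n_samples:
        raise ValueError(f"k must be < number of samples ({grm.n_samples})")
    if not np.isfinite(grm.values).all():
        raise ValueError("GRM contains non-finite entries")
    eigvals, eigvecs = np.linalg.eigh(grm.values)
    order = np.argsort(eigvals)[::-1][:k]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return PCSet(scores=scores, eigenvalues=vals, sample_ids=list(grm.sample_ids))
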