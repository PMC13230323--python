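"""Population diversity and differentiation on harmonized genotype matrices.

Nucleotide diversity (pi) per SNP is the mean pairwise allelic difference
among the 2n sampled alleles; pairwise differentiation is the Weir &
Cockerham (1984) FST estimator for two populations, combined across loci as
a ratio of sums of the per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals).
Missing calls are handled per locus by complete-case allele counts; negative
per-locus components are retained, as in the original estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markerio import GenotypeMatrix


class PopStatsError(ValueError):
    pass


@dataclass
class DiversityResult:
    per_locus_pi: np.ndarray
    mean_pi: float
    n_loci: int

    def to_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"pi": self.per_locus_pi})
        if variants is not None:
            df = pd.concat([variants.reset_index(drop=True), df], axis=1)
        return df


def nucleotide_diversity(
    gm: GenotypeMatrix, sample_subset: list[str] | None = None
) -> DiversityResult:
    """Per-SNP mean pairwise difference and its average over usable loci.

    With a alt alleles among m non-missing alleles at a locus,
    pi = [C(m,2) - C(a,2) - C(m-a,2)] / C(m,2); loci with m < 2 are excluded.
    """
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise PopStatsError("empty sample subset")
        gm = gm.take_samples(sample_subset)
    d = gm.dosage
    obs = ~np.isnan(d)
    m = 2.0 * obs.sum(axis=0)
    a = np.nansum(d, axis=0)
    usable = m >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pairs = m * (m - 1) / 2.0
        same = a * (a - 1) / 2.0 + (m - a) * (m - a - 1) / 2.0
        pi = np.where(usable, (pairs - same) / np.where(usable, pairs, 1.0), np.nan)
    pi_used = pi[usable]
    if pi_used.size == 0:
        raise PopStatsError("no locus with at least two non-missing alleles")
    return DiversityResult(
        per_locus_pi=pi, mean_pi=float(pi_used.mean()), n_loci=int(usable.sum())
    )


@dataclass
class FstResult:
    a: np.ndarray  # among-population component per locus
    b: np.ndarray  # among individuals within populations
    c: np.ndarray  # within individuals
    fst: float
    n_loci: int

    def per_locus_frame(self, variants: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"a": self.a, "b": self.b, "c": self.c})
        if variants is not None:
            df = pd.concat([variants.reset_index(drop=True), df], axis=1)
        return df


def pairwise_fst(gmA: GenotypeMatrix, gmB: GenotypeMatrix) -> FstResult:
    """Two-population Weir-Cockerham FST, ratio of sums across loci.

    Inputs must be harmonized (identical variant tables).  Loci monomorphic
    across both populations, or with fewer than two genotyped individuals in
    either population, are excluded from the sums (their components are nan).
    """
    if not gmA.variants[["chrom", "pos", "ref", "alt"]].equals(
        gmB.variants[["chrom", "pos", "ref", "alt"]]
    ):
        raise PopStatsError("inputs are not harmonized (variant tables differ)")

    r = 2.0
    comps = []
    for dA, dB in ((gmA.dosage, gmB.dosage),):
        nA = np.sum(~np.isnan(dA), axis=0).astype(float)  # individuals
        nB = np.sum(~np.isnan(dB), axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pA = np.nansum(dA, axis=0) / (2.0 * nA)
            pB = np.nansum(dB, axis=0) / (2.0 * nB)
            hA = np.nansum(dA == 1, axis=0) / nA  # observed het frequency
            hB = np.nansum(dB == 1, axis=0) / nB
            nbar = (nA + nB) / r
            nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
            pbar = (nA * pA + nB * pB) / (r * nbar)
            s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (nA * hA + nB * hB) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (1.0 / (nbar - 1.0))
                * (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            )
            b = (nbar / (nbar - 1.0)) * (
                pbar * (1.0 - pbar)
                - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c = hbar / 2.0
        poly = ~((pbar <= 0.0) | (pbar >= 1.0))
        valid = (nA >= 2) & (nB >= 2) & poly & np.isfinite(a)
        a = np.where(valid, a, np.nan)
        b = np.where(valid, b, np.nan)
        c = np.where(valid, c, np.nan)
        comps.append((a, b, c, valid))
    a, b, c, valid = comps[0]
    denom = np.nansum(a + b + c)
    if not valid.any() or denom <= 0:
        raise PopStatsError("no informative loci for FST (denominator <= 0)")
    fst = float(np.nansum(a) / denom)
    return FstResult(a=a, b=b, c=c, fst=fst, n_loci=int(valid.sum()))
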