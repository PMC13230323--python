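"""Marker representations for genomic prediction: SNP dosages, haplotype-block
(HAP) markers, and principal-component (PC) markers.

Haplotype blocks follow the Haploview-style confidence-interval ("Gabriel")
definition: pairwise D' is estimated by EM from two-locus genotype counts, a
95% CI on |D'| comes from the normalized likelihood evaluated on a grid, and
pairs are classified strong LD (CI lower >= 0.70 and upper >= 0.98), strong
recombination (CI upper < 0.90) or inconclusive.  A block is a run of loci
whose endpoint pair is in strong LD and where >= 95% of informative pairs are
in strong LD; overlaps are resolved greedily by descending span.

HAP markers encode each block's haplotype alleles as allele-count columns
(rare alleles pooled), so the feature matrix stays numeric for linear
predictors; loci outside any block remain plain SNP dosage features.  PC
markers are principal components of the (training) SNP matrix retaining the
smallest number of components explaining 95% of variance, with test samples
projected on training loadings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .markerio import GenotypeMatrix


class MarkerRepError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise D' with likelihood-grid confidence interval
# ---------------------------------------------------------------------------

@dataclass
class GabrielConfig:
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    min_strong_fraction: float = 0.95
    max_block_span_loci: int = 50
    min_informative_maf: float = 0.05
    n_grid: int = 101
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.strong_ci_low < self.strong_ci_high:
            raise MarkerRepError("strong_ci_low must be < strong_ci_high")


@dataclass
class LDPairStats:
    locus_i: int
    locus_j: int
    dprime: float
    ci_low: float
    ci_high: float
    classification: str  # strong_LD | strong_recombination | inconclusive


def _em_haplotype_freqs(counts: np.ndarray, tol=1e-10, max_iter=500) -> np.ndarray:
    """EM haplotype frequencies (p00, p01, p10, p11) from a 3x3 two-locus
    genotype count table; double heterozygotes are the only ambiguous class."""
    n = counts.sum()
    # known haplotype contributions (each individual = 2 haplotypes)
    base = np.zeros(4)
    base[0] = 2 * counts[0, 0] + counts[0, 1] + counts[1, 0]
    base[1] = 2 * counts[0, 2] + counts[0, 1] + counts[1, 2]
    base[2] = 2 * counts[2, 0] + counts[1, 0] + counts[2, 1]
    base[3] = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    dh = counts[1, 1]
    h = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        tot = cis + trans
        f_cis = 0.5 if tot == 0 else cis / tot
        new = base.astype(float)
        new[0] += dh * f_cis
        new[3] += dh * f_cis
        new[1] += dh * (1 - f_cis)
        new[2] += dh * (1 - f_cis)
        new /= 2.0 * n
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    return h


def _genotype_class_probs(h: np.ndarray) -> np.ndarray:
    """3x3 genotype class probabilities under random union of haplotypes
    (p00, p01, p10, p11 ordered as ref/alt at locus i then j)."""
    p = np.zeros((3, 3))
    h00, h01, h10, h11 = h
    p[0, 0] = h00**2
    p[0, 1] = 2 * h00 * h01
    p[0, 2] = h01**2
    p[1, 0] = 2 * h00 * h10
    p[1, 1] = 2 * (h00 * h11 + h01 * h10)
    p[1, 2] = 2 * h01 * h11
    p[2, 0] = h10**2
    p[2, 1] = 2 * h10 * h11
    p[2, 2] = h11**2
    return p


def dprime_ci(
    gm: GenotypeMatrix,
    i: int,
    j: int,
    config: GabrielConfig | None = None,
) -> LDPairStats:
    """D' and its likelihood-grid CI for a pair of loci, plus the Gabriel
    classification.

    The CI is the 5th/95th percentile of the normalized likelihood of the
    observed two-locus genotype counts evaluated on a |D'| grid, holding
    allele frequencies at their observed values.
    """
    cfg = config or GabrielConfig()
    d = gm.dosage
    xi, xj = d[:, i], d[:, j]
    ok = ~np.isnan(xi) & ~np.isnan(xj)
    xi = np.rint(xi[ok]).astype(int)
    xj = np.rint(xj[ok]).astype(int)
    counts = np.zeros((3, 3))
    np.add.at(counts, (xi, xj), 1)
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * counts.sum())
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * counts.sum())
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MarkerRepError(f"locus pair ({i}, {j}) not both polymorphic")

    h = _em_haplotype_freqs(counts)
    D = h[3] - pA * pB  # cov between alt alleles
    if D >= 0:
        dmax_pos = min(pA * (1 - pB), (1 - pA) * pB)
        dmax = dmax_pos
        sign = 1.0
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
        sign = -1.0
    dprime = 0.0 if dmax == 0 else abs(D) / dmax

    grid = np.linspace(0.0, 1.0, cfg.n_grid)
    loglik = np.empty(cfg.n_grid)
    mask = counts > 0
    for k, g in enumerate(grid):
        Dg = sign * g * dmax
        hg = np.array(
            [
                (1 - pA) * (1 - pB) + Dg,
                (1 - pA) * pB - Dg,
                pA * (1 - pB) - Dg,
                pA * pB + Dg,
            ]
        )
        hg = np.clip(hg, 1e-12, None)
        probs = _genotype_class_probs(hg)
        loglik[k] = np.sum(counts[mask] * np.log(probs[mask]))
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lo_q, hi_q = cfg.alpha / 2.0 * 2.0, 1.0 - cfg.alpha / 2.0 * 2.0  # 5%, 95%
    ci_low = float(grid[np.searchsorted(cum, lo_q)])
    ci_high = float(grid[np.searchsorted(cum, hi_q)])

    if ci_low >= cfg.strong_ci_low and ci_high >= cfg.strong_ci_high:
        cls = "strong_LD"
    elif ci_high < cfg.recomb_ci_high:
        cls = "strong_recombination"
    else:
        cls = "inconclusive"
    return LDPairStats(
        locus_i=i,
        locus_j=j,
        dprime=float(min(dprime, 1.0)),
        ci_low=ci_low,
        ci_high=ci_high,
        classification=cls,
    )


# ---------------------------------------------------------------------------
# Gabriel block finding
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    chrom: str
    start_idx: int  # locus indices into the full matrix, inclusive
    end_idx: int

    @property
    def n_loci(self) -> int:
        return self.end_idx - self.start_idx + 1

    def locus_indices(self) -> np.ndarray:
        return np.arange(self.start_idx, self.end_idx + 1)


def classify_pairs(
    gm: GenotypeMatrix, config: GabrielConfig | None = None
) -> dict[tuple[int, int], str]:
    """Gabriel classification for every within-chromosome pair inside the
    span window.  Pairs with a monomorphic member are labelled 'inconclusive'
    (they can never be informative)."""
    cfg = config or GabrielConfig()
    chroms = gm.variants["chrom"].to_numpy()
    maf = gm.maf()
    out: dict[tuple[int, int], str] = {}
    for i in range(gm.n_loci):
        for j in range(i + 1, min(i + cfg.max_block_span_loci + 1, gm.n_loci)):
            if chroms[i] != chroms[j]:
                break
            if maf[i] == 0 or maf[j] == 0 or np.isnan(maf[i]) or np.isnan(maf[j]):
                out[(i, j)] = "inconclusive"
                continue
            out[(i, j)] = dprime_ci(gm, i, j, cfg).classification
    return out


def find_blocks(
    gm: GenotypeMatrix, config: GabrielConfig | None = None
) -> list[HaplotypeBlock]:
    """Confidence-interval haplotype blocks.

    A candidate interval [a, b] (same chromosome, at least two loci, span at
    most ``max_block_span_loci``) qualifies when its endpoint pair is in
    strong LD and the strong-LD fraction of informative pairs inside it is at
    least ``min_strong_fraction`` (informative = not inconclusive and both
    MAFs >= ``min_informative_maf``).  Final blocks are chosen greedily by
    descending locus span, ties to the leftmost, discarding overlaps.
    """
    cfg = config or GabrielConfig()
    pairs = classify_pairs(gm, cfg)
    maf = gm.maf()
    chroms = gm.variants["chrom"].to_numpy()

    def informative(i, j):
        return (
            pairs[(i, j)] != "inconclusive"
            and maf[i] >= cfg.min_informative_maf
            and maf[j] >= cfg.min_informative_maf
        )

    candidates = []
    for (a, b), cls in pairs.items():
        if cls != "strong_LD":
            continue
        inf = strong = 0
        for i in range(a, b + 1):
            for jj in range(i + 1, b + 1):
                if informative(i, jj):
                    inf += 1
                    if pairs[(i, jj)] == "strong_LD":
                        strong += 1
        if inf > 0 and strong / inf >= cfg.min_strong_fraction:
            candidates.append((a, b))

    candidates.sort(key=lambda ab: (-(ab[1] - ab[0]), ab[0]))
    taken = np.zeros(gm.n_loci, dtype=bool)
    blocks = []
    for a, b in candidates:
        if taken[a : b + 1].any():
            continue
        taken[a : b + 1] = True
        blocks.append(HaplotypeBlock(chrom=str(chroms[a]), start_idx=a, end_idx=b))
    blocks.sort(key=lambda blk: blk.start_idx)
    return blocks


def blocks_to_frame(gm: GenotypeMatrix, blocks: list[HaplotypeBlock]) -> pd.DataFrame:
    """BED-like table (1-based inclusive positions) for writing as TSV."""
    pos = gm.variants["pos"].to_numpy()
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in blocks],
            "start_pos": [int(pos[b.start_idx]) for b in blocks],
            "end_pos": [int(pos[b.end_idx]) for b in blocks],
            "n_loci": [b.n_loci for b in blocks],
        }
    )


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    """Numeric samples x features matrix tagged with kind and provenance."""

    samples: list[str]
    values: np.ndarray
    feature_names: list[str]
    kind: str  # SNP | HAP | PC
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.feature_names)


def snp_markers(gm: GenotypeMatrix) -> MarkerSet:
    """Plain alt-dosage features, one per SNP (matrix must be imputed)."""
    if np.isnan(gm.dosage).any():
        raise MarkerRepError("impute before building marker features")
    names = [
        f"{c}:{p}" for c, p in zip(gm.variants["chrom"], gm.variants["pos"])
    ]
    return MarkerSet(
        samples=list(gm.samples),
        values=gm.dosage.copy(),
        feature_names=names,
        kind="SNP",
        provenance={"n_snps": gm.n_loci},
    )


def encode_hap_markers(
    gm: GenotypeMatrix,
    blocks: list[HaplotypeBlock],
    min_hap_freq: float = 0.05,
) -> MarkerSet:
    """Numeric haplotype-allele features.

    Within a block, a line with only homozygous (rounded) dosages carries two
    copies of one haplotype allele; each allele with frequency >=
    ``min_hap_freq`` becomes a count column (0/2 for inbred lines), the rest
    pool into one rare column.  Lines heterozygous inside the block are
    ambiguous and contribute the frequency-weighted average dosage, so
    columns still sum to 2.  Loci outside blocks are appended as SNP dosages.
    """
    if np.isnan(gm.dosage).any():
        raise MarkerRepError("impute before building marker features")
    d = np.rint(gm.dosage).astype(int)
    n = gm.n_samples
    cols, names = [], []
    n_block_alleles = 0
    in_block = np.zeros(gm.n_loci, dtype=bool)
    for bi, blk in enumerate(blocks):
        idx = blk.locus_indices()
        in_block[idx] = True
        sub = d[:, idx]
        ambiguous = (sub == 1).any(axis=1)
        patterns: dict[tuple, int] = {}
        line_pattern = np.full(n, -1)
        for s in range(n):
            if ambiguous[s]:
                continue
            pat = tuple(sub[s] // 2)
            line_pattern[s] = patterns.setdefault(pat, len(patterns))
        n_unamb = int((~ambiguous).sum())
        if n_unamb == 0:
            continue
        counts = np.bincount(
            line_pattern[line_pattern >= 0], minlength=len(patterns)
        )
        freqs = counts / n_unamb
        keep = np.flatnonzero(freqs >= min_hap_freq)
        rare = np.flatnonzero(freqs < min_hap_freq)
        block_cols = []
        for ai, pat_idx in enumerate(keep):
            col = np.where(line_pattern == pat_idx, 2.0, 0.0)
            col[ambiguous] = 2.0 * freqs[pat_idx]
            block_cols.append(col)
            names.append(f"HAP{bi + 1}_A{ai + 1}")
        if rare.size:
            col = np.where(np.isin(line_pattern, rare), 2.0, 0.0)
            col[ambiguous] = 2.0 * freqs[rare].sum()
            block_cols.append(col)
            names.append(f"HAP{bi + 1}_rare")
        n_block_alleles += len(block_cols)
        cols.extend(block_cols)
    out_idx = np.flatnonzero(~in_block)
    for j in out_idx:
        cols.append(gm.dosage[:, j].astype(float))
        names.append(f"{gm.variants['chrom'][j]}:{gm.variants['pos'][j]}")
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return MarkerSet(
        samples=list(gm.samples),
        values=values,
        feature_names=names,
        kind="HAP",
        provenance={
            "n_blocks": len(blocks),
            "n_block_allele_columns": n_block_alleles,
            "n_snp_features": int(out_idx.size),
            "min_hap_freq": min_hap_freq,
        },
    )


@dataclass
class PCMarkerSet:
    train: MarkerSet
    test: MarkerSet | None
    n_components: int
    explained_variance_ratio: np.ndarray
    means: np.ndarray
    loadings: np.ndarray


def pc_markers(
    train_gm: GenotypeMatrix,
    test_gm: GenotypeMatrix | None = None,
    var_explained_target: float = 0.95,
) -> PCMarkerSet:
    """PC features fitted on the training matrix only (centered, unscaled);
    N is the smallest count whose cumulative explained variance reaches the
    target.  Test samples are projected with training means and loadings."""
    if np.isnan(train_gm.dosage).any():
        raise MarkerRepError("impute before PCA")
    X = train_gm.dosage
    cap = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=cap, svd_solver="full")
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    hit = np.flatnonzero(cum >= var_explained_target)
    if hit.size == 0:
        warnings.warn(
            f"variance target {var_explained_target} unreachable with "
            f"{cap} components; using all {cap}"
        )
        n_comp = cap
    else:
        n_comp = int(hit[0]) + 1
    names = [f"PC{k + 1}" for k in range(n_comp)]
    train_ms = MarkerSet(
        samples=list(train_gm.samples),
        values=scores[:, :n_comp],
        feature_names=names,
        kind="PC",
        provenance={"var_explained_target": var_explained_target, "n_components": n_comp},
    )
    test_ms = None
    if test_gm is not None:
        if not train_gm.variants[["chrom", "pos", "ref", "alt"]].equals(
            test_gm.variants[["chrom", "pos", "ref", "alt"]]
        ):
            raise MarkerRepError("test matrix not harmonized with training matrix")
        if np.isnan(test_gm.dosage).any():
            raise MarkerRepError("impute before PCA")
        proj = (test_gm.dosage - pca.mean_) @ pca.components_[:n_comp].T
        test_ms = MarkerSet(
            samples=list(test_gm.samples),
            values=proj,
            feature_names=names,
            kind="PC",
            provenance={"projected_from_training": True},
        )
    return PCMarkerSet(
        train=train_ms,
        test=test_ms,
        n_components=n_comp,
        explained_variance_ratio=pca.explained_variance_ratio_[:n_comp],
        means=pca.mean_,
        loadings=pca.components_[:n_comp],
    )
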