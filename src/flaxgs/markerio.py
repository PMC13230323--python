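"""Genotype I/O, quality control, imputation, and cross-population marker harmonization.

Genotypes are held as alt-allele dosages (0/1/2, ``nan`` for missing) for
biallelic SNPs, the canonical representation for genomic prediction.  QC
follows the standard GBS pipeline thresholds: minor allele frequency >= 0.05,
call rate >= 80% and per-SNP heterozygosity <= 20%, with multi-allelic sites
excluded at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


class MarkerIOError(ValueError):
    """Malformed input or incompatible genotype matrices."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci alt-allele dosage matrix with a variant table.

    ``dosage`` is float with values in {0, 1, 2} and ``nan`` for missing calls.
    ``variants`` has columns (chrom, pos, ref, alt), pos 1-based, unique on
    (chrom, pos) and sorted by it.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise MarkerIOError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise MarkerIOError("duplicate sample ids")
        key = self.variants[["chrom", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise MarkerIOError("duplicate (chrom, pos) in variant table")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.variants)

    # --- per-locus statistics (non-missing calls only) ---

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosage), axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt allele frequency among non-missing calls (nan if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def het_fraction(self) -> np.ndarray:
        het = np.nansum(self.dosage == 1, axis=0)
        n = np.sum(~np.isnan(self.dosage), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    # --- subsetting ---

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx],
            meta=dict(self.meta),
        )

    def take_samples(self, ids) -> "GenotypeMatrix":
        pos = {s: k for k, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise MarkerIOError(f"unknown sample ids: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return GenotypeMatrix(
            samples=list(ids),
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :],
            meta=dict(self.meta),
        )

    def variant_keys(self) -> pd.Index:
        return pd.Index(
            self.variants[VARIANT_COLUMNS].itertuples(index=False, name=None)
        )


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT field) into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped; the count is logged and stored in
    ``meta['excluded_multiallelic']``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        gts = var.genotypes  # [[a0, a1, phased], ...]
        d = np.empty(len(samples))
        for k, g in enumerate(gts):
            a = [x for x in g[:-1] if x >= 0]
            d[k] = np.nan if len(a) < 2 else float(sum(a))
        dosages.append(d)
    vcf.close()
    if n_multi:
        logger.info("read_vcf: excluded %d multi-allelic records", n_multi)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = (
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        meta={"excluded_multiallelic": n_multi},
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write integer-dosage genotypes as VCF v4.2 (GT only, "./." missing).

    Fractional (imputed) dosages are not representable; they raise.
    """
    d = gm.dosage
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0))
    if not ok.all():
        raise MarkerIOError("write_vcf requires integer dosages 0/1/2 or missing")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.variants["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            calls = "\t".join(
                "./." if np.isnan(d[i, j]) else _GT_CODE[d[i, j]]
                for i in range(gm.n_samples)
            )
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    min_maf: float = 0.05
    min_call_rate: float = 0.80
    max_het: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "max_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MarkerIOError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_input: int
    removed_call_rate: int
    removed_het: int
    removed_maf: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def qc_filter(
    gm: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Per-locus QC: call rate, then heterozygosity, then MAF (inclusive bounds).

    A removed locus is counted against the first criterion it fails, in that
    order. Statistics use non-missing calls only (QC runs before imputation).
    """
    th = thresholds or QCThresholds()
    cr = gm.call_rate()
    het = gm.het_fraction()
    maf = gm.maf()
    fail_cr = cr < th.min_call_rate
    with np.errstate(invalid="ignore"):
        fail_het = ~fail_cr & (np.nan_to_num(het, nan=1.0) > th.max_het)
        fail_maf = (
            ~fail_cr & ~fail_het & (np.nan_to_num(maf, nan=-1.0) < th.min_maf)
        )
    keep = ~(fail_cr | fail_het | fail_maf)
    report = QCReport(
        n_input=gm.n_loci,
        removed_call_rate=int(fail_cr.sum()),
        removed_het=int(fail_het.sum()),
        removed_maf=int(fail_maf.sum()),
        n_retained=int(keep.sum()),
    )
    return gm.take_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def impute(
    gm: GenotypeMatrix, method: str = "mean_dosage", seed: int | None = None
) -> GenotypeMatrix:
    """Fill missing calls per locus.

    mean_dosage: locus mean of non-missing dosages (fractional values allowed
    downstream, natural for ridge-type predictors). population_mode: most
    frequent dosage, ties broken toward the lower dosage.
    """
    d = gm.dosage.copy()
    n_obs = np.sum(~np.isnan(d), axis=0)
    if np.any(n_obs == 0):
        bad = np.flatnonzero(n_obs == 0)
        raise MarkerIOError(
            f"{len(bad)} loci have no non-missing calls (first index {bad[0]}); "
            "run qc_filter before impute"
        )
    if method == "mean_dosage":
        fill = np.nanmean(d, axis=0)
    elif method == "population_mode":
        counts = np.stack([np.nansum(d == v, axis=0) for v in (0.0, 1.0, 2.0)])
        fill = np.argmax(counts, axis=0).astype(float)  # argmax takes lowest tie
    else:
        raise MarkerIOError(f"unknown imputation method {method!r}")
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(fill, d.shape)[miss]
    out = GenotypeMatrix(
        samples=list(gm.samples),
        variants=gm.variants.copy(),
        dosage=d,
        meta=dict(gm.meta),
    )
    out.meta["imputed"] = method
    return out


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def harmonize(gm_list: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Restrict matrices to loci shared by all, matching (chrom, pos, ref, alt).

    Position matches with swapped or differing ref/alt are dropped (and
    counted in each output's ``meta['harmonize_dropped_allele_mismatch']``);
    no strand flipping is attempted.  Output loci are sorted by (chrom, pos).
    """
    if len(gm_list) < 2:
        raise MarkerIOError("harmonize needs at least two matrices")
    keysets = [set(gm.variant_keys()) for gm in gm_list]
    shared = set.intersection(*keysets)
    if not shared:
        # name the pair with the smallest overlap for the error message
        worst, size = (0, 1), None
        for i in range(len(gm_list)):
            for j in range(i + 1, len(gm_list)):
                ov = len(keysets[i] & keysets[j])
                if size is None or ov < size:
                    worst, size = (i, j), ov
        raise MarkerIOError(
            f"no loci shared by all inputs; smallest pairwise overlap is "
            f"{size} loci (inputs {worst[0]} and {worst[1]})"
        )
    pos_shared = set.intersection(
        *[{(c, p) for c, p, _, _ in ks} for ks in keysets]
    )
    out = []
    for gm in gm_list:
        keys = gm.variant_keys()
        mask = np.array([k in shared for k in keys])
        n_allele_mismatch = int(
            sum((k[0], k[1]) in pos_shared and k not in shared for k in keys)
        )
        sub = gm.take_loci(np.flatnonzero(mask))
        order = np.lexsort((sub.variants["pos"], sub.variants["chrom"]))
        sub = sub.take_loci(order)
        sub.meta["harmonize_dropped_allele_mismatch"] = n_allele_mismatch
        out.append(sub)
    return out
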