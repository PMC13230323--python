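"""Synthetic breeding-population generator.

Emulates the data a deployment-oriented genomic-selection study consumes: a
diverse founder panel with block-structured linkage disequilibrium, biparental
F6 recombinant-inbred-line (RIL) and doubled-haploid (DH) populations derived
by explicit meiosis, an additive polygenic yield trait, replicated
multi-experiment field trials with shared checks, and GBS-style genotyping
noise (missingness and call errors).

Founder haplotypes come from a sequential Markov copying process: after
``n_seed`` independent seed haplotypes, each new haplotype is a mosaic of
previously generated ones, switching template at ``copying_rate`` per Morgan
with a small per-locus mutation probability.  Nearby loci therefore share
template segments (LD decaying with map distance), which is what the
haplotype-block machinery downstream needs.  Meiosis uses the Haldane model:
crossover counts Poisson in the chromosome map length, positions uniform, no
interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markerio import GenotypeMatrix


class SimulationParameterError(ValueError):
    pass


class DegenerateSimulationError(RuntimeError):
    """The generator produced no polymorphic loci (e.g. copying with a
    single seed haplotype and no mutation)."""


# ---------------------------------------------------------------------------
# Founder panel
# ---------------------------------------------------------------------------

@dataclass
class FounderPanel:
    """2*n_founders x n_loci binary haplotypes plus map and variant table."""

    haplotypes: np.ndarray  # uint8, (2*n_founders, n_loci)
    genetic_map: pd.DataFrame  # chrom, pos, morgans
    variants: pd.DataFrame  # chrom, pos, ref, alt
    sample_ids: list[str]
    meta: dict = field(default_factory=dict)

    @property
    def n_founders(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def founder_haplotypes(self, founder_id: str) -> np.ndarray:
        i = self.sample_ids.index(founder_id)
        return self.haplotypes[2 * i : 2 * i + 2]

    def to_genotype_matrix(self) -> GenotypeMatrix:
        dos = (
            self.haplotypes[0::2].astype(float)
            + self.haplotypes[1::2].astype(float)
        )
        return GenotypeMatrix(
            samples=list(self.sample_ids),
            variants=self.variants.copy(),
            dosage=dos,
            meta={"source": "simulated_founders"},
        )


def expected_pi(maf_low: float, maf_high: float) -> float:
    """Mean 2p(1-p) when alt frequency ~ Uniform(maf_low, maf_high) — the
    diversity target the founder generator is configured against."""
    # E[2p(1-p)] = 2(E p - E p^2) with p uniform
    m = (maf_low + maf_high) / 2.0
    v = (maf_high - maf_low) ** 2 / 12.0
    return 2.0 * (m - (v + m * m))


def simulate_founders(
    n_founders: int,
    n_loci: int,
    n_chrom: int = 5,
    target_maf_dist: tuple[float, float] = (0.1, 0.5),
    copying_rate: float = 0.1,
    mutation_rate: float = 0.001,
    n_seed: int = 16,
    chrom_length_morgans: float = 1.5,
    seed: int = 0,
) -> FounderPanel:
    """Simulate a diverse founder collection with LD decaying along the map.

    Monomorphic loci are dropped from the returned panel; if none remain the
    output is flagged degenerate via :class:`DegenerateSimulationError`.
    """
    if n_founders < 2 or n_loci < n_chrom or n_chrom < 1:
        raise SimulationParameterError(
            f"need n_founders >= 2 and n_loci >= n_chrom >= 1, got "
            f"({n_founders}, {n_loci}, {n_chrom})"
        )
    if n_seed < 1:
        raise SimulationParameterError("n_seed must be >= 1")
    rng = np.random.default_rng(seed)

    # map: loci spread over n_chrom chromosomes, uniform positions
    per_chrom = np.full(n_chrom, n_loci // n_chrom)
    per_chrom[: n_loci % n_chrom] += 1
    chroms, morgans = [], []
    for c in range(n_chrom):
        pos = np.sort(rng.uniform(0.0, chrom_length_morgans, per_chrom[c]))
        chroms.extend([f"chr{c + 1}"] * per_chrom[c])
        morgans.extend(pos)
    chrom_arr = np.array(chroms)
    morgan_arr = np.array(morgans)

    lo, hi = target_maf_dist
    p = rng.uniform(lo, hi, n_loci)

    # founders are inbred accessions (selfing crop): one distinct haplotype
    # per founder, doubled below
    n_hap = n_founders
    haps = np.zeros((n_hap, n_loci), dtype=np.uint8)
    k0 = min(n_seed, n_hap)
    haps[:k0] = rng.random((k0, n_loci)) < p

    # per-locus template-switch probability from map gap (Haldane-style)
    gaps = np.zeros(n_loci)
    for c in range(n_chrom):
        m = chrom_arr == f"chr{c + 1}"
        g = np.diff(morgan_arr[m], prepend=np.nan)
        g[0] = np.inf  # new chromosome: always re-draw template
        gaps[m] = g
    switch_p = 1.0 - np.exp(-copying_rate * gaps)
    switch_p[np.isinf(gaps)] = 1.0

    for h in range(k0, n_hap):
        switches = rng.random(n_loci) < switch_p
        switches[0] = True
        seg_ids = np.cumsum(switches) - 1
        templates = rng.integers(0, h, seg_ids[-1] + 1)
        hap = haps[templates[seg_ids], np.arange(n_loci)]
        if mutation_rate > 0:
            flip = rng.random(n_loci) < mutation_rate
            hap = np.where(flip, 1 - hap, hap)
        haps[h] = hap

    poly = haps.min(axis=0) != haps.max(axis=0)
    if not poly.any():
        raise DegenerateSimulationError(
            "no polymorphic loci generated; increase n_seed or mutation_rate"
        )
    haps = np.repeat(haps[:, poly], 2, axis=0)  # doubled: fully inbred lines
    chrom_arr = chrom_arr[poly]
    morgan_arr = morgan_arr[poly]

    bp = (morgan_arr * 1e6).round().astype(int) + 1
    # enforce unique, strictly increasing positions within chromosomes
    for c in np.unique(chrom_arr):
        m = chrom_arr == c
        bp[m] = np.maximum.accumulate(bp[m] + np.arange(m.sum()))
    ref_alt = rng.choice(list("ACGT"), size=(poly.sum(), 2))
    same = ref_alt[:, 0] == ref_alt[:, 1]
    ref_alt[same, 1] = np.where(ref_alt[same, 0] == "A", "G", "A")

    variants = pd.DataFrame(
        {"chrom": chrom_arr, "pos": bp, "ref": ref_alt[:, 0], "alt": ref_alt[:, 1]}
    )
    genetic_map = pd.DataFrame(
        {"chrom": chrom_arr, "pos": bp, "morgans": morgan_arr}
    )
    ids = [f"F{i + 1:04d}" for i in range(n_founders)]
    return FounderPanel(
        haplotypes=haps,
        genetic_map=genetic_map,
        variants=variants,
        sample_ids=ids,
        meta={
            "seed": seed,
            "n_dropped_monomorphic": int((~poly).sum()),
            "target_pi": expected_pi(lo, hi),
        },
    )


# ---------------------------------------------------------------------------
# Meiosis and biparental populations
# ---------------------------------------------------------------------------

def _gamete(
    hap_pair: np.ndarray,
    chrom_arr: np.ndarray,
    morgan_arr: np.ndarray,
    chrom_ids: np.ndarray,
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product under the Haldane model (Poisson crossovers,
    uniform positions, no interference)."""
    out = np.empty(hap_pair.shape[1], dtype=np.uint8)
    for c, length in zip(chrom_ids, chrom_lengths):
        m = chrom_arr == c
        pos = morgan_arr[m]
        n_xo = rng.poisson(length)
        cur = rng.integers(0, 2)
        if n_xo == 0:
            out[m] = hap_pair[cur, m]
            continue
        xo = np.sort(rng.uniform(0.0, length, n_xo))
        phase = (cur + np.searchsorted(xo, pos)) % 2
        idx = np.flatnonzero(m)
        out[idx] = hap_pair[phase, idx]
    return out


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame  # line, parentA, parentB, scheme
    haplotypes: np.ndarray | None = None  # (2*n_lines, n_loci)
    true_bv: np.ndarray | None = None
    trait: "TraitArchitecture | None" = None
    genetic_map: pd.DataFrame | None = None

    @property
    def line_ids(self) -> list[str]:
        return self.genotypes.samples


def make_biparental(
    panel: FounderPanel,
    parentA: str,
    parentB: str,
    scheme: str,
    n_lines: int,
    seed: int = 0,
    prefix: str | None = None,
) -> SimulatedPopulation:
    """Derive a biparental population from one F1 of two founders.

    RIL_F6: the F1 is selfed generation by generation to the F6 (five selfing
    steps), both haplotypes tracked, so residual heterozygosity (~1/2^5 at
    F1-heterozygous loci) and breakpoint density emerge mechanically.
    DH: a single F1 gamete is doubled, forcing homozygosity everywhere.
    """
    if scheme not in ("RIL_F6", "DH"):
        raise SimulationParameterError(f"unknown scheme {scheme!r}")
    for pid in (parentA, parentB):
        if pid not in panel.sample_ids:
            raise KeyError(f"parent {pid!r} not in founder panel")
    rng = np.random.default_rng(seed)
    chrom_arr = panel.genetic_map["chrom"].to_numpy()
    morgan_arr = panel.genetic_map["morgans"].to_numpy()
    chrom_ids = pd.unique(panel.genetic_map["chrom"])
    chrom_lengths = np.array(
        [morgan_arr[chrom_arr == c].max() for c in chrom_ids]
    )
    args = (chrom_arr, morgan_arr, chrom_ids, chrom_lengths, rng)

    hapA = panel.founder_haplotypes(parentA)
    hapB = panel.founder_haplotypes(parentB)
    f1 = np.stack([_gamete(hapA, *args), _gamete(hapB, *args)])

    n_loci = panel.n_loci
    haps = np.empty((2 * n_lines, n_loci), dtype=np.uint8)
    for i in range(n_lines):
        if scheme == "DH":
            g = _gamete(f1, *args)
            haps[2 * i] = g
            haps[2 * i + 1] = g
        else:
            ind = f1
            for _ in range(5):  # F1 -> F6
                ind = np.stack([_gamete(ind, *args), _gamete(ind, *args)])
            haps[2 * i] = ind[0]
            haps[2 * i + 1] = ind[1]

    prefix = prefix or f"{parentA}x{parentB}_{scheme}"
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n_lines)]
    dosage = haps[0::2].astype(float) + haps[1::2].astype(float)
    gm = GenotypeMatrix(
        samples=ids,
        variants=panel.variants.copy(),
        dosage=dosage,
        meta={"source": f"simulated_{scheme}", "seed": seed},
    )
    pedigree = pd.DataFrame(
        {"line": ids, "parentA": parentA, "parentB": parentB, "scheme": scheme}
    )
    return SimulatedPopulation(
        genotypes=gm,
        pedigree=pedigree,
        haplotypes=haps,
        genetic_map=panel.genetic_map.copy(),
    )


def population_from_panel(panel: FounderPanel) -> SimulatedPopulation:
    """Wrap the founder panel itself as a population (scheme FOUNDER)."""
    gm = panel.to_genotype_matrix()
    pedigree = pd.DataFrame(
        {
            "line": gm.samples,
            "parentA": None,
            "parentB": None,
            "scheme": "FOUNDER",
        }
    )
    return SimulatedPopulation(
        genotypes=gm,
        pedigree=pedigree,
        haplotypes=panel.haplotypes,
        genetic_map=panel.genetic_map.copy(),
    )


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    h2: float
    sigma_g2: float
    sigma_e2: float
    sigma_gxe2: float

    def __post_init__(self) -> None:
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise SimulationParameterError("qtl_indices must be unique")
        tot = self.sigma_g2 + self.sigma_e2 + self.sigma_gxe2
        if tot > 0 and abs(self.h2 - self.sigma_g2 / tot) > 1e-9:
            raise SimulationParameterError(
                "variance components inconsistent with h2"
            )

    def entry_mean_h2(self, n_plots: int, n_env: int = 1) -> float:
        """Heritability of line means over n_plots total plots spread across
        n_env environments (G x E averages over environments, residual over
        plots)."""
        denom = (
            self.sigma_g2
            + self.sigma_gxe2 / n_env
            + self.sigma_e2 / n_plots
        )
        return self.sigma_g2 / denom if denom > 0 else 1.0


def assign_trait(
    pop: SimulatedPopulation,
    n_qtl: int,
    h2: float,
    effect_dist: str = "normal",
    gxe_fraction: float = 0.0,
    seed: int = 0,
) -> TraitArchitecture:
    """Sample an additive polygenic trait; fills ``pop.true_bv`` (centered).

    Non-genetic variance is scaled so the plot-level narrow-sense h2 matches
    the request exactly; ``gxe_fraction`` of it is labelled G x E.
    """
    if not 0.0 < h2 <= 1.0:
        raise SimulationParameterError(f"h2={h2} outside (0, 1]")
    n_loci = pop.genotypes.n_loci
    if n_qtl > n_loci:
        raise SimulationParameterError("n_qtl exceeds available loci")
    rng = np.random.default_rng(seed)
    qtl = rng.choice(n_loci, size=n_qtl, replace=False)
    qtl.sort()
    if effect_dist == "normal":
        eff = rng.standard_normal(n_qtl)
    elif effect_dist == "laplace":
        eff = rng.laplace(size=n_qtl)
    else:
        raise SimulationParameterError(f"unknown effect_dist {effect_dist!r}")
    bv = pop.genotypes.dosage[:, qtl] @ eff
    bv = bv - bv.mean()
    sigma_g2 = float(bv.var())
    if sigma_g2 == 0.0:
        raise DegenerateSimulationError("all QTL monomorphic; true_bv constant")
    nongen = sigma_g2 * (1.0 - h2) / h2
    trait = TraitArchitecture(
        qtl_indices=qtl,
        qtl_effects=eff,
        h2=h2,
        sigma_g2=sigma_g2,
        sigma_gxe2=gxe_fraction * nongen,
        sigma_e2=(1.0 - gxe_fraction) * nongen,
    )
    pop.true_bv = bv
    pop.trait = trait
    return trait


# ---------------------------------------------------------------------------
# Multi-experiment trials
# ---------------------------------------------------------------------------

@dataclass
class TrialPlan:
    """Multi-subset RCBD plan with shared checks in every experiment."""

    n_experiments: int = 8
    lines_per_experiment: int = 37
    checks: tuple[str, ...] = ()
    reps_per_experiment: int = 2
    locations: tuple[str, ...] = ("LOC1",)
    years: tuple[int, ...] = (2025,)
    mu: float = 0.0
    block_sd: float = 0.0
    loc_sd: float = 0.0
    year_sd: float = 0.0
    gxe_sd: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.reps_per_experiment < 1:
            raise SimulationParameterError("reps_per_experiment must be >= 1")
        if self.n_experiments < 1 or self.lines_per_experiment < 1:
            raise SimulationParameterError("empty trial plan")

    @property
    def entries_per_experiment(self) -> int:
        return self.lines_per_experiment + len(self.checks)


def plan_for_trait(trait: TraitArchitecture, **kwargs) -> TrialPlan:
    """TrialPlan whose noise SDs realize the trait's variance components."""
    kwargs.setdefault("residual_sd", float(np.sqrt(trait.sigma_e2)))
    kwargs.setdefault("gxe_sd", float(np.sqrt(trait.sigma_gxe2)))
    return TrialPlan(**kwargs)


def simulate_trials(
    pop: SimulatedPopulation, plan: TrialPlan, seed: int = 0
) -> pd.DataFrame:
    """One plot record per entry x experiment x rep.

    value = mu + true_bv + year + location + G x E + block + residual, each
    component drawn from its configured SD.  Checks appear in every
    experiment; the remaining lines are split across experiments in order.
    Returns a PhenotypeRecords table (line, experiment, location, year,
    block, value).
    """
    if pop.true_bv is None:
        raise SimulationParameterError("assign_trait before simulate_trials")
    rng = np.random.default_rng(seed)
    ids = pop.line_ids
    bv = dict(zip(ids, pop.true_bv))
    checks = list(plan.checks)
    for c in checks:
        if c not in bv:
            raise KeyError(f"check {c!r} not in population")
    test_lines = [s for s in ids if s not in set(checks)]
    need = plan.n_experiments * plan.lines_per_experiment
    if len(test_lines) < need:
        raise SimulationParameterError(
            f"plan needs {need} non-check lines, population has {len(test_lines)}"
        )
    loc_eff = {l: rng.normal(0.0, plan.loc_sd) for l in plan.locations}
    year_eff = {y: rng.normal(0.0, plan.year_sd) for y in plan.years}
    gxe_eff: dict[tuple[str, str], float] = {}
    rows = []
    for e in range(plan.n_experiments):
        exp_id = f"EXP{e + 1}"
        loc = plan.locations[e % len(plan.locations)]
        year = plan.years[e % len(plan.years)]
        entries = (
            test_lines[
                e * plan.lines_per_experiment : (e + 1) * plan.lines_per_experiment
            ]
            + checks
        )
        for rep in range(1, plan.reps_per_experiment + 1):
            block_eff = rng.normal(0.0, plan.block_sd)
            for line in entries:
                key = (line, loc)
                if key not in gxe_eff:
                    gxe_eff[key] = rng.normal(0.0, plan.gxe_sd)
                value = (
                    plan.mu
                    + bv[line]
                    + year_eff[year]
                    + loc_eff[loc]
                    + gxe_eff[key]
                    + block_eff
                    + rng.normal(0.0, plan.residual_sd)
                )
                rows.append((line, exp_id, loc, year, rep, value))
    return pd.DataFrame(
        rows, columns=["line", "experiment", "location", "year", "block", "value"]
    )


# ---------------------------------------------------------------------------
# GBS noise
# ---------------------------------------------------------------------------

def apply_gbs_noise(
    gm: GenotypeMatrix,
    missing_rate: float = 0.3,
    error_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Independently drop calls to missing and flip retained calls to a
    random other dosage; the variant table is unchanged."""
    if not (0.0 <= missing_rate <= 1.0 and 0.0 <= error_rate <= 1.0):
        raise SimulationParameterError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d = gm.dosage.copy()
    miss = rng.random(d.shape) < missing_rate
    if error_rate > 0:
        err = (rng.random(d.shape) < error_rate) & ~miss & ~np.isnan(d)
        shift = rng.integers(1, 3, size=d.shape)  # +1 or +2 mod 3: other dosage
        d[err] = (d[err] + shift[err]) % 3
    d[miss] = np.nan
    return GenotypeMatrix(
        samples=list(gm.samples),
        variants=gm.variants.copy(),
        dosage=d,
        meta={**gm.meta, "gbs_noise": (missing_rate, error_rate, seed)},
    )
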