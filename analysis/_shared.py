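"""Shared configuration for the analysis drivers.

The study system: a diverse founder collection (the training panel), two
biparental populations (an F6-RIL and a DH cross), and a breeding population
evaluated in a multi-subset RCBD trial with shared checks.  Every driver
regenerates what it needs from these seeds, so each step is reproducible in
isolation; bulky intermediates live in scratch/, small result tables in
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

MASTER_SEED = 20260101

# founder panel emulating a genotyped core collection
N_FOUNDERS = 301  # 296 breeding lines + 5 checks -> eight 37-line subsets
N_LOCI = 2000

# biparental test populations
RIL_PARENTS = ("F0001", "F0002")
DH_PARENTS = ("F0003", "F0004")
N_RIL = 91
N_DH = 76

# trait: polygenic seed yield surrogate
N_QTL = 500
H2 = 0.8


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def make_panel():
    from flaxgs import simpop

    return simpop.simulate_founders(N_FOUNDERS, N_LOCI, seed=MASTER_SEED)


def make_trait_population(panel):
    from flaxgs import simpop

    pop = simpop.population_from_panel(panel)
    trait = simpop.assign_trait(pop, N_QTL, h2=H2, seed=MASTER_SEED + 1)
    return pop, trait
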