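"""Simulate the study populations and field trials.

Builds the founder panel (training collection), an F6-RIL and a DH
biparental population, assigns a polygenic yield trait, runs the
multi-subset RCBD trial with five shared checks twice (two independent seed
sources), and applies GBS-style genotyping noise to the breeding material.
Writes VCFs and phenotype CSVs to scratch/, and a population summary to
results/population_summary.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import _shared
from flaxgs import markerio, simpop


def main():
    _shared.ensure_dirs()
    panel = _shared.make_panel()
    pop, trait = _shared.make_trait_population(panel)

    ril = simpop.make_biparental(
        panel, *_shared.RIL_PARENTS, "RIL_F6", _shared.N_RIL,
        seed=_shared.MASTER_SEED + 2,
    )
    dh = simpop.make_biparental(
        panel, *_shared.DH_PARENTS, "DH", _shared.N_DH,
        seed=_shared.MASTER_SEED + 3,
    )

    plan = simpop.plan_for_trait(
        trait,
        n_experiments=8,
        lines_per_experiment=37,
        checks=tuple(pop.line_ids[:5]),
        reps_per_experiment=2,
    )
    rec_a = simpop.simulate_trials(pop, plan, seed=_shared.MASTER_SEED + 4)
    rec_b = simpop.simulate_trials(pop, plan, seed=_shared.MASTER_SEED + 5)

    gbs = simpop.apply_gbs_noise(
        pop.genotypes, missing_rate=0.10, error_rate=0.002,
        seed=_shared.MASTER_SEED + 6,
    )

    out = _shared.SCRATCH
    markerio.write_vcf(panel.to_genotype_matrix(), out / "founders.vcf")
    markerio.write_vcf(ril.genotypes, out / "ril.vcf")
    markerio.write_vcf(dh.genotypes, out / "dh.vcf")
    markerio.write_vcf(gbs, out / "founders_gbs.vcf")
    rec_a.to_csv(out / "trials_sourceA.csv", index=False)
    rec_b.to_csv(out / "trials_sourceB.csv", index=False)
    np.save(out / "true_bv.npy", pop.true_bv)
    pd.Series(pop.line_ids).to_csv(out / "line_ids.csv", index=False, header=False)

    summary = pd.DataFrame(
        [
            ("founder_panel", panel.n_founders, panel.n_loci, "FOUNDER"),
            ("ril_population", _shared.N_RIL, panel.n_loci, "RIL_F6"),
            ("dh_population", _shared.N_DH, panel.n_loci, "DH"),
        ],
        columns=["population", "n_lines", "n_loci", "scheme"],
    )
    summary.to_csv(_shared.RESULTS / "population_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\ntrial records per seed source: {len(rec_a)} "
        f"({plan.entries_per_experiment} entries x {plan.reps_per_experiment} reps "
        f"x {plan.n_experiments} experiments)"
    )
    print(f"trait: {_shared.N_QTL} QTL, plot-level h2 = {trait.h2}")


if __name__ == "__main__":
    main()
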