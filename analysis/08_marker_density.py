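"""Marker-density subsampling study.

How many SNPs does across-population prediction need?  Random SNP subsets of
increasing size (10 replicates per bin), panel-trained RR-BLUP predicting
the RIL population; the plateau bin is the smallest reaching 99% of the best
mean PA.  Writes results/marker_density_curve.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import _shared
from flaxgs import evaluate, simpop


def main():
    _shared.ensure_dirs()
    panel = _shared.make_panel()
    pop, trait = _shared.make_trait_population(panel)
    ril = simpop.make_biparental(
        panel, *_shared.RIL_PARENTS, "RIL_F6", _shared.N_RIL,
        seed=_shared.MASTER_SEED + 2,
    )
    rng = np.random.default_rng(_shared.MASTER_SEED + 8)
    y_train = pop.true_bv + rng.normal(
        0, np.sqrt(trait.sigma_e2 / 2), len(pop.true_bv)
    )
    bv_test = ril.genotypes.dosage[:, trait.qtl_indices] @ trait.qtl_effects
    y_test = bv_test + rng.normal(0, np.sqrt(trait.sigma_e2 / 2), len(bv_test))

    n_loci = pop.genotypes.n_loci
    grid = np.arange(250, n_loci + 1, 250)
    curve = evaluate.marker_subsample_curve(
        pop.genotypes, y_train, ril.genotypes, y_test,
        {"rrblup": "rrblup"}, grid=grid, reps=10, seed=_shared.MASTER_SEED,
    )
    table = curve.to_frame()
    table.to_csv(_shared.RESULTS / "marker_density_curve.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"\nplateau (99% of best mean PA): {curve.plateau['rrblup']} SNPs")


if __name__ == "__main__":
    main()
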