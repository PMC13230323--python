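"""Within-population cross-validation of the linear prediction engines.

Five-fold CV on the founder panel's merged BLUPs: RR-BLUP and GBLUP over all
SNPs with the full 10-partition scheme (50 replicate evaluations), the
costlier elastic net, Bayesian ridge and stacking ensemble over a random
SNP subset with 2 partitions, plus PC features refit inside every training
fold.  Writes results/cv_predictive_ability.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import _shared
from flaxgs import evaluate, markerio, markerrep
from flaxgs.predict import BayesianRidge, RegularizedRegression, RRBLUP, StackingEnsemble


def main():
    _shared.ensure_dirs()
    src = _shared.SCRATCH
    if not (src / "merged_blups.csv").exists():
        sys.exit("run 05_phenotype_analysis.py first")

    gm = markerio.read_vcf(src / "founders.vcf")
    blups = pd.read_csv(src / "merged_blups.csv").set_index("line")["estimate"]
    keep = [s for s in gm.samples if s in blups.index]
    gm = gm.take_samples(keep)
    y = blups[keep].to_numpy()
    X = gm.dosage

    scheme = evaluate.make_cv_scheme(
        len(y), k=5, partitions=10, seed=_shared.MASTER_SEED
    )
    light = evaluate.CVScheme(
        k=scheme.k, n_partitions=2, seed=scheme.seed, folds=scheme.folds[:2]
    )
    # expensive samplers run on a random SNP subset (marker-density study
    # shows a few hundred SNPs already reach the PA plateau here)
    rng = np.random.default_rng(_shared.MASTER_SEED + 9)
    sub = np.sort(rng.choice(gm.n_loci, size=min(400, gm.n_loci), replace=False))
    Xsub = X[:, sub]

    def enet():
        return RegularizedRegression(alpha=0.5, lambda_grid=np.logspace(-2, 1, 5))

    runs = [
        ("rrblup", "SNP", X, "rrblup", scheme),
        ("gblup", "SNP", X, "gblup", scheme),
        ("elasticnet", "SNP_sub400", Xsub, enet, light),
        ("brr", "SNP_sub400", Xsub,
         lambda: BayesianRidge(iters=300, burn_in=100, seed=1), light),
        ("ensemble", "SNP_sub400", Xsub,
         lambda: StackingEnsemble(base_factories=[lambda: RRBLUP(), enet], seed=1),
         light),
    ]
    rows = []
    for name, markers, Xr, spec, sch in runs:
        res = evaluate.run_cv(Xr, y, spec, sch)
        rows.append((name, markers, len(res.replicate_pa), res.mean_pa, res.sd_pa))
        print(f"{name:10s} {markers:10s} mean PA {res.mean_pa:.3f} +- {res.sd_pa:.3f}")

    def pc_featurizer(markers, tr, te):
        train_gm = gm.take_samples([keep[i] for i in tr])
        test_gm = gm.take_samples([keep[i] for i in te])
        pcs = markerrep.pc_markers(train_gm, test_gm)
        return pcs.train.values, pcs.test.values

    res = evaluate.run_cv(X, y, "rrblup", light, featurizer=pc_featurizer)
    rows.append(("rrblup", "PC", len(res.replicate_pa), res.mean_pa, res.sd_pa))
    print(f"{'rrblup':10s} {'PC':10s} mean PA {res.mean_pa:.3f} +- {res.sd_pa:.3f}")

    table = pd.DataFrame(
        rows, columns=["model", "markers", "n_replicates", "mean_pa", "sd_pa"]
    )
    table.to_csv(
        _shared.RESULTS / "cv_predictive_ability.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
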