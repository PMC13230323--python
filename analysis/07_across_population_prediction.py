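"""Across-population prediction (APP): panel-trained models predict the
biparental RIL and DH populations.

This is the deployment scenario: the model never sees the test population.
Phenotypes for the test populations are fresh 2-rep trial means.  Writes
results/app_predictive_ability.tsv and scratch GEBVs for the decision step.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import _shared
from flaxgs import evaluate, markerio, simpop
from flaxgs.markerrep import snp_markers
from flaxgs.predict import make_model


def main():
    _shared.ensure_dirs()
    src = _shared.SCRATCH
    if not (src / "merged_blups.csv").exists():
        sys.exit("run 05_phenotype_analysis.py first")

    panel = _shared.make_panel()
    pop, trait = _shared.make_trait_population(panel)
    blups = pd.read_csv(src / "merged_blups.csv").set_index("line")["estimate"]
    keep = [s for s in pop.line_ids if s in blups.index]
    train_gm = pop.genotypes.take_samples(keep)
    y_train = blups[keep].to_numpy()

    rows = []
    gebv_tables = []
    for name, parents, scheme_kind, n in (
        ("ril", _shared.RIL_PARENTS, "RIL_F6", _shared.N_RIL),
        ("dh", _shared.DH_PARENTS, "DH", _shared.N_DH),
    ):
        test_pop = simpop.make_biparental(
            panel, *parents, scheme_kind, n,
            seed=_shared.MASTER_SEED + (2 if name == "ril" else 3),
        )
        bv = test_pop.genotypes.dosage[:, trait.qtl_indices] @ trait.qtl_effects
        rng = np.random.default_rng(_shared.MASTER_SEED + 7)
        y_test = bv + rng.normal(0, np.sqrt(trait.sigma_e2 / 2), len(bv))
        from flaxgs.predict import RegularizedRegression

        model_specs = {
            "rrblup": "rrblup",
            "gblup": "gblup",
            "elasticnet": lambda: RegularizedRegression(
                alpha=0.5, lambda_grid=np.logspace(-2, 1, 5)
            ),
        }
        for model, spec in model_specs.items():
            res = evaluate.run_app(
                snp_markers(train_gm), y_train,
                snp_markers(test_pop.genotypes), y_test, spec,
            )
            rows.append((name, model, res.provenance["shared_markers"], res.mean_pa))
            print(f"{name:4s} {model:10s} PA {res.mean_pa:.3f}")
        fit = make_model("rrblup").fit(snp_markers(train_gm), y_train)
        gebv = fit.predict(snp_markers(test_pop.genotypes)).gebv
        gebv_tables.append(
            pd.DataFrame(
                {
                    "population": name,
                    "line": test_pop.line_ids,
                    "observed": y_test,
                    "gebv": gebv,
                }
            )
        )

    table = pd.DataFrame(rows, columns=["test_population", "model", "n_markers", "pa"])
    table.to_csv(_shared.RESULTS / "app_predictive_ability.tsv", sep="\t", index=False)
    pd.concat(gebv_tables).to_csv(src / "app_gebvs.csv", index=False)


if __name__ == "__main__":
    main()
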