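"""Quality-control the genotype matrices and harmonize marker sets.

Reads the VCFs written by 01, applies the standard GBS thresholds
(MAF >= 0.05, call rate >= 0.80, per-SNP heterozygosity <= 0.20),
mean-dosage imputes the survivors, and harmonizes the founder panel with the
biparental test populations to the shared-locus set used for
across-population prediction.  Writes results/qc_report.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

import _shared
from flaxgs import markerio


def main():
    _shared.ensure_dirs()
    out = _shared.SCRATCH
    if not (out / "founders.vcf").exists():
        sys.exit("run 01_simulate_populations.py first")

    rows = []
    matrices = {}
    for name in ("founders", "founders_gbs", "ril", "dh"):
        gm = markerio.read_vcf(out / f"{name}.vcf")
        filtered, rep = markerio.qc_filter(gm)
        imputed = markerio.impute(filtered, "mean_dosage")
        matrices[name] = imputed
        rows.append(
            (
                name,
                rep.n_input,
                rep.removed_call_rate,
                rep.removed_het,
                rep.removed_maf,
                rep.n_retained,
            )
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "population", "n_input", "removed_call_rate", "removed_het",
            "removed_maf", "n_retained",
        ],
    )
    report.to_csv(_shared.RESULTS / "qc_report.tsv", sep="\t", index=False)
    print(report.to_string(index=False))

    shared = markerio.harmonize(
        [matrices["founders"], matrices["ril"], matrices["dh"]]
    )
    print(f"\nshared loci across founder/RIL/DH after harmonization: {shared[0].n_loci}")
    for name, gm in zip(("founders_h", "ril_h", "dh_h"), shared):
        markerio.write_vcf(gm, out / f"{name}.vcf")


if __name__ == "__main__":
    main()
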