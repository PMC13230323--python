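"""Population diversity and differentiation.

Nucleotide diversity (pi) per population and pairwise Weir-Cockerham FST on
the harmonized marker set: the founder panel should show the highest
diversity, the biparental RIL/DH populations much lower diversity and strong
differentiation from the panel.  Writes results/diversity.tsv and
results/fst_matrix.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

import _shared
from flaxgs import markerio, popstats


def main():
    _shared.ensure_dirs()
    src = _shared.SCRATCH
    if not (src / "founders_h.vcf").exists():
        sys.exit("run 02_marker_qc.py first")
    pops = {
        name: markerio.read_vcf(src / f"{name}_h.vcf")
        for name in ("founders", "ril", "dh")
    }

    div_rows = [
        (name, gm.n_samples, res.n_loci, round(res.mean_pi, 4))
        for name, gm in pops.items()
        for res in [popstats.nucleotide_diversity(gm)]
    ]
    diversity = pd.DataFrame(
        div_rows, columns=["population", "n_lines", "n_loci", "mean_pi"]
    )
    diversity.to_csv(_shared.RESULTS / "diversity.tsv", sep="\t", index=False)
    print(diversity.to_string(index=False))

    names = list(pops)
    fst = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            v = popstats.pairwise_fst(pops[a], pops[b]).fst
            fst.loc[a, b] = fst.loc[b, a] = round(v, 4)
    fst.to_csv(_shared.RESULTS / "fst_matrix.tsv", sep="\t")
    print("\npairwise Weir-Cockerham FST:")
    print(fst.to_string())


if __name__ == "__main__":
    main()
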