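import numpy as np
import pandas as pd
import pytest

from flaxgs import simpop
from flaxgs.markerio import GenotypeMatrix


def make_gm(dosage, chrom="chr1", samples=None, pos=None) -> GenotypeMatrix:
    """Small helper: wrap a dosage array in a GenotypeMatrix."""
    d = np.asarray(dosage, dtype=float)
    n, p = d.shape
    samples = samples or [f"s{i}" for i in range(n)]
    pos = pos if pos is not None else np.arange(1, p + 1) * 100
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=d)


@pytest.fixture(scope="session")
def founder_panel():
    """Mid-sized founder panel shared across tests (seeded, deterministic)."""
    return simpop.simulate_founders(n_founders=120, n_loci=600, seed=11)


@pytest.fixture(scope="session")
def trait_population(founder_panel):
    """Founder panel as a population with an additive trait (h2=0.8)."""
    pop = simpop.population_from_panel(founder_panel)
    simpop.assign_trait(pop, n_qtl=100, h2=0.8, seed=12)
    return pop
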