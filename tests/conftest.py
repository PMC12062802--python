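import numpy as np
import pytest

from hircus.core_io import GenotypeMatrix, SnpLocus
from hircus.synthetic_data import SimConfig, simulate_genotypes, simulate_traits

# printed marker-characterisation reference: genotype count triples per locus
TABLE4_COUNTS = {
    "g.18413T>C": (21, 80, 52),
    "g.15523T>C": (22, 80, 51),
    "g.15530G>C": (22, 83, 48),
    "g.19711G>A": (18, 80, 55),
}


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (153 animals, 78M/75F, 4 linked SNPs)."""
    cfg = SimConfig(seed=1)
    gm = simulate_genotypes(cfg, seed=1)
    traits = simulate_traits(gm, cfg, seed=1)
    return cfg, gm, traits


def make_matrix(dosage, sex=None, n_loci=None, loci=None):
    """Small GenotypeMatrix from a dosage array for unit tests."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, L = dosage.shape
    if loci is None:
        bases = [("T", "C"), ("G", "C"), ("A", "G"), ("C", "T"), ("G", "A")]
        loci = [
            SnpLocus(f"L{j}", *bases[j % len(bases)]) for j in range(L)
        ]
    if sex is None:
        sex = ["male" if i % 2 == 0 else "female" for i in range(n)]
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(loci, ids, list(sex), dosage)
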