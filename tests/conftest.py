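import numpy as np
import pytest

from domscan.simulate import HybridSpec, SimulationConfig, simulate_cohort
from domscan.types import GenotypeMatrix, VariantSite

# Published admixture proportions (percent or fractions, as printed) for a
# 30-accession avocado cohort over the Guatemalan/Mexican/Lowland groups,
# with the group each accession is expected to classify into at Qi > 0.80.
ACCESSION_TABLE = [
    ("069-02", {"Guatemalan": 37.61, "Mexican": 62.39, "Lowland": 0.00}, "admixed"),
    ("263-C", {"Guatemalan": 0.00, "Mexican": 0.00, "Lowland": 1.00}, "Lowland"),
    ("Anaheim", {"Guatemalan": 93.06, "Mexican": 6.94, "Lowland": 0.00}, "Guatemalan"),
    ("Bacon", {"Guatemalan": 37.69, "Mexican": 62.31, "Lowland": 0.00}, "admixed"),
    ("Carlsbad", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("CH-CR-25", {"Guatemalan": 50.01, "Mexican": 7.98, "Lowland": 42.01}, "admixed"),
    ("CH-G-07", {"Guatemalan": 84.08, "Mexican": 0.00, "Lowland": 15.92}, "Guatemalan"),
    ("CH-G-10", {"Guatemalan": 89.28, "Mexican": 0.00, "Lowland": 10.72}, "Guatemalan"),
    ("CH-G-11", {"Guatemalan": 89.96, "Mexican": 0.00, "Lowland": 10.04}, "Guatemalan"),
    ("Fairchild", {"Guatemalan": 0.00, "Mexican": 0.00, "Lowland": 1.00}, "Lowland"),
    ("Fuerte", {"Guatemalan": 58.48, "Mexican": 41.52, "Lowland": 0.00}, "admixed"),
    ("Ganter", {"Guatemalan": 0.00, "Mexican": 1.00, "Lowland": 0.00}, "Mexican"),
    ("Gwen", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Hass", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Linda", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Lyon", {"Guatemalan": 83.78, "Mexican": 16.22, "Lowland": 0.00}, "Guatemalan"),
    ("Mendez", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Nabal", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Nimlioh", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("PequenoCharly", {"Guatemalan": 0.00, "Mexican": 1.00, "Lowland": 0.00}, "Mexican"),
    ("Pinkerton", {"Guatemalan": 81.00, "Mexican": 19.00, "Lowland": 0.00}, "Guatemalan"),
    ("Reed", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Simmonds", {"Guatemalan": 0.00, "Mexican": 0.00, "Lowland": 1.00}, "Lowland"),
    ("Taft", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("Thille", {"Guatemalan": 1.00, "Mexican": 0.00, "Lowland": 0.00}, "Guatemalan"),
    ("TopaTopa", {"Guatemalan": 0.00, "Mexican": 1.00, "Lowland": 0.00}, "Mexican"),
    ("VC26", {"Guatemalan": 0.00, "Mexican": 0.00, "Lowland": 1.00}, "Lowland"),
    ("Velvick", {"Guatemalan": 59.18, "Mexican": 0.00, "Lowland": 40.82}, "admixed"),
    ("Waldin", {"Guatemalan": 0.00, "Mexican": 0.00, "Lowland": 1.00}, "Lowland"),
    ("Zutano", {"Guatemalan": 38.35, "Mexican": 61.65, "Lowland": 0.00}, "admixed"),
]


@pytest.fixture(scope="session")
def accession_table():
    return ACCESSION_TABLE


@pytest.fixture(scope="session")
def cohort():
    """A small three-population cohort plus one admixed accession."""
    cfg = SimulationConfig(
        chrom_lengths={"chr1": 200_000, "chr2": 150_000},
        hybrids=[HybridSpec("Hyb1", {"Guatemalan": 0.38, "Mexican": 0.62})],
    )
    return simulate_cohort(cfg, seed=7)


def build_matrix(columns, populations=None, chrom="chr1", positions=None):
    """Hand-build a GenotypeMatrix from per-site haplotype columns."""
    hap = np.array(columns, dtype=np.int8).T
    n_samples = hap.shape[0] // 2
    if positions is None:
        positions = range(1, hap.shape[1] + 1)
    sites = [
        VariantSite(chrom, int(p), "A", ("T",), qual=60.0, depth=25)
        for p in positions
    ]
    samples = [f"s{i}" for i in range(n_samples)]
    pops = populations or ["pop"] * n_samples
    return GenotypeMatrix(hap, samples, pops, sites)
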