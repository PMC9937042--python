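import numpy as np
import pytest

from mitoscan.genome_io import GenotypeMatrix
from mitoscan.synthetic_data import SimulationConfig, write_fixture_bundle


def make_matrix(dosages, positions=None, chrom="chr1", groups=None, samples=None):
    """GenotypeMatrix from a (sites x samples) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if positions is None:
        positions = np.arange(n_sites) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {
            s: ("g1" if i < half else "g2") for i, s in enumerate(samples)
        }
    return GenotypeMatrix(
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        genotypes=dosages,
        samples=samples,
        groups=groups,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=42,
        n_sites=2000,
        chromosome_length=1_500_000,
        samples_per_population=10,
        n_genes=120,
        planted_roh=[("pop1_s01", 400_000, 900_000)],
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("bundle")
    write_fixture_bundle(small_config, out, codons_per_gene=40, cds_genes=40)
    return out
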