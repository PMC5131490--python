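import numpy as np
import pytest

from recmap.io import GenotypeMatrix, MarkerMap
from recmap.sim import SimulationConfig, simulate_population, simulate_region_variants


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    """One default-design cohort shared by read-only tests."""
    haps, genotypes, markers, samples, truth = simulate_population(default_cfg)
    return {"haps": haps, "genotypes": genotypes, "markers": markers,
            "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def default_variants(default_cfg, default_sim):
    return simulate_region_variants(default_cfg, default_sim["truth"],
                                    default_sim["samples"])


def make_map(n_loci, chrom="1", spacing=1000, start=1):
    pos = start + spacing * np.arange(n_loci)
    return MarkerMap(chrom=[chrom] * n_loci, position_bp=pos,
                     snp_id=[f"{chrom}_s{j}" for j in range(n_loci)],
                     ref_allele=["A"] * n_loci, alt_allele=["G"] * n_loci)


def make_genotypes(dosages, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    mm = make_map(dosages.shape[1], chrom=chrom)
    ids = [f"s{i}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, ids, mm)
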