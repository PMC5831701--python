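import numpy as np
import pytest

from svdgp import SimConfig, simulate_population
from svdgp.genotype_io import GenotypeMatrix, center
from svdgp import examples


@pytest.fixture
def example1():
    return examples.example1()


@pytest.fixture
def example2():
    return examples.example2()


def random_genotypes(rng, n, k, n_chrom=2, ids_prefix="i"):
    raw = rng.integers(0, 3, size=(n, k)).astype(float)
    # even split with remainder on the last chromosome
    sizes = [k // n_chrom] * n_chrom
    sizes[-1] += k - sum(sizes)
    chrom = np.concatenate([np.full(s, str(c + 1), dtype=object)
                            for c, s in enumerate(sizes)])
    return GenotypeMatrix(
        dosages=raw,
        ids=np.array([f"{ids_prefix}{j}" for j in range(n)], dtype=object),
        snp_ids=np.array([f"s{j}" for j in range(k)], dtype=object),
        allele_freq=raw.mean(axis=0) / 2.0,
        chrom_of=chrom,
        coding="raw")


@pytest.fixture
def small_centered():
    rng = np.random.default_rng(11)
    return center(random_genotypes(rng, 30, 200))


@pytest.fixture(scope="session")
def scaled_sim_2000():
    """The headline-replication population (~2000 animals); shared because
    the forward simulation takes ~10 s."""
    from svdgp.evaluation import headline_config
    return simulate_population(headline_config(seed=1))


@pytest.fixture(scope="session")
def tiny_sim():
    """Small but polymorphic simulated population shared across tests."""
    cfg = SimConfig(n_chromosomes=2, ne_historical=60,
                    n_burnin_generations=240, ne_final=30,
                    n_final_animals=400, n_qtl_per_chrom=20,
                    genome_bp=1e7, h2=0.5, seed=7)
    return simulate_population(cfg)
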