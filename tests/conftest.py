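import numpy as np
import pytest

from haploscan import simdata


def hard_gl(genotypes):
    """Hard-call likelihood triplets (one-hot) from genotype codes 0/1/2."""
    return np.eye(3)[np.asarray(genotypes, dtype=int)]


def reads_to_gl(genotypes, depth, eps, rng):
    """Simulate read counts for true genotypes and return GL triplets."""
    from haploscan import gl_engine

    g = np.asarray(genotypes)
    d = rng.poisson(depth, size=g.shape)
    n1 = rng.binomial(d, np.array([eps, 0.5, 1.0 - eps])[g])
    return gl_engine.genotype_likelihoods_from_counts(d - n1, n1, eps), d


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with a planted inversion at frequency 0.5 in one deme.

    2 demes x 28 individuals, 6 Mb chromosome, 2.4 Mb inversion, 3x depth.
    Session-scoped: several modules probe different facets of the same data.
    """
    cfg = simdata.SimConfig(
        n_demes=2,
        n_per_deme=28,
        chrom_length=6_000_000,
        n_sites=3_600,
        inversion_interval=(2_000_000, 4_400_000),
        inversion_freq_per_deme=(0.5, 0.0),
        n_inv_founder_mutations=430,
        mean_depth=3.0,
        seq_error=0.01,
        seed=42,
    )
    ds, truth = simdata.simulate_cohort(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def deep_cohort():
    """Same layout at 30x depth, where dosages are essentially hard calls."""
    cfg = simdata.SimConfig(
        n_demes=2,
        n_per_deme=18,
        chrom_length=6_000_000,
        n_sites=2_000,
        inversion_interval=(2_000_000, 4_400_000),
        inversion_freq_per_deme=(0.5, 0.0),
        n_inv_founder_mutations=240,
        mean_depth=30.0,
        seq_error=0.01,
        seed=7,
    )
    ds, truth = simdata.simulate_cohort(cfg)
    return cfg, ds, truth
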