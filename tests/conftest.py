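import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gcusage import CohortSpec, UsageProfile, simulate_profiles

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_spec():
    """A light cohort: 12 genomes, 3 phyla, 30 genes of 60 codons."""
    return CohortSpec(
        n_genomes=12,
        genes_per_genome=30,
        gene_length_codons=60,
        n_phyla=3,
        noise_sd=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    profiles, metadata = simulate_profiles(small_spec)
    return profiles, metadata


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return small_cohort[0]


def random_profiles(n, rng, gcs=None):
    """Profiles with uniformly random simplex vectors (no GC structure)."""
    out = []
    for i in range(n):
        base = np.concatenate(
            [rng.dirichlet(np.ones(4)) for _ in range(3)]
        )
        out.append(
            UsageProfile(
                genome_id=f"R{i:03d}",
                gc=float(gcs[i]) if gcs is not None else float(rng.uniform(0.1, 0.9)),
                n_genes=1,
                base_vec=base,
                codon_vec=rng.dirichlet(np.ones(64)),
                aa_vec=rng.dirichlet(np.ones(20)),
            )
        )
    return out
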