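import numpy as np
import pytest
from hypothesis import settings

from noveltax import (
    CommunitySpec,
    LongReadSpec,
    ShortReadSpec,
    ValidationConfig,
    align_short_reads,
    generate_community,
    simulate_long_reads,
    simulate_short_pairs,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return ValidationConfig()


@pytest.fixture(scope="session")
def community():
    """Five references at >=3% mutual divergence plus two novel variants."""
    return generate_community(
        CommunitySpec(
            n_taxa=5,
            seq_length=1500,
            min_pairwise_divergence=0.03,
            novel_taxa=[(0, 0.93), (1, 0.93)],
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def short_reads(community):
    """Error-free paired short reads at mean depth 50 over the community."""
    reads, frags = simulate_short_pairs(
        community, ShortReadSpec(mean_depth=50.0, seed=13)
    )
    return reads, frags


@pytest.fixture(scope="session")
def clean_long_reads(community):
    reads, truth = simulate_long_reads(
        community, LongReadSpec(n_reads=50, seed=17)
    )
    return reads, truth


@pytest.fixture(scope="session")
def chimera_long_reads(community):
    reads, truth = simulate_long_reads(
        community,
        LongReadSpec(
            n_reads=50, chimera_fraction=1.0, junction_guard_k=60, seed=19
        ),
        id_prefix="chim",
    )
    return reads, truth


@pytest.fixture(scope="session")
def support_index(community, short_reads, clean_long_reads, chimera_long_reads):
    """Support alignments for every session candidate, grouped by target."""
    cfg = ValidationConfig()
    candidates = clean_long_reads[0] + chimera_long_reads[0]
    supports = align_short_reads(candidates, short_reads[0], cfg)
    by = {c.id: [] for c in candidates}
    for s in supports:
        by[s.target_id].append(s)
    return by


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
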