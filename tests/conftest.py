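import numpy as np
import pytest
from hypothesis import settings

import cuttaggro as ctg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1)


def tiny_sim_config(seed: int = 1, **overrides) -> ctg.SimConfig:
    """A small but fully featured simulation used across the suite."""
    defaults = dict(
        seed=seed,
        n_chroms=1,
        chrom_len=700_000,
        n_genes=18,
        gene_length_ranges=((2_000, 5_000), (6_000, 10_000), (12_000, 20_000)),
        gene_gap_range=(4_000, 6_000),
        n_induced=4,
        n_repressed=4,
        n_microsat=8,
        n_isolated=8,
        n_tandem_per_class=2,
        gro_background=500,
        ct_background=5_000,
        ct_mean_frags=150.0,
    )
    defaults.update(overrides)
    return ctg.SimConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bundle() -> ctg.SimBundle:
    return ctg.simulate_dataset(tiny_sim_config(), preset="lce")


@pytest.fixture(scope="session")
def tiny_chrom_sizes(tiny_bundle) -> dict[str, int]:
    return {c: len(s) for c, s in tiny_bundle.genome.items()}
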