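import numpy as np
import pytest

from defensescan import simulate as sim


def small_config(seed: int = 1, **overrides) -> sim.SimConfig:
    """A compact but fully-featured simulation: 1 chromosome, 100 kb."""
    defaults = dict(
        seed=seed,
        n_chrom=1,
        chrom_length=100_000,
        n_genes=8,
    )
    defaults.update(overrides)
    return sim.SimConfig(**defaults)


def rip_only_config(seed: int = 1, rip_rate: float = 0.1) -> sim.SimConfig:
    """Families where RIP is the sole mutational process (identity 1.0)."""
    return small_config(
        seed=seed,
        rip_rate=rip_rate,
        families=[
            sim.FamilySpec("f1", 600, 6, 1.0, 0.3, "LTR"),
            sim.FamilySpec("f2", 450, 5, 1.0, 0.5, "TIR"),
        ],
    )


@pytest.fixture(scope="session")
def sim_result() -> sim.SimResult:
    """One shared full simulation for read-only assertions."""
    return sim.simulate(small_config(seed=1))


@pytest.fixture(scope="session")
def rip_only_result() -> sim.SimResult:
    return sim.simulate(rip_only_config(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
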