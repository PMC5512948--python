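import numpy as np
import pytest

from broadscan.motif_scan import ScanParams
from broadscan.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Two 400 kb chromosomes of 42% GC background."""
    cfg = SimulationConfig(
        seed=7, n_chromosomes=2, chrom_length=400_000, n_enhancers=0,
        planted_motifs=(),
    )
    return simulate_genome(cfg)


@pytest.fixture(scope="session")
def big_genome():
    """Four 2 Mb chromosomes; shared by the classifier-scale experiments."""
    cfg = SimulationConfig(
        seed=42, n_chromosomes=4, chrom_length=2_000_000, n_enhancers=0,
        planted_motifs=(),
    )
    return simulate_genome(cfg)


@pytest.fixture
def default_params():
    return ScanParams()


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_pwm(rng: np.random.Generator, length: int) -> np.ndarray:
    """Dirichlet-random PWM probabilities for oracle tests."""
    return rng.dirichlet(np.ones(4) * 0.8, size=length)
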