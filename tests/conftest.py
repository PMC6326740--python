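import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from netbgc import PipelineConfig, SimulationConfig, run_pipeline, simulate_cohort
from netbgc.connectivity import FCMatrix, NetworkPartition
from netbgc.synthetic import make_partition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def toy_partition():
    """Two networks of two regions each."""
    return make_partition([2, 2], ["A", "B"])


def random_instance(rng, n_regions=24, n_networks=4):
    """Random partition + random symmetric FC matrix for oracle checks."""
    sizes = np.full(n_networks, 2)
    extra = rng.multinomial(n_regions - 2 * n_networks, np.ones(n_networks) / n_networks)
    sizes = sizes + extra
    names = [f"N{k}" for k in range(n_networks)]
    part = make_partition(sizes.tolist(), names)
    w = rng.uniform(-0.8, 0.8, size=(n_regions, n_regions))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return part, FCMatrix(w, part.region_ids)


@pytest.fixture(scope="session")
def small_cohort():
    """24-subject scaled-down cohort for structural pipeline checks."""
    cfg = SimulationConfig.scaled_down(n_subjects=24, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_report():
    """Full-pipeline report on a 500-subject cohort with the default planted
    effect; shared between recovery and ranking checks."""
    cfg = SimulationConfig.scaled_down(n_subjects=500, seed=42)
    pc = PipelineConfig(simulation=cfg, seed=42)
    return run_pipeline(pc, simulate_cohort(cfg))
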