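import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from subnetmark import ExpressionDataset, InteractionNetwork, SimulationConfig

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_dataset(values, gene_ids=None, sample_ids=None, labels=None, clinical=None):
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    return ExpressionDataset(
        gene_ids=gene_ids or [f"g{i}" for i in range(n_g)],
        sample_ids=sample_ids or [f"s{j}" for j in range(n_s)],
        values=values,
        class_labels=labels,
        clinical=clinical,
    )


@pytest.fixture
def two_class_dataset():
    """4 genes x 6 samples, 3 tumor / 3 normal, g0/g1 shifted up in tumor."""
    rng = np.random.default_rng(7)
    values = rng.normal(7.0, 0.5, size=(4, 6))
    values[0, :3] += 3.0
    values[1, :3] += 3.0
    values[2, :3] -= 3.0
    return make_dataset(values, labels=["tumor"] * 3 + ["normal"] * 3)


@pytest.fixture
def small_network():
    edges = [
        ("g0", "g1", 900.0),
        ("g1", "g2", 800.0),
        ("g2", "g3", 950.0),
        ("g0", "g2", 750.0),
    ]
    return InteractionNetwork.from_edges(edges)


@pytest.fixture(scope="session")
def tiny_sim_config():
    """Reduced-scale study configuration for fast end-to-end tests."""
    return SimulationConfig(
        n_genes=200, n_planted_modules=2, module_size=12, seed=11
    )
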