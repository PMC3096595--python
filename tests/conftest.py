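import pytest

from netfootprint.synthetic import SimulationConfig, generate_dataset
from netfootprint.tf_repertoire import classify_tfs


@pytest.fixture(scope="session")
def zero_loss_dataset():
    """Synthetic dataset with no losses: every class must be fully conserved."""
    cfg = SimulationConfig(n_families=300, n_source_edges=150,
                           loss_rate=0.0, tri_loss_rate=0.0, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tri_dataset():
    """Synthetic dataset with planted ortholog/DBD losses (TRI ground truth)."""
    cfg = SimulationConfig(n_families=500, n_source_edges=200,
                           loss_rate=0.0, tri_loss_rate=0.1, seed=3)
    return generate_dataset(cfg)


def tf_sets_of(dataset):
    proteins = dataset.proteins_by_species()
    annotations = dataset.annotations_by_species()
    catalog = dataset.catalog()
    return {sp: classify_tfs(proteins[sp], annotations[sp], catalog)
            for sp in dataset.config.species}


@pytest.fixture(scope="session")
def zero_loss_tf_sets(zero_loss_dataset):
    return tf_sets_of(zero_loss_dataset)


@pytest.fixture(scope="session")
def tri_tf_sets(tri_dataset):
    return tf_sets_of(tri_dataset)
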