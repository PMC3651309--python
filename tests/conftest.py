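import numpy as np
import pytest

from mcsd.data_io import ExpressionMatrix, LabeledDataset
from mcsd.experiments import block_split_experiment, recovery_experiment


def make_dataset(values, labels, class_names=None, probe_prefix="p", sample_prefix="s"):
    """Labeled dataset from a raw array and a per-column class-index list."""
    values = np.asarray(values, dtype=float)
    probe_ids = [f"{probe_prefix}{i}" for i in range(values.shape[0])]
    sample_ids = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    labels = list(labels)
    if class_names is None:
        class_names = [f"c{k}" for k in range(max(labels) + 1)]
    matrix = ExpressionMatrix(probe_ids, sample_ids, values)
    return LabeledDataset(matrix, dict(zip(sample_ids, labels)), class_names)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def recovery_runs():
    """Cascaded 4-class recovery at effect size 4 sigma, 20 seeds."""
    return recovery_experiment(n_seeds=20, effect_size=4.0, base_seed=101)


@pytest.fixture(scope="session")
def null_runs():
    """Same design with no planted effect: chance-level control, 20 seeds."""
    return recovery_experiment(n_seeds=20, effect_size=0.0, base_seed=102)


@pytest.fixture(scope="session")
def block_split_runs():
    """Signal split across blocks: combined vs single-block fits, 20 seeds."""
    return block_split_experiment(n_seeds=20, base_seed=103)
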