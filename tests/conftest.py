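import numpy as np
import pytest

from toxqsar.datamodel import CompoundTable, DescriptorSpec
from toxqsar.synthetic import GeneratorConfig, calibrate, generate


@pytest.fixture(scope="session")
def gen_config():
    """Calibrated default generator configuration (shared across the run)."""
    return calibrate(GeneratorConfig())


@pytest.fixture(scope="session")
def table_small(gen_config):
    return generate(gen_config, 200, seed=101)


@pytest.fixture(scope="session")
def table_medium(gen_config):
    return generate(gen_config, 800, seed=202)


@pytest.fixture(scope="session")
def table_large(gen_config):
    return generate(gen_config, 1500, seed=303)


@pytest.fixture(scope="session")
def table_test_split(gen_config):
    """Independent draw used as an external test set."""
    return generate(gen_config, 500, seed=404)


def random_table(rng, n=20, p=4, with_y=True):
    """Small random valid table for round-trip/property tests."""
    X = rng.normal(size=(n, p)).round(6)
    specs = [DescriptorSpec(f"d{j}", "continuous",
                            float(X[:, j].min()) - 1.0,
                            float(X[:, j].max()) + 1.0,
                            float(np.median(X[:, j])),
                            float(X[:, j].mean()),
                            float(X[:, j].std(ddof=1)),
                            float(X[:, j].var(ddof=1)), 0.0, 0)
             for j in range(p)]
    ids = [f"CMP{i:04d}" for i in range(n)]
    y = rng.normal(size=n).round(6) if with_y else None
    return CompoundTable(np.array(ids, dtype=object), X, specs, y)
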