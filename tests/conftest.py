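import numpy as np
import pytest

import magicqtl as m
from magicqtl.pipeline import PipelineConfig, full_pipeline

#: seed for all simulated fixtures used by the suite
FIXTURE_SEED = 1234


def random_genotypes(n: int, p: int, seed: int) -> m.GenotypeMatrix:
    """Independent ±1 markers (no linkage), handy for oracle comparisons."""
    rng = np.random.default_rng(seed)
    vals = np.where(rng.random((n, p)) < 0.5, 1, -1).astype(np.int8)
    return m.GenotypeMatrix(
        line_ids=tuple(f"L{i:04d}" for i in range(n)),
        marker_ids=tuple(f"M{j:04d}" for j in range(p)),
        values=vals,
    )


@pytest.fixture(scope="session")
def desk_config() -> PipelineConfig:
    return PipelineConfig(preset="desk", master_seed=777)


@pytest.fixture(scope="session")
def recovery_dataset() -> m.SimDataset:
    return m.make_fixture("recovery_epistasis", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def null_dataset() -> m.SimDataset:
    return m.make_fixture("null", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def recovery_report(recovery_dataset, desk_config):
    return full_pipeline(
        recovery_dataset.genotypes,
        recovery_dataset.phenotypes,
        recovery_dataset.map,
        desk_config,
    )


@pytest.fixture(scope="session")
def null_report(null_dataset, desk_config):
    return full_pipeline(
        null_dataset.genotypes,
        null_dataset.phenotypes,
        null_dataset.map,
        desk_config,
    )
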