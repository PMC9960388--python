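import pytest
from hypothesis import settings

from cnlri import TwoStageConfig, WorldParams, generate_world, run_two_stage

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def world7():
    """The default 300-compound synthetic world at seed 7."""
    return generate_world(WorldParams(seed=7))


@pytest.fixture(scope="session")
def result7(world7):
    """One full two-stage run on the seed-7 world."""
    return run_two_stage(
        world7.replicate_tables,
        world7.corpus_table,
        world7.labels,
        world7.spectra,
        TwoStageConfig(seed=7),
    )


@pytest.fixture(scope="session")
def multi_seed_runs():
    """Five seeded end-to-end runs for distributional properties."""
    runs = []
    for seed in range(1, 6):
        world = generate_world(WorldParams(seed=seed))
        result = run_two_stage(
            world.replicate_tables,
            world.corpus_table,
            world.labels,
            world.spectra,
            TwoStageConfig(seed=seed),
        )
        runs.append((world, result))
    return runs


@pytest.fixture
def small_world():
    """A 40-compound world for fast file-based tests."""
    return generate_world(
        WorldParams(n_compounds=40, n_experimental=20, n_ood=5, seed=3)
    )
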