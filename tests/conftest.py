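import pytest

from loopwise import SimulationConfig, make_worked_fixture, run_pipeline, simulate_bundle


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced synthetic bundle shared by tests that only need shape, not power."""
    out = tmp_path_factory.mktemp("small_bundle")
    cfg = SimulationConfig(
        n_genes=60,
        n_peaks=90,
        n_stable_loops=80,
        n_gained_number=10,
        n_lost_number=10,
        n_gained_strength=6,
        n_lost_strength=6,
        n_decoy_fdr=5,
        n_decoy_pets=5,
        seed=11,
    )
    truth, run_config = simulate_bundle(cfg, out)
    return cfg, truth, run_config


@pytest.fixture(scope="session")
def small_run(small_bundle):
    _, truth, run_config = small_bundle
    return truth, run_pipeline(run_config)


@pytest.fixture(scope="session")
def worked_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("worked")
    run_config = make_worked_fixture(out)
    return out, run_config
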