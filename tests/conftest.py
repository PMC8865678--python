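import pytest

from spliceshift import (
    PipelineConfig,
    PlantedEvent,
    SimulationConfig,
    default_planted_events,
    make_toy_reference,
    run_pipeline,
)


def small_planted_mix() -> list[PlantedEvent]:
    return (
        [PlantedEvent("A5_slipUU")] * 2
        + [PlantedEvent("A5_GUshift")] * 1
        + [PlantedEvent("A3_upstream_inframe")] * 1
        + [PlantedEvent("SE", psi_control=0.80, psi_mutant=0.40)] * 1
        + [PlantedEvent("RI", psi_control=0.90, psi_mutant=0.55)] * 1
        + [PlantedEvent("null", psi_control=0.5, psi_mutant=0.5)] * 2
    )


@pytest.fixture(scope="session")
def toy_reference():
    cfg = SimulationConfig(seed=3, planted_events=default_planted_events())
    return make_toy_reference(cfg)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on a small simulation, shared across tests."""
    outdir = tmp_path_factory.mktemp("small_run")
    sim = SimulationConfig(seed=5, planted_events=small_planted_mix(),
                           background_per_event=5)
    cfg = PipelineConfig(outdir=outdir, seed=5, simulation=sim)
    return run_pipeline(cfg)
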