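import pytest

from tewave import (GenomeLayout, SimulationConfig, simulate_counts,
                    simulate_genome_annotation, simulate_peaks_and_signal)


@pytest.fixture(scope="session")
def annotation():
    """Default synthetic annotation, shared across the suite."""
    return simulate_genome_annotation(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def stage_peaks(annotation):
    return simulate_peaks_and_signal(annotation)


@pytest.fixture(scope="session")
def counts(annotation):
    return simulate_counts(annotation)


@pytest.fixture()
def small_layout():
    return GenomeLayout.from_dict({"chr1": 100_000, "chr2": 50_000})
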