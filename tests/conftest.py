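import pytest

from calchip import (OccupancyModel, make_genome_layout, plant_features,
                     simulate_experiment)


@pytest.fixture(scope="session")
def layout():
    return make_genome_layout(2, [200_000, 100_000])


@pytest.fixture(scope="session")
def features(layout):
    return plant_features(
        layout, n_hotspots=30, n_axis=10, n_centromere=2, n_coldspots=8,
        min_gap=500, seed=11,
    )


@pytest.fixture(scope="session")
def experiment(layout, features):
    return simulate_experiment(
        layout, features, OccupancyModel(), n_reads=60_000, seed=3,
    )
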