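from datetime import datetime

import pytest

from trackanim import (
    FixtureSpec,
    add_movement_attributes,
    generate_tracks,
    load_tracks,
    register_attributes,
)

REFERENCE_NOW = datetime(2026, 1, 1)


@pytest.fixture(scope="session")
def small_spec():
    return FixtureSpec(n_individuals=3, n_points_per_track=60, seed=7)


@pytest.fixture(scope="session")
def small_csv(small_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "small.csv"
    return generate_tracks(small_spec, path)


@pytest.fixture(scope="session")
def small_dataset(small_csv):
    dataset, report = load_tracks(small_csv, reference_now=REFERENCE_NOW)
    add_movement_attributes(dataset)
    register_attributes(dataset)
    return dataset
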