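"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from airr_repkit.schema_model import default_schema
from airr_repkit.synthetic_data import (
    RecombinationModel,
    simulate_truths,
    toy_germline_set,
)
from airr_repkit.tsv_io import write_rearrangements


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def heavy_set():
    return toy_germline_set(include_d=True)


@pytest.fixture(scope="session")
def light_set():
    return toy_germline_set(include_d=False)


@pytest.fixture(scope="session")
def model():
    return RecombinationModel(seed=42)


@pytest.fixture(scope="session")
def truths200(heavy_set, model):
    return simulate_truths(200, heavy_set, model)


@pytest.fixture()
def records200(truths200):
    # fresh copies so tests may mutate freely
    return [t.record.copy() for t in truths200]


@pytest.fixture(scope="session")
def sim_file(tmp_path_factory, truths200, schema):
    path = tmp_path_factory.mktemp("sim") / "sim200.tsv"
    write_rearrangements([t.record for t in truths200], path, schema)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
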