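import numpy as np
import pandas as pd
import pytest

from lohscan import (
    GenotypeMatrix,
    MarkerMap,
    NoiseModel,
    build_default_genome,
    build_marker_map,
)


@pytest.fixture(scope="session")
def genome():
    return build_default_genome()


@pytest.fixture(scope="session")
def markers_chr4(genome):
    """Chr IV-specific design: 2,300 dense + 20 sparse per chromosome."""
    return build_marker_map(genome, "chr4_specific", seed=1)


@pytest.fixture(scope="session")
def markers_wg(genome):
    """Whole-genome design, ~13,000 markers."""
    return build_marker_map(genome, "whole_genome", seed=1)


@pytest.fixture(scope="session")
def markers_small(genome):
    """Sparse map (20 markers/chromosome) for fast per-marker tests."""
    table = build_marker_map(genome, "chr4_specific", seed=2, n_dense=40).table
    return MarkerMap(table, genome)


@pytest.fixture
def noiseless():
    return NoiseModel(sigma=0.0, seed=0)


@pytest.fixture
def baseline_one(markers_small):
    return GenotypeMatrix.baseline(markers_small, ["iso"])
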