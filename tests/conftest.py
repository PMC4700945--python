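from __future__ import annotations

import os
import sys

sys.path.insert(0, os.path.dirname(__file__))

import numpy as np
import pytest

from indelfit import generate_benchmark_tree, read_tree

SMALL_NEWICK = "((A:0.12,B:0.08):0.05,(C:0.2,D:0.1):0.07,E:0.15);"


@pytest.fixture(scope="session")
def small_tree():
    """A fixed 5-leaf tree with modest branch lengths."""
    return read_tree(SMALL_NEWICK)


@pytest.fixture(scope="session")
def bench_tree():
    """The seeded 29-taxon surrogate benchmark tree."""
    return generate_benchmark_tree(n_taxa=29, total_length=5.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
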