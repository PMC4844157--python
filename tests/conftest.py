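"""Shared fixtures: synthetic studies and derived hit tables.

The default-size study and its all-vs-all hit tables are expensive enough
to build once per session; unit tests that only need a handful of families
use the small study.
"""

import numpy as np
import pytest

from famscan.align import all_vs_all, search
from famscan.expression import quantify
from famscan.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 50 families, duplicates, decoys."""
    return simulate(SimConfig())


@pytest.fixture(scope="session")
def small_sim():
    """A miniature study for cheap structural checks."""
    cfg = SimConfig(
        seed=11, n_families=6, family_mix=(2, 3, 1), n_tandem=1, n_segmental=1,
        n_scaffold_dups=1, n_decoys=6, reads_per_sample=4000,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def self_hits(default_sim):
    """All-vs-all within-species hit table (prefiltered) for the default study."""
    return all_vs_all(default_sim.genome_a.proteins())


@pytest.fixture(scope="session")
def cross_hits(default_sim):
    """Both directional cross-species hit tables for orthology."""
    pa = default_sim.genome_a.proteins()
    pb = default_sim.genome_b.proteins()
    return search(pa, pb), search(pb, pa)


@pytest.fixture(scope="session")
def expr_matrix(default_sim):
    """RPKM/count matrices over all genes of the default study."""
    return quantify(default_sim.read_sets, default_sim.genome_a.transcripts())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160425)
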