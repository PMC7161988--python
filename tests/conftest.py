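"""Shared fixtures: small trees, toy pillars and simulated datasets."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wgdloss.dcs_pipeline import Pillar
from wgdloss.io_formats import PhyloTree
from wgdloss.wgd_model import WGDModelSpec
from wgdloss.wgd_simulator import simulate_dataset, two_clade_tree


def make_pillar(anchor: str, **slots) -> Pillar:
    """Pillar from keyword slot pairs, e.g. A=("a1", None)."""
    return Pillar(anchor=anchor, slots={g: list(pair) for g, pair in slots.items()})


@pytest.fixture(scope="session")
def tree2():
    """Two leaves under an explicit root branch."""
    return PhyloTree.from_newick("((A:0.5,B:0.8):0.3);")


@pytest.fixture(scope="session")
def tree3():
    return PhyloTree.from_newick("((A:0.4,B:0.7):0.2,C:0.5);")


@pytest.fixture(scope="session")
def toy_pillars2():
    """Three pillars over genomes A and B with mixed copy states."""
    return [
        make_pillar("p0", A=("a1", "a2"), B=("b1", None)),
        make_pillar("p1", A=("a3", None), B=(None, "b2")),
        make_pillar("p2", A=(None, "a4"), B=("b3", "b4")),
    ]


@pytest.fixture(scope="session")
def clean_sim():
    """Loss-free, flip-free dataset: every pillar duplicated everywhere."""
    tree = two_clade_tree(3, branch_length=0.0, root_branch=0.0)
    return simulate_dataset(
        WGDModelSpec.from_name("WGD-n"), tree, 0.0, [30], seed=1
    )


@pytest.fixture(scope="session")
def small_sim():
    """Typical 4-genome dataset with losses and flips, with gene orders."""
    tree = two_clade_tree(4, branch_length=0.25, root_branch=0.25)
    spec = WGDModelSpec.from_name("WGD-bc_nbn_f", gamma=0.05, delta=0.15, eps1=0.8)
    return simulate_dataset(spec, tree, 0.03, [100, 100], seed=11)


def all_configs(n: int):
    return list(itertools.product([0, 1], repeat=n))
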