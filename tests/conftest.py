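"""Shared fixtures: tiny hand-built networks and one default synthetic study."""

from pathlib import Path

import networkx as nx
import pytest

from convergenet.model import GeneSet, Interactome
from convergenet.simulate import default_study

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def path_net() -> Interactome:
    """A - B - C path; B is the unique connector of A and C."""
    return Interactome.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net() -> Interactome:
    """Hub H with leaves L1..L4."""
    return Interactome.from_edges([("H", f"L{i}") for i in range(1, 5)])


@pytest.fixture
def cycle_net() -> Interactome:
    """4-cycle A - B - C - D - A; two symmetric connectors for {A, C}."""
    return Interactome.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


def random_connected_interactome(n: int, p: float, seed: int) -> Interactome:
    """G(n, p) conditioned on connectivity (resamples until connected)."""
    for offset in range(1000):
        g = nx.gnp_random_graph(n, p, seed=seed * 1000 + offset)
        if n > 0 and nx.is_connected(g):
            return Interactome(
                graph=nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            )
    raise RuntimeError("could not draw a connected graph")


def random_tree_interactome(n: int, seed: int) -> Interactome:
    t = nx.random_labeled_tree(n, seed=seed)
    return Interactome(graph=nx.relabel_nodes(t, {i: f"N{i:02d}" for i in t.nodes}))


def geneset(*symbols: str) -> GeneSet:
    return GeneSet.from_iterable("seeds", symbols)


@pytest.fixture(scope="session")
def study():
    """One default-preset synthetic study shared across read-only tests."""
    s = default_study(rng_seed=7)
    return s


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, study):
    """The same study written out as pipeline input files."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = study.write_dir(outdir)
    return paths
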