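"""Shared fixtures: tiny hand-built inputs, a small synthetic bundle, and
random weighted heterogeneous networks for walk tests."""

from __future__ import annotations

import numpy as np
import pytest

from ktcspm import (
    PpiGraph,
    RunConfig,
    SynthParams,
    build_network,
    generate_dataset,
    read_annotations,
    read_domain_map,
    read_essential_list,
    read_ppi_edges,
)
from ktcspm.io_formats import DomainMap
from ktcspm.net_build import WeightedHeteroNetwork
from ktcspm.rwr import TransitionMatrix


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture()
def tmp_table(tmp_path):
    """Factory writing a list of lines to a temp file."""
    def _write(lines, name="table.tsv"):
        return write_lines(tmp_path / name, lines)
    return _write


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A complete generated dataset (80 proteins, 20 domains) plus parsed
    structures, shared across tests that only read it."""
    outdir = tmp_path_factory.mktemp("bundle")
    params = SynthParams(n_proteins=80, n_domains=20, seed=3)
    paths = generate_dataset(params, outdir)
    graph = read_ppi_edges(paths["ppi"])
    dmap = read_domain_map(paths["domains"], graph)
    ann = read_annotations(paths["subcell"], paths["hom"], graph)
    essential = read_essential_list(paths["essential"])
    return {
        "params": params,
        "paths": paths,
        "graph": graph,
        "dmap": dmap,
        "ann": ann,
        "essential": essential,
    }


@pytest.fixture(scope="session")
def small_het(small_bundle) -> WeightedHeteroNetwork:
    return build_network(small_bundle["graph"], small_bundle["dmap"])


@pytest.fixture()
def small_config(small_bundle, tmp_path) -> RunConfig:
    paths = small_bundle["paths"]
    return RunConfig(
        ppi=str(paths["ppi"]), domains=str(paths["domains"]),
        subcell=str(paths["subcell"]), hom=str(paths["hom"]),
        essential=str(paths["essential"]), outdir=str(tmp_path / "out"),
    )


def random_graph(rng: np.random.Generator, n: int, p: float = 0.25) -> PpiGraph:
    """A random simple undirected graph as a PpiGraph."""
    names = [f"P{i}" for i in range(n)]
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.add((names[i], names[j]))
    return PpiGraph(proteins=names, edges=edges)


def random_domain_map(rng: np.random.Generator, graph: PpiGraph,
                      n_domains: int) -> DomainMap:
    names = [f"D{j}" for j in range(n_domains)]
    membership = {}
    for d in names:
        k = int(rng.integers(1, max(2, graph.n_proteins // 3)))
        members = rng.choice(graph.proteins, size=k, replace=False)
        membership[d] = set(members.tolist())
    return DomainMap(domains=names, membership=membership)


def random_transition(rng: np.random.Generator, n: int,
                      zero_rows: int = 0) -> TransitionMatrix:
    """A random row-stochastic transition matrix, optionally with dangling rows."""
    m = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
    for i in rng.choice(n, size=zero_rows, replace=False):
        m[i, :] = 0.0
    # make sure non-designated rows have at least one positive entry
    for i in range(n):
        if m[i].sum() == 0 and zero_rows == 0:
            m[i, int(rng.integers(n))] = 1.0
    row = m.sum(axis=1)
    dangling = frozenset(int(i) for i in np.flatnonzero(row == 0))
    values = m / np.where(row > 0, row, 1.0)[:, None]
    return TransitionMatrix(values=values, dangling=dangling)
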