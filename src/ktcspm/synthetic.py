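"""Seeded generator of complete toy datasets with a planted essentiality signal.

The generator emulates the structure of the yeast-style inputs the model
consumes: a scale-free PPI network grown by preferential attachment, Pfam-
style domain memberships, subcellular compartment labels, orthology scores,
and a reference essential-protein list. Essentiality is planted along four
independently tunable axes, each a nonnegative bias that is signal-free at
zero:

* ``degree_bias`` — essentials are sampled with probability proportional to
  degree**degree_bias (the centrality-lethality rule);
* ``domain_bias`` — essentials carry on average (1 + domain_bias) times as
  many domain annotations;
* ``subcell_bias`` — essentials preferentially occupy high-occupancy
  compartments;
* ``hom_bias`` — essentials' orthology scores are shifted up by hom_bias.

All randomness flows from ``params.seed`` through one numpy Generator, so a
given parameter set reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np


@dataclass
class SynthParams:
    """Conditions for one synthetic dataset.

    Defaults describe a mid-sized study: 500 proteins, 100 domains, 20%
    essential, unit planted biases on every axis.
    """

    n_proteins: int = 500
    n_domains: int = 100
    essential_fraction: float = 0.2
    attach_edges: int = 3
    degree_bias: float = 1.0
    domain_bias: float = 1.0
    subcell_bias: float = 1.0
    hom_bias: float = 1.0
    n_compartments: int = 8
    mean_domains_per_protein: float = 2.0
    mean_extra_compartments: float = 0.7
    hom_coverage: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 10:
            raise ValueError("n_proteins must be at least 10")
        if self.n_domains < 2:
            raise ValueError("n_domains must be at least 2")
        if not 0 < self.essential_fraction < 1:
            raise ValueError("essential_fraction must lie in (0, 1)")
        if self.attach_edges < 1 or self.attach_edges >= self.n_proteins:
            raise ValueError("attach_edges must satisfy 1 <= m < n_proteins")
        if self.n_compartments < 2:
            raise ValueError("n_compartments must be at least 2")
        for name in ("degree_bias", "domain_bias", "subcell_bias", "hom_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class SynthDataset:
    """In-memory synthetic tables plus the ground-truth essential set."""

    proteins: list[str]
    edges: list[tuple[str, str]]
    memberships: list[tuple[str, str]]
    subcell: list[tuple[str, str]]
    hom: list[tuple[str, float]]
    essential: list[str]
    params: SynthParams = field(repr=False, default=None)


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         weights: np.ndarray, k: int) -> np.ndarray:
    p = weights / weights.sum()
    return rng.choice(len(weights), size=k, replace=False, p=p)


def generate_tables(params: SynthParams) -> SynthDataset:
    """Draw one complete dataset according to ``params``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, n_d = params.n_proteins, params.n_domains
    proteins = [f"P{i:04d}" for i in range(n)]
    domains = [f"D{j:03d}" for j in range(n_d)]

    # scale-free PPI backbone (preferential attachment); networkx draws from
    # a python Random, so it gets an integer sub-seed from the one Generator
    graph_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(n, params.attach_edges, seed=graph_seed)
    degrees = np.array([g.degree(i) for i in range(n)], dtype=float)
    edges = [(proteins[min(a, b)], proteins[max(a, b)]) for a, b in sorted(g.edges())]

    # essentials: exact count, degree-weighted sampling
    n_ess = round(params.essential_fraction * n)
    ess_idx = np.sort(_weighted_sample_without_replacement(
        rng, degrees**params.degree_bias, n_ess))
    is_ess = np.zeros(n, dtype=bool)
    is_ess[ess_idx] = True
    essential = [proteins[i] for i in ess_idx]

    # domain memberships: essentials draw (1 + domain_bias)x more domains on
    # average; domains have power-law popularity; empty domains get a member
    dom_pop = 1.0 / np.arange(1, n_d + 1)
    memberships: list[tuple[str, str]] = []
    member_count = np.zeros(n_d, dtype=int)
    mu = params.mean_domains_per_protein
    for i in range(n):
        lam = mu * (1.0 + params.domain_bias * is_ess[i])
        k = min(int(rng.poisson(lam)), n_d)
        if k == 0:
            continue
        chosen = np.sort(_weighted_sample_without_replacement(rng, dom_pop, k))
        for j in chosen:
            memberships.append((proteins[i], domains[j]))
            member_count[j] += 1
    for j in np.flatnonzero(member_count == 0):
        i = int(rng.integers(n))
        memberships.append((proteins[i], domains[int(j)]))

    # subcellular labels: compartments have geometric popularity; essentials
    # sample with sharpened popularity weights
    comp = [f"C{c:02d}" for c in range(params.n_compartments)]
    comp_pop = 0.6 ** np.arange(params.n_compartments)
    subcell: list[tuple[str, str]] = []
    for i in range(n):
        k = min(1 + int(rng.poisson(params.mean_extra_compartments)),
                params.n_compartments)
        w = comp_pop ** (1.0 + params.subcell_bias) if is_ess[i] else comp_pop
        chosen = np.sort(_weighted_sample_without_replacement(rng, w, k))
        for c in chosen:
            subcell.append((proteins[i], comp[int(c)]))

    # orthology scores: uniform noise plus an essentiality shift, partial coverage
    hom: list[tuple[str, float]] = []
    covered = rng.random(n) < params.hom_coverage
    base = rng.random(n)
    for i in range(n):
        if covered[i]:
            score = base[i] + params.hom_bias * float(is_ess[i])
            hom.append((proteins[i], round(float(score), 6)))

    return SynthDataset(proteins=proteins, edges=edges, memberships=memberships,
                        subcell=subcell, hom=hom, essential=essential,
                        params=params)


#: file names used by generate_dataset, in io_formats dialects
FILE_NAMES = {
    "ppi": "ppi_edges.tsv",
    "domains": "domain_membership.tsv",
    "subcell": "subcell.tsv",
    "hom": "orthology.tsv",
    "essential": "essential.txt",
}


def generate_dataset(params: SynthParams, outdir) -> dict[str, Path]:
    """Generate one dataset and write the five input tables to ``outdir``.

    Returns the path of each table keyed by its role. Same params (including
    seed) produce byte-identical files.
    """
    data = generate_tables(params)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in FILE_NAMES.items()}
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in data.edges:
            fh.write(f"{a}\t{b}\n")
    with open(paths["domains"], "w", encoding="utf-8") as fh:
        fh.write("# protein\tdomain\n")
        for p, d in data.memberships:
            fh.write(f"{p}\t{d}\n")
    with open(paths["subcell"], "w", encoding="utf-8") as fh:
        fh.write("# protein\tcompartment\n")
        for p, c in data.subcell:
            fh.write(f"{p}\t{c}\n")
    with open(paths["hom"], "w", encoding="utf-8") as fh:
        fh.write("# protein\tscore\n")
        for p, s in data.hom:
            fh.write(f"{p}\t{s}\n")
    with open(paths["essential"], "w", encoding="utf-8") as fh:
        for p in data.essential:
            fh.write(f"{p}\n")
    return paths
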