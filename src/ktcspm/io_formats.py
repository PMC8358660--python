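"""Readers and writers for the five plain-text input tables.

All inputs are whitespace/tab-separated UTF-8 text; lines starting with
``#`` are comments and blank lines are skipped. Protein and domain
identifiers are treated as opaque strings (no ID-system reconciliation is
attempted). Node ordering is global and stable: proteins in
first-appearance order in the edge list, then domains in first-appearance
order in the membership table; every matrix in the package is indexed by
this ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger("ktcspm")


class InputFormatError(ValueError):
    """A malformed or empty input table."""


def _data_lines(path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, whitespace-split fields) for data lines."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


# ---------------------------------------------------------------------------
# Protein-protein interaction network
# ---------------------------------------------------------------------------


@dataclass
class PpiGraph:
    """A simple undirected PPI graph.

    ``proteins`` preserves first-appearance order from the input file and
    defines the row/column order of every protein-indexed matrix. ``edges``
    holds canonical (lexicographically sorted) unordered pairs; self-loops
    and duplicate records (in either orientation) have been removed.
    """

    proteins: list[str]
    edges: set[tuple[str, str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.proteins)}

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def index(self, protein: str) -> int:
        return self._index[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self._index

    def neighbors(self, protein: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return out


def read_ppi_edges(path) -> PpiGraph:
    """Parse a two-column edge list into a :class:`PpiGraph`.

    Self-loops are dropped and reciprocal/duplicate records collapsed, so
    the result is a simple undirected graph. Proteins are ordered by first
    appearance (scanning each line left to right).
    """
    proteins: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_lines = 0
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}: line {lineno}: expected two protein IDs, got {len(fields)} field(s)"
            )
        a, b = fields[0], fields[1]
        n_lines += 1
        for p in (a, b):
            if p not in seen:
                seen.add(p)
                proteins.append(p)
        if a == b:
            logger.debug("%s: line %d: self-loop %s dropped", path, lineno, a)
            continue
        edges.add((a, b) if a < b else (b, a))
    if n_lines == 0:
        raise InputFormatError(f"{path}: no edges")
    return PpiGraph(proteins=proteins, edges=edges)


# ---------------------------------------------------------------------------
# Protein-domain membership
# ---------------------------------------------------------------------------


@dataclass
class DomainMap:
    """Domain membership: which proteins carry each domain.

    ``domains`` preserves first-appearance order and, offset by the number
    of proteins, defines the domain-node indices of the heterogeneous
    network. Every retained domain has at least one member.
    """

    domains: list[str]
    membership: dict[str, set[str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {d: j for j, d in enumerate(self.domains)}

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def index(self, domain: str) -> int:
        return self._index[domain]

    def size(self, domain: str) -> int:
        """|d_j|: the number of distinct member proteins of a domain."""
        return len(self.membership[domain])


def read_domain_map(path, graph: PpiGraph, restrict: bool = True) -> DomainMap:
    """Parse (protein, domain) records into a :class:`DomainMap`.

    With ``restrict`` (default), records whose protein is absent from the
    PPI graph are dropped with a logged warning, and domains left with no
    retained member are removed entirely.
    """
    order: list[str] = []
    membership: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{path}: line {lineno}: expected (protein, domain), got {len(fields)} field(s)"
            )
        protein, domain = fields[0], fields[1]
        if restrict and protein not in graph:
            logger.warning(
                "%s: line %d: protein %s not in PPI network; record dropped",
                path, lineno, protein,
            )
            continue
        if domain not in membership:
            membership[domain] = set()
            order.append(domain)
        membership[domain].add(protein)
    domains = [d for d in order if membership[d]]
    return DomainMap(domains=domains, membership={d: membership[d] for d in domains})


# ---------------------------------------------------------------------------
# Subcellular localization and orthology annotations
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Subcellular compartment memberships and orthology scores.

    ``compartment_counts[c]`` is the number of distinct proteins annotated
    to compartment ``c`` (repeated records count once); ``hom`` maps a
    protein to its nonnegative orthology/conservation score.
    """

    subcell: dict[str, set[str]]
    compartment_counts: dict[str, int]
    hom: dict[str, float]

    @property
    def n_compartments(self) -> int:
        return len(self.compartment_counts)

    @property
    def n_hom(self) -> int:
        return len(self.hom)


def read_annotations(subcell_path, hom_path, graph: PpiGraph,
                     restrict: bool = True) -> AnnotationSet:
    """Parse the localization and orthology tables into an :class:`AnnotationSet`.

    Proteins absent from either table simply have no entry; downstream
    scoring assigns them a zero component score. Duplicate
    (protein, compartment) records are counted once.
    """
    subcell: dict[str, set[str]] = {}
    for lineno, fields in _data_lines(subcell_path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{subcell_path}: line {lineno}: expected (protein, compartment)"
            )
        protein, comp = fields[0], fields[1]
        if restrict and protein not in graph:
            logger.warning(
                "%s: line %d: protein %s not in PPI network; record dropped",
                subcell_path, lineno, protein,
            )
            continue
        subcell.setdefault(protein, set()).add(comp)

    counts: dict[str, int] = {}
    for comps in subcell.values():
        for c in comps:
            counts[c] = counts.get(c, 0) + 1

    hom: dict[str, float] = {}
    for lineno, fields in _data_lines(hom_path):
        if len(fields) < 2:
            raise InputFormatError(
                f"{hom_path}: line {lineno}: expected (protein, score)"
            )
        protein = fields[0]
        try:
            score = float(fields[1])
        except ValueError:
            raise InputFormatError(
                f"{hom_path}: line {lineno}: non-numeric orthology score {fields[1]!r}"
            ) from None
        if score < 0:
            raise InputFormatError(
                f"{hom_path}: line {lineno}: negative orthology score {score}"
            )
        if restrict and protein not in graph:
            logger.warning(
                "%s: line %d: protein %s not in PPI network; record dropped",
                hom_path, lineno, protein,
            )
            continue
        hom[protein] = score

    return AnnotationSet(subcell=subcell, compartment_counts=counts, hom=hom)


# ---------------------------------------------------------------------------
# Essential-protein reference list and ranking output
# ---------------------------------------------------------------------------


def read_essential_list(path) -> set[str]:
    """Read the reference essential-protein list (one ID per line).

    IDs absent from the network are retained; evaluation intersects with
    the ranked set later.
    """
    out: set[str] = set()
    for _lineno, fields in _data_lines(path):
        out.add(fields[0])
    if not out:
        raise InputFormatError(f"{path}: empty essential-protein list")
    return out


def write_ranking(path, ranking: Sequence[tuple[str, float]]) -> None:
    """Write a ranking as TSV (rank, protein ID, score) at full precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# rank\tprotein\tscore\n")
        for rank, (protein, score) in enumerate(ranking, start=1):
            fh.write(f"{rank}\t{protein}\t{score!r}\n")


def read_ranking(path) -> list[tuple[str, float]]:
    """Read a ranking written by :func:`write_ranking` (lossless round-trip)."""
    out: list[tuple[str, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise InputFormatError(
                f"{path}: line {lineno}: expected (rank, protein, score)"
            )
        out.append((fields[1], float(fields[2])))
    if not out:
        raise InputFormatError(f"{path}: empty ranking")
    return out
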