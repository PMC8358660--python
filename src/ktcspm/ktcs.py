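"""Key target convergence sets (KTCS) from reciprocal-weight network distances.

Every node of the heterogeneous network gets (1) a seed set: for a protein,
the domain nodes it carries; for a domain, its member proteins; and (2) a
final convergence set: the ``ktcs_size`` counterpart-type nodes with the
smallest mean network distance to the seed set, where the distance between
two same-type nodes is the reciprocal of their W_DD (domains) or W_PP
(proteins) weight, infinite when the weight is zero. The convergence set
later masks that node's restart-walk vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import DomainMap
from .net_build import WeightedHeteroNetwork

DEFAULT_KTCS_SIZE = 200


def network_distance(weight):
    """Reciprocal-weight distance: 1/w for w > 0, +inf for w = 0.

    Accepts scalars or arrays; negative weights are rejected.
    """
    w = np.asarray(weight, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weight has no network distance")
    with np.errstate(divide="ignore"):
        out = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    if np.isscalar(weight) or np.ndim(weight) == 0:
        return float(out)
    return out


def seed_sets(het: WeightedHeteroNetwork, dmap: DomainMap) -> list[np.ndarray]:
    """Per-node seed sets (global node indices of the counterpart type).

    seed(protein p) = the domain nodes whose domains contain p;
    seed(domain d) = the protein nodes that are members of d.
    """
    n_p = het.n_proteins
    protein_index = {p: i for i, p in enumerate(het.node_ids[:n_p])}
    seeds: list[list[int]] = [[] for _ in range(het.n_nodes)]
    for j, d in enumerate(dmap.domains):
        dj = n_p + j
        for p in dmap.membership[d]:
            i = protein_index[p]
            seeds[i].append(dj)
            seeds[dj].append(i)
    return [np.array(sorted(s), dtype=int) for s in seeds]


@dataclass
class KtcsIndex:
    """Seed and convergence sets for every node of the heterogeneous network.

    ``seed[i]`` and ``ktcs[i]`` hold global node indices of the counterpart
    type; ``ktcs[i]`` is ordered by ascending mean distance (ties by node
    index) and truncated to ``ktcs_size``. Nodes with an empty seed set are
    flagged in ``empty_seed`` and keep an empty convergence set: downstream
    their masked walk vector is defined equal to the unmasked one.
    """

    seed: list[np.ndarray]
    ktcs: list[np.ndarray]
    ktcs_size: int
    empty_seed: set[int] = field(default_factory=set)


def _mean_distances(dist_block: np.ndarray, seed_local: np.ndarray,
                    inf_policy: str) -> np.ndarray:
    """Mean distance from a seed set (rows) to every candidate (columns).

    With ``inf_policy="exclude"`` (default) infinite entries are dropped
    from the average as long as at least one seed member is at finite
    distance; a candidate unreachable from the entire seed set stays
    infinite. ``"strict"`` is the literal mean (any infinity wins).
    """
    sub = dist_block[seed_local, :]
    if inf_policy == "strict":
        return sub.mean(axis=0)
    finite = np.isfinite(sub)
    counts = finite.sum(axis=0)
    sums = np.where(finite, sub, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.inf)
    return means


def build_ktcs(het: WeightedHeteroNetwork, seeds: list[np.ndarray],
               ktcs_size: int = DEFAULT_KTCS_SIZE,
               inf_policy: str = "exclude") -> KtcsIndex:
    """Rank counterpart nodes by mean seed distance and keep the closest.

    Protein nodes rank all domain nodes using domain-domain distances
    (1/W_DD); domain nodes rank all protein nodes using 1/W_PP. Ties are
    broken by ascending node index; unreachable candidates (infinite mean)
    rank last but are still kept if the counterpart pool is smaller than
    ``ktcs_size``.
    """
    if ktcs_size < 1:
        raise ValueError("ktcs_size must be positive")
    if inf_policy not in ("exclude", "strict"):
        raise ValueError(f"unknown ktcs_inf_policy {inf_policy!r}")
    n_p, n_d = het.n_proteins, het.n_domains
    dist_dd = network_distance(het.w_dd)
    dist_pp = network_distance(het.w_pp)

    ktcs: list[np.ndarray] = []
    empty: set[int] = set()
    for node, seed in enumerate(seeds):
        if seed.size == 0:
            empty.add(node)
            ktcs.append(np.array([], dtype=int))
            continue
        if node < n_p:  # protein: rank domains among themselves via W_DD
            local_seed = seed - n_p
            means = _mean_distances(dist_dd, local_seed, inf_policy)
            offset, pool = n_p, n_d
        else:  # domain: rank proteins via W_PP
            means = _mean_distances(dist_pp, seed, inf_policy)
            offset, pool = 0, n_p
        order = np.argsort(means, kind="stable")  # ties -> ascending index
        take = min(ktcs_size, pool)
        ktcs.append(order[:take] + offset)
    return KtcsIndex(seed=list(seeds), ktcs=ktcs, ktcs_size=ktcs_size,
                     empty_seed=empty)
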