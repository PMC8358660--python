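"""Random walk with restart on the heterogeneous network, with KTCS masking.

For each start node i the walk iterates

    R_i(t) = (1 - alpha) * W' R_i(t-1) + alpha * R_i(0)

where W is the row-normalized transition matrix of the weighted
protein-domain network and R_i(0) is row i of W. Each node is solved twice:
unmasked over the intact node set (IS) and masked to its key target
convergence set (entries outside KTCS(i) zeroed after every update), and
the two stationary vectors are averaged. A protein's final score is the
mean of its averaged stationary mass and its annotation prior.

Masked and unmasked maps are both (1-alpha)-contractions in L1, so the
fixed point exists, is unique, and is independent of the starting vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ktcs import KtcsIndex
from .net_build import WeightedHeteroNetwork
from .priors import PriorScores

logger = logging.getLogger("ktcspm")

DEFAULT_ALPHA = 0.3
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000


class ConvergenceError(RuntimeError):
    """The walk failed to reach a stable vector within max_iter hops."""


@dataclass
class TransitionMatrix:
    """Row-normalized transition probabilities over the heterogeneous network.

    Rows of ``values`` sum to 1 except the ``dangling`` (all-zero-weight)
    nodes, whose rows are left at zero: a walker starting there has nowhere
    to go and receives no stationary mass.
    """

    values: np.ndarray
    dangling: frozenset[int]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def transition_matrix(het: WeightedHeteroNetwork) -> TransitionMatrix:
    """W(i,j) = M_PD(i,j) / sum_k M_PD(i,k); zero rows stay zero (dangling)."""
    m = het.m_pd
    row_sums = m.sum(axis=1)
    dangling = frozenset(int(i) for i in np.flatnonzero(row_sums == 0))
    safe = np.where(row_sums > 0, row_sums, 1.0)
    values = m / safe[:, None]
    if dangling:
        logger.info("transition matrix: %d dangling node(s)", len(dangling))
    return TransitionMatrix(values=values, dangling=dangling)


def restart_vector(w: TransitionMatrix, i: int) -> np.ndarray:
    """R_i(0): row i of the transition matrix (zero vector for dangling i)."""
    if not 0 <= i < w.n_nodes:
        raise IndexError(f"node index {i} out of range for {w.n_nodes} nodes")
    return w.values[i].copy()


def _as_mask(mask, n: int) -> np.ndarray | None:
    if mask is None:
        return None
    idx = np.fromiter(mask, dtype=int) if len(mask) else np.array([], dtype=int)
    m = np.zeros(n, dtype=bool)
    m[idx] = True
    return m


def propagate(w: TransitionMatrix, r0: np.ndarray, alpha: float = DEFAULT_ALPHA,
              mask=None, tol: float = DEFAULT_TOL,
              max_iter: int = DEFAULT_MAX_ITER,
              node_label: str | int = "?",
              x0: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Iterate the restart map (optionally masked) to its stable vector.

    The mask, if given, is the set of node indices allowed to hold
    probability: entries outside it are zeroed after every update. Stops
    when the L1 change between consecutive iterates is <= ``tol``; returns
    the stable vector and the hop count. The map is a (1-alpha)-contraction,
    so the fixed point does not depend on the starting iterate ``x0``
    (default: the restart vector itself).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    mask_vec = _as_mask(mask, w.n_nodes) if not isinstance(mask, np.ndarray) else mask
    wt = w.values.T
    r = np.asarray(r0 if x0 is None else x0, dtype=float).copy()
    for t in range(1, max_iter + 1):
        r_new = (1.0 - alpha) * (wt @ r) + alpha * r0
        if mask_vec is not None:
            r_new = np.where(mask_vec, r_new, 0.0)
        if np.abs(r_new - r).sum() <= tol:
            return r_new, t
        r = r_new
    raise ConvergenceError(
        f"walk from node {node_label} did not stabilize in {max_iter} hops"
    )


def solve_fixpoint_oracle(w: TransitionMatrix, r0: np.ndarray, alpha: float,
                          mask=None) -> np.ndarray:
    """Dense linear-system solution of the (masked) restart fixed point.

    Solves R = alpha * (I - (1-alpha) M W')^{-1} M R(0), with M the 0/1
    diagonal mask projection (identity when unmasked). Intended for
    verification on small networks only.
    """
    n = w.n_nodes
    if n > 500:
        raise ValueError("dense fixed-point solve limited to 500 nodes")
    mask_vec = _as_mask(mask, n) if not isinstance(mask, np.ndarray) else mask
    m_wt = w.values.T.copy()
    r0_eff = np.asarray(r0, dtype=float).copy()
    if mask_vec is not None:
        m_wt[~mask_vec, :] = 0.0
        r0_eff[~mask_vec] = 0.0
    system = np.eye(n) - (1.0 - alpha) * m_wt
    return alpha * np.linalg.solve(system, r0_eff)


@dataclass
class WalkResult:
    """Stationary walk vectors for every node, stacked row-wise.

    Row i of ``r_is`` is the unmasked (intact-set) stable vector of node i;
    ``r_ktcs`` the masked one (equal to ``r_is`` where the node's seed set
    was empty); ``r_ans`` their entrywise mean. ``k_inf`` is the stacked
    unmasked matrix whose four blocks split at the protein/domain boundary.
    """

    r_is: np.ndarray
    r_ktcs: np.ndarray
    r_ans: np.ndarray
    alpha: float
    n_proteins: int
    n_domains: int
    iterations_is: np.ndarray
    iterations_ktcs: np.ndarray

    @property
    def k_inf(self) -> np.ndarray:
        return self.r_is

    @property
    def k1(self) -> np.ndarray:
        return self.r_is[: self.n_proteins, : self.n_proteins]

    @property
    def k2(self) -> np.ndarray:
        return self.r_is[: self.n_proteins, self.n_proteins:]

    @property
    def k3(self) -> np.ndarray:
        return self.r_is[self.n_proteins:, : self.n_proteins]

    @property
    def k4(self) -> np.ndarray:
        return self.r_is[self.n_proteins:, self.n_proteins:]


def _batch_iterate(wt: np.ndarray, r0_cols: np.ndarray, alpha: float,
                   mask_cols: np.ndarray | None, tol: float,
                   max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Solve all per-node restart problems at once (column i = node i).

    Each column follows exactly the per-node map of :func:`propagate`; the
    batch runs until every column has stabilized, recording the hop at
    which each column first met the tolerance.
    """
    x = r0_cols.copy()  # start from the restart columns, as propagate does
    n = x.shape[1]
    first_conv = np.zeros(n, dtype=int)
    for t in range(1, max_iter + 1):
        x_new = (1.0 - alpha) * (wt @ x) + alpha * r0_cols
        if mask_cols is not None:
            x_new *= mask_cols
        diffs = np.abs(x_new - x).sum(axis=0)
        newly = (first_conv == 0) & (diffs <= tol)
        first_conv[newly] = t
        x = x_new
        if np.all(first_conv > 0):
            return x, first_conv
    bad = int(np.flatnonzero(first_conv == 0)[0])
    raise ConvergenceError(f"walk from node {bad} did not stabilize in {max_iter} hops")


def walk_all(w: TransitionMatrix, ktcs: KtcsIndex, n_proteins: int,
             alpha: float = DEFAULT_ALPHA, tol: float = DEFAULT_TOL,
             max_iter: int = DEFAULT_MAX_ITER) -> WalkResult:
    """Run the unmasked and KTCS-masked walks from every node.

    All start nodes are solved as one batched iteration (each column is an
    independent restart problem, so the batch is exactly the per-node
    computation). Nodes with an empty seed set take their unmasked vector
    as the masked one.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = w.n_nodes
    wt = w.values.T
    r0_cols = wt.copy()  # column i = restart vector of node i

    x_is, iters_is = _batch_iterate(wt, r0_cols, alpha, None, tol, max_iter)

    mask_cols = np.zeros((n, n))
    for i in range(n):
        if i in ktcs.empty_seed:
            mask_cols[:, i] = 1.0  # unmasked: masked vector defined = IS vector
        else:
            mask_cols[ktcs.ktcs[i], i] = 1.0
    x_ktcs, iters_ktcs = _batch_iterate(wt, r0_cols, alpha, mask_cols, tol, max_iter)

    r_is = x_is.T
    r_ktcs = x_ktcs.T
    for i in ktcs.empty_seed:
        r_ktcs[i] = r_is[i]
    r_ans = (r_is + r_ktcs) / 2.0

    return WalkResult(
        r_is=r_is, r_ktcs=r_ktcs, r_ans=r_ans, alpha=alpha,
        n_proteins=n_proteins, n_domains=n - n_proteins,
        iterations_is=iters_is, iterations_ktcs=iters_ktcs,
    )


def final_scores(result: WalkResult, priors: PriorScores,
                 proteins: list[str], score_block: str = "cross") -> dict[str, float]:
    """Final_Score(p_i) = (sum_j R^ANS_i,j + Initial_Score(p_i)) / 2.

    By default the sum runs over the domain columns only — the cross-type
    block of the stationary matrix, which is the result block the model
    predicts essentiality from. ``score_block="all"`` sums the whole row
    instead; note that the unmasked half of that sum is identically 1
    (stationary vectors are probability distributions), so the whole-row
    variant differs from the cross-block one only through the masked walk's
    retained mass.
    """
    if score_block not in ("all", "cross"):
        raise ValueError(f"unknown score_block {score_block!r}")
    n_p = len(proteins)
    block = result.r_ans[:n_p, n_p:] if score_block == "cross" else result.r_ans[:n_p, :]
    walk_mass = block.sum(axis=1)
    return {
        p: (float(walk_mass[i]) + priors.initial_score[p]) / 2.0
        for i, p in enumerate(proteins)
    }
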