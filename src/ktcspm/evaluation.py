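"""Ranking evaluation: top-k% accuracy, jackknife, PR/ROC, overlaps, baselines.

The positive class is the reference essential-protein set. All metrics are
computed on the ranked network proteins; reference essentials absent from
the network are ignored by intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .io_formats import PpiGraph

Ranking = list[tuple[str, float]]

DEFAULT_PERCENTS = (1, 5, 10, 15, 20, 25)


def rank_proteins(scores: Mapping[str, float]) -> Ranking:
    """Sort proteins by descending score, ties broken by ascending ID."""
    if not scores:
        raise ValueError("no scores to rank")
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def topk_accuracy(ranking: Ranking, essential: set[str],
                  percents: Sequence[float] = DEFAULT_PERCENTS
                  ) -> list[tuple[float, int, int, float]]:
    """Accuracy within the top p% of the ranking for each requested p.

    The cutoff is k = ceil(p/100 * N); each row of the result is
    (percent, k, true-essential count in top k, accuracy = count/k).
    """
    n = len(ranking)
    rows = []
    ids = [p for p, _ in ranking]
    for p in percents:
        if not 0 < p <= 100:
            raise ValueError(f"percent {p} outside (0, 100]")
        k = math.ceil(p / 100.0 * n)
        hits = sum(1 for pid in ids[:k] if pid in essential)
        rows.append((p, k, hits, hits / k))
    return rows


def jackknife_curve(ranking: Ranking, essential: set[str]) -> np.ndarray:
    """Cumulative count of true essentials among the top-m proteins, m=1..N."""
    flags = np.fromiter((p in essential for p, _ in ranking), dtype=int,
                        count=len(ranking))
    return np.cumsum(flags)


def pr_roc(scores: Mapping[str, float], essential: set[str]
           ) -> tuple[list[tuple[float, float]], list[tuple[float, float]],
                      float, float]:
    """PR and ROC curves from a threshold sweep over distinct scores.

    Tied scores are grouped at a single threshold, so a constant scorer
    yields AUROC 0.5 (the random baseline) and a perfect separator 1.0.
    Areas are trapezoidal. Returns (pr points as (recall, precision),
    roc points as (FPR, TPR), AUPR, AUROC).
    """
    y = np.array([1 if p in essential else 0 for p in scores])
    s = np.array([scores[p] for p in scores], dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present for PR/ROC")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auroc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn returns recall descending; reorder ascending for the area
    order = np.argsort(recall, kind="stable")
    aupr = float(np.trapezoid(precision[order], recall[order]))
    pr_points = list(zip(recall[order].tolist(), precision[order].tolist()))
    roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return pr_points, roc_points, aupr, auroc


@dataclass
class OverlapRecord:
    """Difference of two methods' top-k predictions and their essential content."""

    k: int
    only_a: set[str]
    only_b: set[str]
    essential_ratio_a: float
    essential_ratio_b: float


def overlap_analysis(a: Ranking, b: Ranking, essential: set[str],
                     k: int = 200) -> OverlapRecord:
    """Compare the top-k sets of two rankings.

    Reports the proteins each method predicts that the other does not, and
    the fraction of true essentials within each unique set (0 when empty).
    """
    if k > len(a) or k > len(b):
        raise ValueError(f"k={k} exceeds a ranking length")
    top_a = {p for p, _ in a[:k]}
    top_b = {p for p, _ in b[:k]}
    only_a = top_a - top_b
    only_b = top_b - top_a
    ra = len(only_a & essential) / len(only_a) if only_a else 0.0
    rb = len(only_b & essential) / len(only_b) if only_b else 0.0
    return OverlapRecord(k=k, only_a=only_a, only_b=only_b,
                         essential_ratio_a=ra, essential_ratio_b=rb)


def centrality(graph: PpiGraph, method: str) -> dict[str, float]:
    """Classical PPI centrality baselines.

    DC: degree. NC: sum over neighbours u of the edge clustering
    coefficient ECC(u,v) = |N(u) ∩ N(v)| / min(|N(u)|-1, |N(v)|-1)
    (0 when the denominator is nonpositive). LAC: mean degree of v's
    neighbours within the subgraph they induce (0 for isolated v).
    """
    g = nx.Graph()
    g.add_nodes_from(graph.proteins)
    g.add_edges_from(graph.edges)
    if method == "DC":
        return {v: float(g.degree(v)) for v in graph.proteins}
    if method == "NC":
        out = {}
        for v in graph.proteins:
            nv = set(g[v])
            total = 0.0
            for u in nv:
                nu = set(g[u])
                denom = min(len(nu) - 1, len(nv) - 1)
                if denom > 0:
                    total += len(nu & nv) / denom
            out[v] = total
        return out
    if method == "LAC":
        out = {}
        for v in graph.proteins:
            nv = list(g[v])
            if not nv:
                out[v] = 0.0
                continue
            sub = g.subgraph(nv)
            out[v] = sum(dict(sub.degree()).values()) / len(nv)
        return out
    raise ValueError(f"unknown centrality method {method!r}")


@dataclass
class EvaluationReport:
    """All evaluation outputs for one ranking against one reference set."""

    topk: list[tuple[float, int, int, float]]
    jackknife: np.ndarray
    pr: list[tuple[float, float]]
    roc: list[tuple[float, float]]
    aupr: float
    auroc: float


def evaluate_ranking(ranking: Ranking, essential: set[str],
                     percents: Sequence[float] = DEFAULT_PERCENTS
                     ) -> EvaluationReport:
    """Run the full evaluation battery on one ranking."""
    scores = dict(ranking)
    pr, roc, aupr, auroc = pr_roc(scores, essential)
    return EvaluationReport(
        topk=topk_accuracy(ranking, essential, percents),
        jackknife=jackknife_curve(ranking, essential),
        pr=pr, roc=roc, aupr=aupr, auroc=auroc,
    )


def write_report(path, report: EvaluationReport) -> None:
    """Serialize a report as sectioned TSV (one block per metric family)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("## topk\n# percent\tcutoff\thits\taccuracy\n")
        for p, k, hits, acc in report.topk:
            fh.write(f"{p}\t{k}\t{hits}\t{acc!r}\n")
        fh.write(f"## areas\n# aupr\tauroc\n{report.aupr!r}\t{report.auroc!r}\n")
        fh.write("## jackknife\n# rank\tcumulative_essentials\n")
        for m, c in enumerate(report.jackknife, start=1):
            fh.write(f"{m}\t{int(c)}\n")
        fh.write("## pr\n# recall\tprecision\n")
        for r, p in report.pr:
            fh.write(f"{r!r}\t{p!r}\n")
        fh.write("## roc\n# fpr\ttpr\n")
        for f, t in report.roc:
            fh.write(f"{f!r}\t{t!r}\n")
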