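"""End-to-end orchestration: inputs -> network -> priors -> KTCS -> walk -> ranking.

``run_pipeline`` executes the whole method in stage order, writes
``ranking.tsv``, ``report.tsv`` (when a reference essential list is given)
and ``manifest.txt`` (every parameter plus a checksum of every input), and
returns the in-memory results. ``alpha_sweep`` reuses the network, priors
and convergence sets across restart weights and reruns only the walk and
scoring stages.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, io_formats, ktcs, net_build, priors, rwr

logger = logging.getLogger("ktcspm")


@dataclass
class RunConfig:
    """All inputs and parameters of one run. Defaults are the model's
    published operating point (alpha 0.3, tol 1e-6, KTCS size 200,
    gamma_prime 1)."""

    ppi: str = ""
    domains: str = ""
    subcell: str = ""
    hom: str = ""
    essential: str | None = None
    outdir: str = "."
    alpha: float = rwr.DEFAULT_ALPHA
    tol: float = rwr.DEFAULT_TOL
    max_iter: int = rwr.DEFAULT_MAX_ITER
    ktcs_size: int = ktcs.DEFAULT_KTCS_SIZE
    gamma_prime: float = 1.0
    ppi_overlap: str = "plain"
    gip_mean_norm: bool = False
    ktcs_inf_policy: str = "exclude"
    score_block: str = "cross"
    restrict_to_graph: bool = True
    topk_percents: list[float] = field(
        default_factory=lambda: list(evaluation.DEFAULT_PERCENTS))
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    ranking: evaluation.Ranking
    report: evaluation.EvaluationReport | None
    walk: rwr.WalkResult
    scores: dict[str, float]
    priors: priors.PriorScores
    manifest: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute every stage in order and (optionally) write the output files."""
    graph = _stage("read_ppi")(io_formats.read_ppi_edges)(cfg.ppi)
    dmap = _stage("read_domains")(io_formats.read_domain_map)(
        cfg.domains, graph, restrict=cfg.restrict_to_graph)
    ann = _stage("read_annotations")(io_formats.read_annotations)(
        cfg.subcell, cfg.hom, graph, restrict=cfg.restrict_to_graph)
    essential = None
    if cfg.essential:
        essential = _stage("read_essential")(io_formats.read_essential_list)(
            cfg.essential)

    het = _stage("network")(net_build.build_network)(
        graph, dmap, gamma_prime=cfg.gamma_prime,
        gip_mean_norm=cfg.gip_mean_norm, ppi_overlap=cfg.ppi_overlap)
    prior = _stage("priors")(priors.compute_priors)(ann, graph.proteins)
    seeds = _stage("ktcs_seeds")(ktcs.seed_sets)(het, dmap)
    index = _stage("ktcs")(ktcs.build_ktcs)(
        het, seeds, ktcs_size=cfg.ktcs_size, inf_policy=cfg.ktcs_inf_policy)
    trans = _stage("transition")(rwr.transition_matrix)(het)
    walk = _stage("walk")(rwr.walk_all)(
        trans, index, graph.n_proteins, alpha=cfg.alpha, tol=cfg.tol,
        max_iter=cfg.max_iter)
    scores = _stage("scores")(rwr.final_scores)(
        walk, prior, graph.proteins, score_block=cfg.score_block)
    ranking = _stage("ranking")(evaluation.rank_proteins)(scores)

    report = None
    if essential is not None:
        report = _stage("evaluation")(evaluation.evaluate_ranking)(
            ranking, essential, cfg.topk_percents)
    else:
        logger.info("no essential list given; evaluation skipped")

    manifest = {
        "config": asdict(cfg),
        "inputs": {
            key: {"path": str(p), "sha256": _sha256(p)}
            for key, p in (("ppi", cfg.ppi), ("domains", cfg.domains),
                           ("subcell", cfg.subcell), ("hom", cfg.hom),
                           ("essential", cfg.essential))
            if p
        },
        "n_proteins": graph.n_proteins,
        "n_domains": dmap.n_domains,
        "dangling_nodes": sorted(trans.dangling),
        "empty_seed_nodes": sorted(index.empty_seed),
        "walk_iterations_max": int(max(walk.iterations_is.max(),
                                       walk.iterations_ktcs.max())),
    }

    if write_outputs:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_ranking(out / "ranking.tsv", ranking)
        if report is not None:
            evaluation.write_report(out / "report.tsv", report)
        with open(out / "manifest.txt", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return PipelineResult(ranking=ranking, report=report, walk=walk,
                          scores=scores, priors=prior, manifest=manifest)


def alpha_sweep(cfg: RunConfig, alphas: list[float]) -> pd.DataFrame:
    """Top-k% true-essential counts for each restart weight alpha.

    Network construction, priors and convergence sets are computed once and
    cached; only the walk and scoring stages rerun per alpha. Requires a
    reference essential list. Returns a grid with one row per top-k percent
    and one column per alpha.
    """
    if len(alphas) < 1:
        raise ValueError("at least one alpha required")
    if any(not 0 < a < 1 for a in alphas):
        raise ValueError("every alpha must lie in (0, 1)")
    if not cfg.essential:
        raise ValueError("alpha sweep requires a reference essential list")

    graph = io_formats.read_ppi_edges(cfg.ppi)
    dmap = io_formats.read_domain_map(cfg.domains, graph,
                                      restrict=cfg.restrict_to_graph)
    ann = io_formats.read_annotations(cfg.subcell, cfg.hom, graph,
                                      restrict=cfg.restrict_to_graph)
    essential = io_formats.read_essential_list(cfg.essential)
    het = net_build.build_network(graph, dmap, gamma_prime=cfg.gamma_prime,
                                  gip_mean_norm=cfg.gip_mean_norm,
                                  ppi_overlap=cfg.ppi_overlap)
    prior = priors.compute_priors(ann, graph.proteins)
    seeds = ktcs.seed_sets(het, dmap)
    index = ktcs.build_ktcs(het, seeds, ktcs_size=cfg.ktcs_size,
                            inf_policy=cfg.ktcs_inf_policy)
    trans = rwr.transition_matrix(het)

    grid: dict[float, list[int]] = {}
    for a in alphas:
        walk = rwr.walk_all(trans, index, graph.n_proteins, alpha=a,
                            tol=cfg.tol, max_iter=cfg.max_iter)
        scores = rwr.final_scores(walk, prior, graph.proteins,
                                  score_block=cfg.score_block)
        ranking = evaluation.rank_proteins(scores)
        rows = evaluation.topk_accuracy(ranking, essential, cfg.topk_percents)
        grid[a] = [hits for _, _, hits, _ in rows]
    return pd.DataFrame(grid, index=[f"top {p}%" for p in cfg.topk_percents])
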