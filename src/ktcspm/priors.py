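"""Prior (initial) protein scores from subcellular localization and orthology.

A protein gets a localization score equal to the relative occupancy of its
most-populated compartment, an orthology score equal to its conservation
score normalized by the maximum over annotated proteins, and an initial
score that is the arithmetic mean of the two. Proteins missing either
annotation receive 0 for that component, so every network protein is
scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import AnnotationSet


def subcell_scores(ann: AnnotationSet, proteins: Sequence[str]) -> dict[str, float]:
    """Subcell_Score(p) = max over compartments c of p of Np(c) / max_k Np(k).

    Unannotated proteins score 0.
    """
    if ann.compartment_counts:
        top = max(ann.compartment_counts.values())
        rel = {c: n / top for c, n in ann.compartment_counts.items()}
    else:
        rel = {}
    out: dict[str, float] = {}
    for p in proteins:
        comps = ann.subcell.get(p)
        out[p] = max(rel[c] for c in comps) if comps else 0.0
    return out


def hom_scores(ann: AnnotationSet, proteins: Sequence[str]) -> dict[str, float]:
    """Hom_Score(p) = Hom(p) / max over annotated proteins of Hom.

    Unannotated proteins score 0; if no protein has a positive score, all
    scores are 0. Negative input scores are rejected.
    """
    if any(v < 0 for v in ann.hom.values()):
        raise ValueError("negative orthology score")
    top = max(ann.hom.values(), default=0.0)
    if top == 0:
        return {p: 0.0 for p in proteins}
    return {p: ann.hom.get(p, 0.0) / top for p in proteins}


@dataclass
class PriorScores:
    """Per-protein prior scores, all in [0, 1]."""

    subcell_score: dict[str, float]
    hom_score: dict[str, float]
    initial_score: dict[str, float]


def initial_scores(sub: Mapping[str, float], hom: Mapping[str, float]) -> PriorScores:
    """Initial_Score(p) = (Subcell_Score(p) + Hom_Score(p)) / 2."""
    if set(sub) != set(hom):
        raise ValueError("subcellular and orthology scores cover different proteins")
    init = {p: (sub[p] + hom[p]) / 2.0 for p in sub}
    return PriorScores(subcell_score=dict(sub), hom_score=dict(hom), initial_score=init)


def compute_priors(ann: AnnotationSet, proteins: Sequence[str]) -> PriorScores:
    """Convenience wrapper running both component scores and their fusion."""
    return initial_scores(subcell_scores(ann, proteins), hom_scores(ann, proteins))
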