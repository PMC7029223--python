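"""End-to-end orchestration: score, cluster, flag.

One call takes a signed graph through balance testing, the appropriate
scoring strategy (convergent diffusion for balanced graphs, subset
consensus for unbalanced ones), sparsity-guided cluster selection and —
on the unbalanced path, where oscillators exist — weak-assignment
flagging.  Both the command-line interface and the robustness replicates
run through this function.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Set

from .clustering import ClusterAssignment, ClusteringParams, select_assignment
from .graph_io import SignedGraph
from .matrix_core import (
    DiffusionParams,
    ScoringMatrix,
    converge_balanced,
    detect_oscillators,
    is_balanced,
    score_unbalanced,
)
from .weak_assignment import WeakParams, flag_weak

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "cluster_signed_network"]


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    scores: ScoringMatrix
    balanced: bool
    oscillators: Set[str] = field(default_factory=set)


def cluster_signed_network(
    g: SignedGraph,
    diffusion: Optional[DiffusionParams] = None,
    clustering: Optional[ClusteringParams] = None,
    weak: Optional[WeakParams] = None,
    flag_weak_nodes: bool = True,
) -> PipelineResult:
    """Cluster a signed network with default parameters throughout.

    Balanced graphs are scored by the convergent diffusion and carry no
    weak flags (there is no flip-flop regime, hence no oscillators);
    unbalanced graphs are scored by subset consensus, and nodes whose
    shortest-path evidence conflicts with their cluster are flagged weak.
    """
    diffusion = diffusion or DiffusionParams()
    clustering = clustering or ClusteringParams()
    weak = weak or WeakParams()

    balanced, _ = is_balanced(g)
    if balanced:
        logger.info("graph is balanced: running convergent diffusion")
        scores = converge_balanced(g, diffusion)
        assignment = select_assignment(g, scores, clustering)
        return PipelineResult(assignment, scores, True, set())

    logger.info("graph is unbalanced: running subset consensus")
    scores = score_unbalanced(g, diffusion)
    assignment = select_assignment(g, scores, clustering)
    oscillators: Set[str] = set()
    if flag_weak_nodes:
        oscillators = detect_oscillators(g, diffusion)
        logger.info("oscillators: %s", sorted(oscillators) or "none")
        if oscillators:
            flag_weak(g, assignment, oscillators, params=weak)
    return PipelineResult(assignment, scores, False, oscillators)
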