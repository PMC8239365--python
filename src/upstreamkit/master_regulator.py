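"""Master-regulator search on the signaling network.

Candidates are molecules from which the module TFs are reachable within a
bounded number of directed SIGNALING steps.  The default network score is a
distance-discounted coverage,

    mr_score(c) = sum over reached TFs t of (r - d(c,t) + 1)/r  /  |TF_module|,

which lies in (0, 1] and rewards both covering many module TFs and sitting
close to them (d is the shortest signaling-path length, 1 <= d <= r).  A pure
coverage score |reached|/|TF_module| is available as an alternative.

A positive feedback loop is recorded when a candidate c signals to a module
TF t within radius r and t in turn transcribes the gene encoding c, either
via an explicit TRANSCRIPTION edge or via a module-passing binding site for
t's motif in that gene's promoter.  A loop is labeled positive when the
product of signaling-edge signs along the path is +1; negative-product loops
are kept but flagged.

Final ranking averages three component ranks: expression log2FC of the
encoding gene, the gene's regulatory (module) score, and the network score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .composite_module import CompositeModule
from .formats_io import SignalingNetwork, get_logger

_log = get_logger(__name__)

DEFAULT_RADIUS = 4
DEFAULT_MIN_TFS = 2

NETWORK_EDGE = "NETWORK_EDGE"
PROMOTER_SITE = "PROMOTER_SITE"


@dataclass
class FeedbackLoop:
    regulator_node: str
    tf_node: str
    signaling_path: list[str]      # regulator -> ... -> tf, SIGNALING edges
    closure: str                   # NETWORK_EDGE or PROMOTER_SITE
    positive: bool


@dataclass
class MRCandidate:
    node_id: str
    gene_id: str | None
    reached_tfs: dict[str, int]    # module TF -> shortest signaling distance
    mr_score: float
    lfc: float = 0.0
    reg_score: float = 0.0
    combined_rank: int = 0
    feedback_loops: list[FeedbackLoop] = field(default_factory=list)
    n_site_tfs: int = 0            # module TFs with a passing site in the gene


def _mr_score_distance(dists: Mapping[str, int], r: int, n_tfs: int) -> float:
    return sum((r - d + 1) / r for d in dists.values()) / n_tfs


def _mr_score_coverage(dists: Mapping[str, int], r: int, n_tfs: int) -> float:
    return len(dists) / n_tfs


SCORES = {"distance": _mr_score_distance, "coverage": _mr_score_coverage}


def find_candidates(network: SignalingNetwork,
                    tf_set: Sequence[str],
                    r: int = DEFAULT_RADIUS,
                    m_min: int = DEFAULT_MIN_TFS,
                    score: str = "distance") -> list[MRCandidate]:
    """Nodes reaching >= m_min of the module TFs within r signaling steps.

    Distances are shortest paths over SIGNALING edges (BFS from each TF on
    the reversed graph); output is ordered by (-mr_score, node_id).
    """
    tfs = [t for t in tf_set if t in network.nodes]
    missing = set(tf_set) - set(tfs)
    if missing:
        raise ValueError(f"TF nodes absent from network: {sorted(missing)}")
    if r < 1:
        raise ValueError("radius r must be >= 1")
    sig = network.signaling_digraph()
    rev = sig.reverse(copy=False)
    reach: dict[str, dict[str, int]] = {}
    for t in tfs:
        for node, d in nx.single_source_shortest_path_length(rev, t, cutoff=r).items():
            if node == t or d == 0:
                continue
            reach.setdefault(node, {})[t] = d
    out = []
    for node, dists in reach.items():
        if len(dists) < m_min:
            continue
        out.append(MRCandidate(
            node_id=node,
            gene_id=network.gene_of.get(node),
            reached_tfs=dict(sorted(dists.items())),
            mr_score=float(SCORES[score](dists, r, len(tfs))),
        ))
    out.sort(key=lambda c: (-c.mr_score, c.node_id))
    if not out:
        _log.warning("no master-regulator candidate reaches >= %d of %d "
                     "module TFs within radius %d", m_min, len(tfs), r)
    return out


def _passing_site(hits: pd.DataFrame, gene: str, motif_id: str,
                  theta: float) -> bool:
    if not len(hits):
        return False
    sub = hits[(hits["gene"] == gene) & (hits["motif"] == motif_id)]
    return bool(len(sub)) and bool((sub["mss"] >= theta).any())


def detect_feedback(network: SignalingNetwork,
                    candidates: list[MRCandidate],
                    modules: Sequence[CompositeModule],
                    hits: pd.DataFrame,
                    motif_of_tf: Mapping[str, str]) -> list[MRCandidate]:
    """Annotate candidates with positive-feedback loops (in place).

    ``motif_of_tf`` maps a TF node id to its motif id; a loop closes when the
    TF has a TRANSCRIPTION edge to the candidate's gene, or a site for its
    motif passing the module threshold lies in that gene's promoter.
    """
    theta_of = {}
    for mod in modules:
        for mm in mod.motifs:
            theta_of[mm.motif_id] = min(theta_of.get(mm.motif_id, 1.0), mm.theta)
    sig = network.signaling_digraph()
    for cand in candidates:
        cand.feedback_loops = []
        gene = cand.gene_id
        if gene is None:
            continue
        site_tfs = set()
        for tf in cand.reached_tfs:
            motif = motif_of_tf.get(tf)
            has_site = (motif is not None and motif in theta_of and
                        _passing_site(hits, gene, motif, theta_of[motif]))
            if has_site:
                site_tfs.add(tf)
            closure = None
            targets = network.transcription_targets(tf)
            if any(network.gene_of.get(v) == gene for v in targets):
                closure = NETWORK_EDGE
            elif has_site:
                closure = PROMOTER_SITE
            if closure is None:
                continue
            path = nx.shortest_path(sig, cand.node_id, tf)
            sign = 1
            for u, v in zip(path, path[1:]):
                sign *= sig.edges[u, v]["sign"]
            cand.feedback_loops.append(FeedbackLoop(
                cand.node_id, tf, path, closure, positive=sign > 0))
        cand.n_site_tfs = len(site_tfs)
    return candidates


def rank_master_regulators(candidates: list[MRCandidate],
                           lfc_of: Mapping[str, float],
                           reg_score_of: Mapping[str, float]
                           ) -> tuple[list[MRCandidate], pd.DataFrame]:
    """Three-component ranking: log2FC, regulatory score, network score.

    Each component is ranked descending (ties share the average rank); the
    combined rank orders candidates by the mean of the three, ties broken by
    node id.  Candidates without an encoding gene score 0 on the expression
    and regulatory components.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    for c in candidates:
        c.lfc = float(lfc_of.get(c.gene_id, 0.0)) if c.gene_id else 0.0
        c.reg_score = (float(reg_score_of.get(c.gene_id, 0.0))
                       if c.gene_id else 0.0)
    lfc_rank = rankdata([-c.lfc for c in candidates], method="average")
    reg_rank = rankdata([-c.reg_score for c in candidates], method="average")
    mr_rank = rankdata([-c.mr_score for c in candidates], method="average")
    mean_rank = (lfc_rank + reg_rank + mr_rank) / 3.0
    order = sorted(range(len(candidates)),
                   key=lambda i: (mean_rank[i], candidates[i].node_id))
    ranked = []
    for pos, i in enumerate(order, start=1):
        candidates[i].combined_rank = pos
        ranked.append(candidates[i])
    table = pd.DataFrame(
        [(c.node_id, c.gene_id or "", c.lfc, c.reg_score, c.mr_score,
          len(c.reached_tfs), c.n_site_tfs, len(c.feedback_loops),
          sum(1 for l in c.feedback_loops if l.positive), c.combined_rank)
         for c in ranked],
        columns=["regulator", "gene", "log2fc", "reg_score", "mr_score",
                 "n_tfs_reached", "n_tfs_site_supported", "n_loops",
                 "n_positive_loops", "rank"])
    return ranked, table


def candidates_to_json(candidates: list[MRCandidate]) -> list[dict]:
    return [{
        "node_id": c.node_id,
        "gene_id": c.gene_id,
        "reached_tfs": c.reached_tfs,
        "mr_score": c.mr_score,
        "log2fc": c.lfc,
        "reg_score": c.reg_score,
        "combined_rank": c.combined_rank,
        "n_tfs_site_supported": c.n_site_tfs,
        "feedback_loops": [{
            "regulator_node": l.regulator_node,
            "tf_node": l.tf_node,
            "signaling_path": l.signaling_path,
            "closure": l.closure,
            "positive": l.positive,
        } for l in c.feedback_loops],
    } for c in candidates]
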