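import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import floyd_warshall

from upstreamkit.composite_module import CompositeModule, ModuleMotif
from upstreamkit.formats_io import SignalingNetwork
from upstreamkit.master_regulator import (NETWORK_EDGE, PROMOTER_SITE,
                                          detect_feedback, find_candidates,
                                          rank_master_regulators)


def net_from_edges(edges, tf_nodes=(), gene_of=None):
    g = nx.MultiDiGraph()
    for u, v, *rest in edges:
        sign = rest[0] if rest else 1
        kind = rest[1] if len(rest) > 1 else "SIGNALING"
        for n in (u, v):
            if n not in g:
                g.add_node(n, kind="TF" if n in tf_nodes else "PROTEIN")
        g.add_edge(u, v, sign=sign, kind=kind)
    for t in tf_nodes:
        if t not in g:
            g.add_node(t, kind="TF")
    return SignalingNetwork(g, dict(gene_of or {}))


# --- closed forms ----------------------------------------------------------

def test_star_graph_score_is_one():
    tfs = [f"t{i}" for i in range(5)]
    net = net_from_edges([("c", t) for t in tfs], tf_nodes=tfs)
    c, = find_candidates(net, tfs, r=4, m_min=2)
    assert c.node_id == "c"
    assert c.mr_score == pytest.approx(1.0)
    assert c.reached_tfs == {t: 1 for t in tfs}


def test_chain_graph_radius_and_score():
    net = net_from_edges([("c", "a"), ("a", "t")], tf_nodes=["t"])
    assert all(c.node_id != "c"
               for c in find_candidates(net, ["t"], r=1, m_min=1))
    c = {x.node_id: x for x in find_candidates(net, ["t"], r=2, m_min=1)}["c"]
    assert c.reached_tfs == {"t": 2}
    # ((r - d + 1)/r) / |TF| = ((2 - 2 + 1)/2) / 1
    assert c.mr_score == pytest.approx(0.5)


def test_missing_tf_node_is_an_error():
    net = net_from_edges([("c", "t")], tf_nodes=["t"])
    with pytest.raises(ValueError, match="absent"):
        find_candidates(net, ["t", "ghost"])


# --- oracle equivalence ----------------------------------------------------

def random_network(rng, n=40, p=0.08):
    nodes = [f"n{i}" for i in range(n)]
    edges = [(a, b) for a, b in itertools.permutations(nodes, 2)
             if rng.random() < p]
    tfs = list(rng.choice(nodes, size=5, replace=False))
    return net_from_edges(edges, tf_nodes=tfs), nodes, tfs


def test_bfs_distances_match_floyd_warshall():
    """Reported shortest signaling distances vs an independent dense
    all-pairs computation (scipy), exact on graphs <= 50 nodes."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        net, nodes, tfs = random_network(rng)
        idx = {n: i for i, n in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for u, v, sign, kind in net.edges():
            if kind == "SIGNALING":
                A[idx[u], idx[v]] = 1
        D = floyd_warshall(A, directed=True, unweighted=True)
        r = 4
        cands = find_candidates(net, tfs, r=r, m_min=1)
        by_node = {c.node_id: c for c in cands}
        for n in nodes:
            expected = {t: int(D[idx[n], idx[t]]) for t in tfs
                        if n != t and D[idx[n], idx[t]] <= r}
            got = by_node[n].reached_tfs if n in by_node else {}
            assert got == expected, n


def test_radius_monotonicity():
    rng = np.random.default_rng(1)
    net, _, tfs = random_network(rng)
    for r in (1, 2, 3):
        small = {c.node_id for c in find_candidates(net, tfs, r=r, m_min=2)}
        big = {c.node_id for c in find_candidates(net, tfs, r=r + 1, m_min=2)}
        assert small <= big


def test_adding_edge_never_decreases_scores():
    rng = np.random.default_rng(2)
    net, nodes, tfs = random_network(rng)
    before = {c.node_id: c.mr_score
              for c in find_candidates(net, tfs, r=4, m_min=1)}
    u, v = "n0", tfs[0]
    net.graph.add_edge(u, v, sign=1, kind="SIGNALING")
    after = {c.node_id: c.mr_score
             for c in find_candidates(net, tfs, r=4, m_min=1)}
    for node, s in before.items():
        assert after[node] >= s - 1e-12


# --- feedback loops --------------------------------------------------------

def simple_module(motifs=("M1",)):
    mm = [ModuleMotif(m, 0.85, 1.0) for m in motifs]
    if len(mm) == 1:
        mm.append(ModuleMotif("M_pad", 0.99, 1e-9))
    return CompositeModule(mm, 300)


def test_smallest_feedback_loop():
    net = net_from_edges([("c", "t"), ("t", "c", 1, "TRANSCRIPTION")],
                         tf_nodes=["t"], gene_of={"c": "G1"})
    cands = find_candidates(net, ["t"], r=2, m_min=1)
    detect_feedback(net, cands, [simple_module()], pd.DataFrame(
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"]),
        {"t": "M1"})
    c = {x.node_id: x for x in cands}["c"]
    assert len(c.feedback_loops) == 1
    loop = c.feedback_loops[0]
    assert loop.signaling_path == ["c", "t"]
    assert loop.closure == NETWORK_EDGE and loop.positive


def test_no_evidence_no_loop():
    net = net_from_edges([("c", "t")], tf_nodes=["t"], gene_of={"c": "G1"})
    cands = find_candidates(net, ["t"], r=2, m_min=1)
    detect_feedback(net, cands, [simple_module()], pd.DataFrame(
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"]),
        {"t": "M1"})
    assert all(len(c.feedback_loops) == 0 for c in cands)


def test_promoter_site_closure_and_threshold():
    net = net_from_edges([("c", "t")], tf_nodes=["t"], gene_of={"c": "G1"})
    hits = pd.DataFrame(
        [("G1", "M1", "t", -100, "+", 0.90, 0.9)],
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"])
    cands = find_candidates(net, ["t"], r=2, m_min=1)
    detect_feedback(net, cands, [simple_module()], hits, {"t": "M1"})
    c = cands[0]
    assert [l.closure for l in c.feedback_loops] == [PROMOTER_SITE]
    assert c.n_site_tfs == 1
    # a site below the module threshold does not close the loop
    weak = hits.assign(mss=0.80)
    cands2 = find_candidates(net, ["t"], r=2, m_min=1)
    detect_feedback(net, cands2, [simple_module()], weak, {"t": "M1"})
    assert cands2[0].feedback_loops == []


def test_negative_sign_path_flagged():
    net = net_from_edges([("c", "a", -1), ("a", "t", 1),
                          ("t", "c", 1, "TRANSCRIPTION")],
                         tf_nodes=["t"], gene_of={"c": "G1"})
    cands = find_candidates(net, ["t"], r=3, m_min=1)
    detect_feedback(net, cands, [simple_module()], pd.DataFrame(
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"]),
        {"t": "M1"})
    c = {x.node_id: x for x in cands}["c"]
    assert len(c.feedback_loops) == 1
    assert not c.feedback_loops[0].positive


def test_loops_match_exhaustive_enumeration():
    """Loop set equals brute-force enumeration over all (candidate, TF)
    pairs on a synthetic network with planted loops."""
    from upstreamkit.synthetic_data import gen_network

    net, truth = gen_network([f"TF{i}" for i in range(1, 7)],
                             ["TF1", "TF2", "TF3"], "G0100",
                             distractor_genes=["G0200"],
                             n_nodes=50, n_distractors=2, rng=9)
    tfs = ["TF1", "TF2", "TF3"]
    cands = find_candidates(net, tfs, r=4, m_min=1)
    empty_hits = pd.DataFrame(
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"])
    detect_feedback(net, cands, [simple_module()], empty_hits,
                    {t: "M1" for t in tfs})
    got = {(c.node_id, l.tf_node) for c in cands for l in c.feedback_loops}

    sig = net.signaling_digraph()
    expected = set()
    for c in cands:
        for t in tfs:
            if t not in c.reached_tfs:
                continue
            gene = net.gene_of.get(c.node_id)
            if gene is None:
                continue
            closes = any(net.gene_of.get(v) == gene
                         for v in net.transcription_targets(t))
            if closes:
                expected.add((c.node_id, t))
    assert got == expected
    assert any(n == truth["regulator_node"] for n, _ in got)


def test_candidate_without_gene_has_no_loops():
    net = net_from_edges([("c", "t"), ("t", "c", 1, "TRANSCRIPTION")],
                         tf_nodes=["t"], gene_of={"c": "G1"})
    # remove gene assignment but keep the transcription edge target valid
    net2 = net_from_edges([("c", "t")], tf_nodes=["t"])
    cands = find_candidates(net2, ["t"], r=2, m_min=1)
    detect_feedback(net2, cands, [simple_module()], pd.DataFrame(
        columns=["gene", "motif", "tf", "start", "strand", "mss", "css"]),
        {"t": "M1"})
    assert cands[0].feedback_loops == []


# --- ranking ---------------------------------------------------------------

def make_candidates():
    net = net_from_edges([("c1", "t1"), ("c1", "t2"),
                          ("c2", "t1"), ("c2", "x"), ("x", "t2")],
                         tf_nodes=["t1", "t2"],
                         gene_of={"c1": "GA", "c2": "GB"})
    return find_candidates(net, ["t1", "t2"], r=4, m_min=2)


def test_single_candidate_ranks_first():
    net = net_from_edges([("c", "t1"), ("c", "t2")], tf_nodes=["t1", "t2"],
                         gene_of={"c": "G"})
    cands = find_candidates(net, ["t1", "t2"], r=4, m_min=2)
    ranked, table = rank_master_regulators(cands, {"G": 1.0}, {"G": 0.5})
    assert ranked[0].combined_rank == 1
    assert list(table["rank"]) == [1]


@pytest.mark.parametrize("lfc,reg", list(itertools.product([0.5, 2.0],
                                                           repeat=2)))
def test_dominating_candidate_ranks_first(lfc, reg):
    """c1 dominates on the network component; whenever it also dominates on
    expression and regulatory score it must come first (all patterns)."""
    cands = make_candidates()
    lfcs = {"GA": lfc, "GB": 0.1}
    regs = {"GA": reg, "GB": 0.05}
    ranked, _ = rank_master_regulators(cands, lfcs, regs)
    assert ranked[0].node_id == "c1"


def test_rank_components_are_averaged():
    cands = make_candidates()
    # c1 wins network+reg, c2 wins lfc heavily -> mean rank decides;
    # c1: ranks (2, 1, 1) -> 4/3; c2: ranks (1, 2, 2) -> 5/3
    ranked, table = rank_master_regulators(
        cands, {"GA": 0.1, "GB": 5.0}, {"GA": 1.0, "GB": 0.0})
    assert ranked[0].node_id == "c1"
    assert list(table.columns[:5]) == ["regulator", "gene", "log2fc",
                                       "reg_score", "mr_score"]


def test_empty_candidate_list_rejected():
    with pytest.raises(ValueError):
        rank_master_regulators([], {}, {})
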