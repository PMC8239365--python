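"""Synthetic study generator with a planted ground truth.

Every pipeline stage is testable without downloads: the generator emits a
two-group expression matrix with planted log2 fold changes, promoter
sequences in which a cluster of sites for a small set of module motifs is
implanted into the yes promoters, a motif library, and a signaling network
with a planted regulator wired upstream of the module TFs plus
transcriptional feedback edges.  A :class:`TruthManifest` records everything
that was planted, and all artifacts are generated from independent seed
streams so changing one artifact's stream leaves the others bit-identical.

The cross-referential structure encodes the positive-feedback premise of the
motivating biology: the module's target genes are a subset of the planted
upregulated genes, and the planted regulator's encoding gene is the planted
UP gene with the largest effect, so a correct end-to-end run should recover
the regulator at rank 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .formats_io import (ExpressionMatrix, PromoterRecord, SignalingNetwork,
                         get_logger)
from .motif_scan import MotifModel, encode

_log = get_logger(__name__)

_RC = str.maketrans("ACGT", "TGCA")


@dataclass
class TruthManifest:
    """Everything that was planted, for verification by downstream tests."""

    planted_up: dict[str, float] = field(default_factory=dict)
    planted_down: dict[str, float] = field(default_factory=dict)
    module_motifs: list[str] = field(default_factory=list)
    module_tfs: list[str] = field(default_factory=list)
    implant_prob: float = 0.9
    implant_window: int = 300
    implants: dict[str, list[dict]] = field(default_factory=dict)
    promoter_yes_genes: list[str] = field(default_factory=list)
    promoter_no_genes: list[str] = field(default_factory=list)
    regulator_node: str = ""
    regulator_gene: str = ""
    regulator_distances: dict[str, int] = field(default_factory=dict)
    distractor_nodes: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def gen_expression(n_genes: int = 2000, n_yes: int = 20, n_no: int = 20,
                   n_up: int = 150, n_down: int = 100,
                   effect: float | tuple[float, float] = (0.6, 1.5),
                   sigma: float = 0.5,
                   rng: np.random.Generator | int = 0
                   ) -> tuple[ExpressionMatrix, dict]:
    """Two-group log2 expression with planted shifts.

    Per-gene baseline ~ N(7, 1); Gaussian noise sd ``sigma``; YES samples of
    planted genes are shifted by +effect (up) or -effect (down), with the
    effect drawn from U(lo, hi) when a tuple is given.
    """
    rng = np.random.default_rng(rng)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = ([f"YES_{i + 1:02d}" for i in range(n_yes)]
               + [f"NO_{i + 1:02d}" for i in range(n_no)])
    groups = {s: ("YES" if s.startswith("YES") else "NO") for s in samples}

    baseline = rng.normal(7.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, sigma,
                                            size=(n_genes, n_yes + n_no))
    planted = rng.choice(n_genes, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]

    def draw_effects(k: int) -> np.ndarray:
        if isinstance(effect, tuple):
            return rng.uniform(effect[0], effect[1], size=k)
        return np.full(k, float(effect))

    up_eff = draw_effects(n_up)
    down_eff = draw_effects(n_down)
    values[np.ix_(up_idx, range(n_yes))] += up_eff[:, None]
    values[np.ix_(down_idx, range(n_yes))] -= down_eff[:, None]

    truth = {
        "planted_up": {genes[i]: float(e) for i, e in zip(up_idx, up_eff)},
        "planted_down": {genes[i]: float(e) for i, e in zip(down_idx, down_eff)},
    }
    return ExpressionMatrix(genes, samples, values, groups), truth


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def _info_bits(freqs: np.ndarray) -> float:
    from .motif_scan import information_vector

    return float(information_vector(freqs).mean() / np.log(2.0))


def gen_motifs(n: int = 20, length_range: tuple[int, int] = (8, 14),
               target_info: float = 1.2, tol: float = 0.2,
               rng: np.random.Generator | int = 0) -> list[MotifModel]:
    """Dirichlet-sampled PFMs tempered to ``target_info`` bits/position.

    Each position's frequencies are raised to a power gamma (then
    renormalized), with gamma found by bisection so the mean per-position
    information content lands within ``tol`` bits of the target.
    """
    rng = np.random.default_rng(rng)
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        base = rng.dirichlet(np.full(4, 0.7), size=L)
        base = np.clip(base, 1e-6, None)
        base /= base.sum(axis=1, keepdims=True)

        def tempered(gamma: float) -> np.ndarray:
            f = base ** gamma
            return f / f.sum(axis=1, keepdims=True)

        lo, hi = 0.02, 60.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _info_bits(tempered(mid)) < target_info:
                lo = mid
            else:
                hi = mid
        freqs = tempered(0.5 * (lo + hi))
        got = _info_bits(freqs)
        if abs(got - target_info) > tol:
            _log.warning("motif %d: information %.2f bits misses target %.2f",
                         i + 1, got, target_info)
        out.append(MotifModel(f"M{i + 1:02d}", f"TF{i + 1:02d}", freqs))
    return out


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def site_mss(motif: MotifModel, site: str) -> float:
    """Forward-strand MSS of a full-length site sequence against a motif."""
    codes = encode(site)
    f, info = motif.freqs, motif.info
    cur = float((info * f[np.arange(motif.length), codes]).sum())
    lo = float((info * f.min(axis=1)).sum())
    hi = float((info * f.max(axis=1)).sum())
    return (cur - lo) / max(hi - lo, 1e-12)


def _sample_site(motif: MotifModel, rng: np.random.Generator,
                 min_mss: float = 0.9, max_tries: int = 200) -> str:
    """High-affinity draw from the PFM (rejection on MSS >= min_mss)."""
    for _ in range(max_tries):
        bases = [rng.choice(4, p=row) for row in motif.freqs]
        site = "".join("ACGT"[b] for b in bases)
        if site_mss(motif, site) >= min_mss:
            return site
    return motif.consensus()


def gen_promoters(motif_list: Sequence[MotifModel],
                  module_motif_ids: Sequence[str],
                  yes_gene_ids: Sequence[str],
                  no_gene_ids: Sequence[str],
                  length: int = 1100, gc: float = 0.5,
                  pi: float = 0.9, W: int = 300,
                  decoy_rate: float = 1.0,
                  window: tuple[int, int] = (-1000, 100),
                  min_site_mss: float = 0.9,
                  rng: np.random.Generator | int = 0
                  ) -> tuple[list[PromoterRecord], dict]:
    """Yes promoters with an implanted site cluster, background no promoters.

    With probability ``pi`` a yes promoter receives one high-affinity site
    per module motif, all placed without overlap inside one random window of
    width ``W``; no promoters are background plus Poisson-distributed decoy
    singleton sites drawn from the non-module motifs (module sites are
    implanted only in yes promoters).
    """
    rng = np.random.default_rng(rng)
    if window[1] - window[0] != length:
        raise ValueError("window extent must equal promoter length")
    by_id = {m.motif_id: m for m in motif_list}
    module = [by_id[m] for m in module_motif_ids]
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    def background() -> list[str]:
        return list(rng.choice(list("ACGT"), size=length, p=probs))

    def place(seq: list[str], motif: MotifModel, lo: int, hi: int,
              occupied: list[tuple[int, int]]) -> dict | None:
        """Implant one site at a random free position in [lo, hi]."""
        Lm = motif.length
        for _ in range(100):
            pos = int(rng.integers(lo, hi - Lm + 2))
            if any(pos < e and pos + Lm > s for s, e in occupied):
                continue
            site = _sample_site(motif, rng, min_site_mss)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = site if strand == "+" else site[::-1].translate(_RC)
            seq[pos:pos + Lm] = list(planted)
            occupied.append((pos, pos + Lm))
            return {"motif": motif.motif_id, "start": window[0] + pos,
                    "strand": strand, "mss": site_mss(motif, site)}
        return None

    promoters, implants = [], {}
    for g in yes_gene_ids:
        seq = background()
        rec_implants = []
        if rng.random() < pi:
            u = int(rng.integers(0, length - W + 1))
            occupied: list[tuple[int, int]] = []
            for motif in module:
                imp = place(seq, motif, u, u + W - 1, occupied)
                if imp is not None:
                    rec_implants.append(imp)
        promoters.append(PromoterRecord(g, "".join(seq), window[0], window[1]))
        implants[g] = rec_implants
    decoy_ids = sorted(set(by_id) - set(module_motif_ids)) or sorted(by_id)
    for g in no_gene_ids:
        seq = background()
        occupied = []
        for _ in range(rng.poisson(decoy_rate)):
            motif = by_id[str(rng.choice(decoy_ids))]
            place(seq, motif, 0, length - 1, occupied)
        promoters.append(PromoterRecord(g, "".join(seq), window[0], window[1]))
    return promoters, {"implants": implants, "pi": pi, "W": W}


# ---------------------------------------------------------------------------
# Signaling network
# ---------------------------------------------------------------------------

def gen_network(tf_names: Sequence[str],
                module_tfs: Sequence[str],
                regulator_gene: str,
                distractor_genes: Sequence[str] = (),
                n_nodes: int = 300,
                mean_out_degree: float = 2.5,
                n_distractors: int = 5,
                rng: np.random.Generator | int = 0
                ) -> tuple[SignalingNetwork, dict]:
    """Signaling network with a planted regulator upstream of the module TFs.

    The planted node reaches the module TFs at distances cycling 1,2,3 (all
    within 3), each distractor hub reaches at most ceil(k/2) of them, and no
    background edge points into the TFs or the planted wiring, so the
    reachability structure is guaranteed by construction.  TRANSCRIPTION
    edges from every module TF to the planted node close the feedback loops.
    """
    rng = np.random.default_rng(rng)
    module_tfs = list(module_tfs)
    k = len(module_tfs)
    g = nx.MultiDiGraph()
    gene_of: dict[str, str] = {}

    for tf in tf_names:
        g.add_node(tf, kind="TF")

    planted = "P0001"
    g.add_node(planted, kind="PROTEIN")
    gene_of[planted] = regulator_gene

    protected = set(module_tfs) | {planted}

    def wire_chain(src: str, tf: str, dist: int, sign_choices=(1,)) -> None:
        """src -> ... -> tf with exactly dist SIGNALING edges."""
        prev = src
        for step in range(dist - 1):
            mid = f"I{len(gene_of) + g.number_of_nodes():04d}_{step}"
            g.add_node(mid, kind="PROTEIN")
            protected.add(mid)
            g.add_edge(prev, mid, sign=int(rng.choice(sign_choices)),
                       kind="SIGNALING")
            prev = mid
        g.add_edge(prev, tf, sign=int(rng.choice(sign_choices)),
                   kind="SIGNALING")

    distances = {}
    for i, tf in enumerate(module_tfs):
        d = (i % 3) + 1
        wire_chain(planted, tf, d, sign_choices=(1,))
        distances[tf] = d

    distractors = []
    max_reach = max(1, int(np.ceil(k / 2)))
    for i in range(n_distractors):
        node = f"D{i + 1:03d}"
        g.add_node(node, kind="PROTEIN")
        protected.add(node)
        if i < len(distractor_genes):
            gene_of[node] = distractor_genes[i]
        n_reach = int(rng.integers(1, max_reach + 1))
        targets = rng.choice(module_tfs, size=n_reach, replace=False)
        for tf in targets:
            wire_chain(node, str(tf), int(rng.integers(1, 4)),
                       sign_choices=(1, 1, 1, -1))
        distractors.append(node)

    n_background = max(n_nodes - g.number_of_nodes(), 0)
    bg_nodes = [f"P{i + 2:04d}" for i in range(n_background)]
    for n in bg_nodes:
        g.add_node(n, kind="PROTEIN")
    # background edges avoid protected targets so planted wiring alone
    # controls who reaches the module TFs
    free_targets = sorted((set(bg_nodes) | set(tf_names)) - set(module_tfs))
    sources = sorted(set(bg_nodes) | {planted} | set(distractors))
    n_edges = int(round(mean_out_degree * len(sources)))
    for _ in range(n_edges):
        u = sources[int(rng.integers(len(sources)))]
        v = free_targets[int(rng.integers(len(free_targets)))]
        if u == v:
            continue
        g.add_edge(u, v, sign=int(rng.choice([1, 1, 1, -1])),
                   kind="SIGNALING")

    for tf in module_tfs:
        g.add_edge(tf, planted, sign=1, kind="TRANSCRIPTION")

    net = SignalingNetwork(g, gene_of)
    truth = {"regulator_node": planted, "regulator_gene": regulator_gene,
             "regulator_distances": distances, "distractor_nodes": distractors}
    return net, truth


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    expression: ExpressionMatrix
    promoters: list[PromoterRecord]
    motifs: list[MotifModel]
    network: SignalingNetwork
    manifest: TruthManifest


def gen_study(seed: int = 0,
              n_genes: int = 2000, n_yes: int = 20, n_no: int = 20,
              n_up: int = 150, n_down: int = 100,
              effect: float | tuple[float, float] = (0.6, 1.5),
              sigma: float = 0.5,
              n_motifs: int = 20, module_size: int = 3,
              n_yes_promoters: int = 50, n_no_promoters: int = 200,
              promoter_length: int = 1100, gc: float = 0.5,
              pi: float = 0.9, implant_W: int = 300, decoy_rate: float = 1.0,
              n_nodes: int = 300, mean_out_degree: float = 2.5,
              n_distractors: int = 5) -> StudyBundle:
    """Generate the full, cross-consistent study bundle from one seed.

    Independent child streams per artifact keep, e.g., the expression matrix
    bit-identical when only the promoter stream changes.
    """
    ss = np.random.SeedSequence(seed)
    s_expr, s_mot, s_prom, s_net = ss.spawn(4)

    motif_list = gen_motifs(n=n_motifs, rng=np.random.default_rng(s_mot))
    module_rng = np.random.default_rng(s_mot.spawn(1)[0])
    module_ids = sorted(module_rng.choice([m.motif_id for m in motif_list],
                                          size=module_size, replace=False))
    module_tfs = [m.tf_name for m in motif_list if m.motif_id in module_ids]

    expr, expr_truth = gen_expression(
        n_genes, n_yes, n_no, n_up, n_down, effect, sigma,
        rng=np.random.default_rng(s_expr))

    # module target genes = the planted UP genes with the largest effects;
    # the regulator's gene is the largest of all (feedback-loop premise)
    up_sorted = sorted(expr_truth["planted_up"].items(),
                       key=lambda kv: (-kv[1], kv[0]))
    targets = [g for g, _ in up_sorted[:n_yes_promoters]]
    regulator_gene = targets[0]
    unplanted = [g for g in expr.gene_ids
                 if g not in expr_truth["planted_up"]
                 and g not in expr_truth["planted_down"]]
    prom_rng = np.random.default_rng(s_prom)
    no_genes = sorted(prom_rng.choice(unplanted, size=n_no_promoters,
                                      replace=False))

    promoters, prom_truth = gen_promoters(
        motif_list, module_ids, targets, no_genes,
        length=promoter_length, gc=gc, pi=pi, W=implant_W,
        decoy_rate=decoy_rate, rng=prom_rng)

    distractor_pool = [g for g, _ in up_sorted[n_yes_promoters:]]
    net_rng = np.random.default_rng(s_net)
    d_genes = list(net_rng.choice(distractor_pool,
                                  size=min(n_distractors, len(distractor_pool)),
                                  replace=False))
    network, net_truth = gen_network(
        [m.tf_name for m in motif_list], module_tfs, regulator_gene,
        distractor_genes=d_genes, n_nodes=n_nodes,
        mean_out_degree=mean_out_degree, n_distractors=n_distractors,
        rng=net_rng)

    manifest = TruthManifest(
        planted_up=expr_truth["planted_up"],
        planted_down=expr_truth["planted_down"],
        module_motifs=list(module_ids),
        module_tfs=module_tfs,
        implant_prob=pi,
        implant_window=implant_W,
        implants=prom_truth["implants"],
        promoter_yes_genes=list(targets),
        promoter_no_genes=list(no_genes),
        regulator_node=net_truth["regulator_node"],
        regulator_gene=net_truth["regulator_gene"],
        regulator_distances=net_truth["regulator_distances"],
        distractor_nodes=net_truth["distractor_nodes"],
        seeds={"study": int(seed)},
    )
    return StudyBundle(expr, promoters, motif_list, network, manifest)


def write_study(bundle: StudyBundle, outdir) -> dict[str, str]:
    """Emit the four input files plus truth.json into ``outdir``."""
    import os

    from .formats_io import (write_expression, write_motifs_transfac,
                             write_network, write_promoters)

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "matrix": os.path.join(outdir, "expression.tsv"),
        "groups": os.path.join(outdir, "groups.tsv"),
        "promoters": os.path.join(outdir, "promoters.fa"),
        "motifs": os.path.join(outdir, "motifs.transfac"),
        "network": os.path.join(outdir, "network.tsv"),
        "nodes": os.path.join(outdir, "nodes.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    write_expression(bundle.expression, paths["matrix"], paths["groups"])
    write_promoters(bundle.promoters, paths["promoters"])
    write_motifs_transfac(bundle.motifs, paths["motifs"])
    write_network(bundle.network, paths["network"], paths["nodes"])
    bundle.manifest.to_json(paths["truth"])
    return paths
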