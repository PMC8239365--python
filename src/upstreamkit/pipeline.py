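"""End-to-end orchestration of the five analysis stages from one YAML config.

Stages run in order — differential expression, promoter scanning, motif
enrichment, composite-module discovery, master-regulator search — writing a
plain TSV/JSON intermediate per stage so any stage can be rerun or replaced
standalone.  Every output embeds the config hash and seeds, and a rerun with
the same config and seeds is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from . import composite_module as cm
from . import diffexpr as de
from . import master_regulator as mr
from . import motif_scan as ms
from . import site_enrichment as se
from .formats_io import (FormatError, get_logger, read_expression,
                         read_motifs, read_network, read_promoters,
                         stage_timer, write_tsv)

_log = get_logger(__name__)

STAGES = ("de", "scan", "enrich", "cma", "mr")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown YAML keys are rejected."""

    matrix: str = ""
    groups: str = ""
    promoters: str = ""
    motifs: str = ""
    network: str = ""
    nodes: str = ""
    out_dir: str = "results"
    alpha: float = 0.05
    lfc: float = 0.5
    no_lfc_max: float = 0.1
    no_cap_factor: int = 10
    mss_cutoff: float = 0.75
    css_cutoff: float = 0.70
    calibrate_cutoffs: bool = True
    calibration_rate: float = 1e-3
    enrich_p_cut: float = 0.05
    enrich_ratio_cut: float = 1.0
    pool_min: int = 5
    null_model: str = "length"
    k_max: int = 6
    n_modules: int = 2
    pop: int = 200
    gens: int = 100
    p_mut: float = 0.3
    p_cross: float = 0.7
    lam: float = 0.1
    n_perm: int = 199
    radius: int = 4
    m_min: int = 2
    mr_score: str = "distance"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise FormatError(f"unknown stage toggles: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of every analysis-relevant setting (the output location is
        excluded so runs into different directories compare equal)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _seed_pool(records, cfg: PipelineConfig) -> list[str]:
    """Motif pool seeding the GA: significance-passing motifs first, padded
    with the next best-ranked motifs up to ``pool_min``.

    The enrichment filter is advisory for seeding — the GA applies its own
    selection pressure (thresholds, weights, complexity penalty), and
    starving it of candidates in marginal datasets loses more than the
    filter gains.
    """
    pool = [r.motif_id for r in
            se.rank_tfs(records, cfg.enrich_p_cut, cfg.enrich_ratio_cut)]
    if len(pool) < cfg.pool_min:
        ranked = sorted(records, key=lambda r: (r.p_binom, -r.ratio,
                                                r.motif_id))
        for r in ranked:
            if len(pool) >= cfg.pool_min:
                break
            if r.motif_id not in pool:
                pool.append(r.motif_id)
    return pool


def _provenance(cfg: PipelineConfig) -> str:
    return f"upstreamkit config_hash={cfg.digest()} seed={cfg.seed} log2FC=YES-NO"


def run_all(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns paths of the written bundle."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    prov = _provenance(cfg)
    paths = {
        "de": os.path.join(cfg.out_dir, "de.tsv"),
        "yes": os.path.join(cfg.out_dir, "yes.txt"),
        "no": os.path.join(cfg.out_dir, "no.txt"),
        "hits": os.path.join(cfg.out_dir, "hits.tsv"),
        "scannable": os.path.join(cfg.out_dir, "scannable.tsv"),
        "enrich": os.path.join(cfg.out_dir, "enrich.tsv"),
        "module": os.path.join(cfg.out_dir, "module.json"),
        "scores": os.path.join(cfg.out_dir, "scores.tsv"),
        "mr": os.path.join(cfg.out_dir, "mr.json"),
        "mr_table": os.path.join(cfg.out_dir, "mr.tsv"),
        "report": os.path.join(cfg.out_dir, "report.md"),
    }

    if cfg.stages.get("de", True):
        with stage_timer("de"):
            try:
                matrix = read_expression(cfg.matrix, cfg.groups)
            except (OSError, FormatError) as exc:
                raise PipelineError(f"stage de: cannot read expression input "
                                    f"({cfg.matrix!r}, {cfg.groups!r}): {exc}")
            results = de.moderated_de(matrix, alpha=cfg.alpha, lfc=cfg.lfc)
            yes, no = de.select_degs(results, cfg.alpha, cfg.lfc,
                                     cfg.no_lfc_max, cfg.no_cap_factor,
                                     seed=cfg.seed)
            write_tsv(de.de_table(results), paths["de"], prov)
            with open(paths["yes"], "w") as fh:
                fh.write("".join(f"{g}\n" for g in yes))
            with open(paths["no"], "w") as fh:
                fh.write("".join(f"{g}\n" for g in no))

    if cfg.stages.get("scan", True):
        with stage_timer("scan"):
            try:
                promoters = read_promoters(cfg.promoters)
                motif_list = read_motifs(cfg.motifs, cfg.mss_cutoff,
                                         cfg.css_cutoff)
            except (OSError, FormatError) as exc:
                raise PipelineError(f"stage scan: bad input: {exc}")
            if cfg.calibrate_cutoffs:
                motif_list = ms.calibrate_cutoffs(
                    motif_list, target_rate=cfg.calibration_rate,
                    seed=cfg.seed, floor=cfg.mss_cutoff)
                hits = ms.scan_all(promoters, motif_list)
            else:
                hits = ms.scan_all(promoters, motif_list,
                                   cfg.mss_cutoff, cfg.css_cutoff)
            write_tsv(hits, paths["hits"], prov)
            write_tsv(ms.scannable_positions(promoters, motif_list),
                      paths["scannable"], prov)

    if cfg.stages.get("enrich", True):
        for dep in ("de", "hits", "scannable"):
            if not os.path.exists(paths[dep]):
                raise PipelineError(f"stage enrich: missing {paths[dep]}")
        with stage_timer("enrich"):
            promoters = read_promoters(cfg.promoters)
            motif_list = read_motifs(cfg.motifs)
            hits = pd.read_csv(paths["hits"], sep="\t", comment="#")
            scannable = pd.read_csv(paths["scannable"], sep="\t", comment="#")
            yes = _read_list(paths["yes"])
            no = _read_list(paths["no"])
            with_prom = {p.gene_id for p in promoters}
            yes_p = [g for g in yes if g in with_prom]
            no_p = [g for g in no if g in with_prom]
            if not yes_p:
                _log.warning("no upregulated gene has a promoter; writing "
                             "empty enrichment")
                write_tsv(se.enrichment_table([]), paths["enrich"], prov)
            else:
                records = se.enrich(hits, yes_p, no_p, motif_list, scannable,
                                    cfg.null_model)
                write_tsv(se.enrichment_table(records), paths["enrich"], prov)

    if cfg.stages.get("cma", True):
        for dep in ("enrich", "hits"):
            if not os.path.exists(paths[dep]):
                raise PipelineError(f"stage cma: missing {paths[dep]}")
        with stage_timer("cma"):
            promoters = read_promoters(cfg.promoters)
            hits = pd.read_csv(paths["hits"], sep="\t", comment="#")
            enr = pd.read_csv(paths["enrich"], sep="\t", comment="#")
            yes = [g for g in _read_list(paths["yes"])
                   if g in {p.gene_id for p in promoters}]
            no = [g for g in _read_list(paths["no"])
                  if g in {p.gene_id for p in promoters}]
            records = [se.EnrichmentRecord(*row) for row in
                       enr.itertuples(index=False)] if len(enr) else []
            pool = _seed_pool(records, cfg)
            if len(pool) < 2:
                raise PipelineError("stage cma: candidate motif pool has "
                                    f"{len(pool)} motifs (need >= 2); input "
                                    f"{paths['enrich']}")
            cma_cfg = cm.CMAConfig(k_max=cfg.k_max, n_modules=cfg.n_modules,
                                   pop=cfg.pop, gens=cfg.gens,
                                   p_mut=cfg.p_mut, p_cross=cfg.p_cross,
                                   seed=cfg.seed, lam=cfg.lam)
            modules, scores, _ = cm.run_cma(hits, promoters, yes, no, pool,
                                            cma_cfg)
            for i, mod in enumerate(modules):
                mod.p_perm = cm.permutation_significance(
                    mod, hits, promoters, yes, no, n_perm=cfg.n_perm,
                    seed=cfg.seed + 1000 + i, config=cma_cfg)
            reg = cm.regulatory_scores(modules, hits, promoters)
            payload = {"provenance": prov,
                       "modules": [m.to_dict() for m in modules],
                       "regulatory_scores": {r.gene_id: r.score for r in reg}}
            with open(paths["module"], "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            write_tsv(scores, paths["scores"], prov)

    if cfg.stages.get("mr", True):
        if not os.path.exists(paths["module"]):
            raise PipelineError("stage mr: missing module.json "
                                f"({paths['module']})")
        with stage_timer("mr"):
            try:
                network = read_network(cfg.network, cfg.nodes or None)
            except (OSError, FormatError) as exc:
                raise PipelineError(f"stage mr: bad network input: {exc}")
            with open(paths["module"]) as fh:
                payload = json.load(fh)
            modules = [cm.CompositeModule.from_dict(d)
                       for d in payload["modules"]]
            motif_list = read_motifs(cfg.motifs)
            tf_of_motif = {m.motif_id: m.tf_name for m in motif_list}
            motif_of_tf = {v: k for k, v in tf_of_motif.items()}
            module_tf_nodes = sorted({
                tf_of_motif[mm.motif_id]
                for mod in modules for mm in mod.motifs
                if tf_of_motif.get(mm.motif_id) in network.nodes})
            if len(module_tf_nodes) < cfg.m_min:
                raise PipelineError("stage mr: fewer module TFs in the "
                                    f"network ({len(module_tf_nodes)}) than "
                                    f"m_min={cfg.m_min}")
            candidates = mr.find_candidates(network, module_tf_nodes,
                                            r=cfg.radius, m_min=cfg.m_min,
                                            score=cfg.mr_score)
            hits = pd.read_csv(paths["hits"], sep="\t", comment="#")
            mr.detect_feedback(network, candidates, modules, hits,
                               motif_of_tf)
            de_df = pd.read_csv(paths["de"], sep="\t", comment="#")
            lfc_of = dict(zip(de_df["gene"], de_df["log2fc"]))
            reg_of = payload["regulatory_scores"]
            if candidates:
                ranked, table = mr.rank_master_regulators(candidates, lfc_of,
                                                          reg_of)
            else:
                ranked, table = [], pd.DataFrame(
                    columns=["regulator", "gene", "log2fc", "reg_score",
                             "mr_score", "n_tfs_reached",
                             "n_tfs_site_supported", "n_loops",
                             "n_positive_loops", "rank"])
            with open(paths["mr"], "w") as fh:
                json.dump({"provenance": prov,
                           "candidates": mr.candidates_to_json(ranked)},
                          fh, indent=1, sort_keys=True)
            write_tsv(table, paths["mr_table"], prov)

    _write_report(cfg, paths, prov)
    return paths


def analyze_bundle(bundle, cfg: PipelineConfig | None = None,
                   run_permutation: bool = False) -> dict:
    """Run the whole analysis in memory on a synthetic StudyBundle.

    Convenience front-end used by tests and benchmark scripts; the file-based
    :func:`run_all` is the production path.  Returns a dict with the per-stage
    results (de, yes/no sets, hits, enrichment, modules, scores, ranked
    master-regulator candidates).
    """
    cfg = cfg or PipelineConfig()
    out: dict = {}
    results = de.moderated_de(bundle.expression, alpha=cfg.alpha, lfc=cfg.lfc)
    yes, no = de.select_degs(results, cfg.alpha, cfg.lfc, cfg.no_lfc_max,
                             cfg.no_cap_factor, seed=cfg.seed)
    out["de"] = results
    prom_genes = {p.gene_id for p in bundle.promoters}
    out["yes"] = [g for g in yes if g in prom_genes]
    out["no"] = [g for g in no if g in prom_genes]

    motif_list = bundle.motifs
    if cfg.calibrate_cutoffs:
        motif_list = ms.calibrate_cutoffs(motif_list,
                                          target_rate=cfg.calibration_rate,
                                          seed=cfg.seed, floor=cfg.mss_cutoff)
    hits = ms.scan_all(bundle.promoters, motif_list)
    scannable = ms.scannable_positions(bundle.promoters, motif_list)
    out["hits"] = hits

    records = se.enrich(hits, out["yes"], out["no"], motif_list, scannable,
                        cfg.null_model)
    out["enrichment"] = records
    pool = _seed_pool(records, cfg)
    out["pool"] = pool
    if len(pool) < 2:
        out["modules"] = []
        out["candidates"] = []
        return out

    cma_cfg = cm.CMAConfig(k_max=cfg.k_max, n_modules=cfg.n_modules,
                           pop=cfg.pop, gens=cfg.gens, p_mut=cfg.p_mut,
                           p_cross=cfg.p_cross, seed=cfg.seed, lam=cfg.lam)
    modules, scores, _ = cm.run_cma(hits, bundle.promoters, out["yes"],
                                    out["no"], pool, cma_cfg)
    if run_permutation:
        for i, mod in enumerate(modules):
            mod.p_perm = cm.permutation_significance(
                mod, hits, bundle.promoters, out["yes"], out["no"],
                n_perm=cfg.n_perm, seed=cfg.seed + 1000 + i, config=cma_cfg)
    out["modules"] = modules
    out["scores"] = scores
    reg = cm.regulatory_scores(modules, hits, bundle.promoters)
    reg_of = {r.gene_id: r.score for r in reg}

    tf_of_motif = {m.motif_id: m.tf_name for m in bundle.motifs}
    tf_nodes = sorted({tf_of_motif[mm.motif_id] for mod in modules
                       for mm in mod.motifs
                       if tf_of_motif.get(mm.motif_id)
                       in bundle.network.nodes})
    candidates = mr.find_candidates(bundle.network, tf_nodes, r=cfg.radius,
                                    m_min=min(cfg.m_min, len(tf_nodes)),
                                    score=cfg.mr_score)
    mr.detect_feedback(bundle.network, candidates, modules, hits,
                       {v: k for k, v in tf_of_motif.items()})
    lfc_of = {r.gene_id: r.log2fc for r in results}
    if candidates:
        ranked, table = mr.rank_master_regulators(candidates, lfc_of, reg_of)
        out["candidates"] = ranked
        out["mr_table"] = table
    else:
        out["candidates"] = []
    return out


def _read_list(path) -> list[str]:
    with open(path) as fh:
        return [l.strip() for l in fh if l.strip()]


def _write_report(cfg: PipelineConfig, paths: dict, prov: str) -> None:
    lines = ["# upstreamkit report", "", f"`{prov}`", ""]
    if os.path.exists(paths["de"]):
        df = pd.read_csv(paths["de"], sep="\t", comment="#")
        n_up = int((df["direction"] == "UP").sum())
        n_down = int((df["direction"] == "DOWN").sum())
        n_sig = int((df["p_adj"] < cfg.alpha).sum())
        lines += ["## Differential expression (log2FC = YES - NO)", "",
                  f"{n_sig} genes significant at adjusted p < {cfg.alpha}; "
                  f"{n_up} upregulated (log2FC > {cfg.lfc}) and {n_down} "
                  f"downregulated (log2FC < -{cfg.lfc}).", "",
                  "Top upregulated genes:", ""]
        top = df.sort_values(["p_adj", "p", "gene"]).query("direction == 'UP'")
        lines.append(top.head(5).to_markdown(index=False))
        lines.append("")
    if os.path.exists(paths["module"]):
        with open(paths["module"]) as fh:
            payload = json.load(fh)
        lines += ["## Composite modules", ""]
        for i, mod in enumerate(payload["modules"], 1):
            comp = ", ".join(f"{m['motif_id']}(theta={m['theta']:.2f},"
                             f"w={m['weight']:.2f})" for m in mod["motifs"])
            lines.append(f"- module {i}: {comp}; window {mod['window_W']} bp; "
                         f"fitness {mod['fitness']:.3f}; "
                         f"p_perm {mod['p_perm']:.4g}")
        lines.append("")
    if os.path.exists(paths["mr_table"]):
        df = pd.read_csv(paths["mr_table"], sep="\t", comment="#")
        lines += ["## Master regulators", ""]
        if len(df):
            lines.append(df.head(10).to_markdown(index=False))
        else:
            lines.append("No candidate reached enough module TFs.")
        lines.append("")
    with open(paths["report"], "w") as fh:
        fh.write("\n".join(lines))
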