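"""Readers and writers for the external formats the pipeline touches.

All downstream stages consume only the domain types defined here (and the
motif/hit types in :mod:`upstreamkit.motif_scan`): an expression matrix with a
two-group sample annotation, TSS-relative promoter records, and a directed,
typed signaling network.

Coordinate convention
---------------------
Promoter coordinates are TSS-relative, 0-based and half-open ``[start, end)``;
the TSS (first transcribed base) is position 0 and negative coordinates are
upstream.  A window of ``[-1000, +100)`` therefore has length 1100, and the
base at local index ``i`` sits at TSS-relative coordinate ``start + i``.
"""

from __future__ import annotations

import contextlib
import logging
import sys
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

YES = "YES"
NO = "NO"

DEFAULT_PROMOTER_WINDOW = (-1000, 100)

NODE_KINDS = ("PROTEIN", "COMPLEX", "TF")
EDGE_KINDS = ("SIGNALING", "TRANSCRIPTION")

_LOG_FORMAT = "%(asctime)s %(levelname)s %(name)s: %(message)s"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def get_logger(name: str = "upstreamkit") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


@contextlib.contextmanager
def stage_timer(stage: str, logger: logging.Logger | None = None):
    """Log wall-clock duration of a pipeline stage to stderr."""
    log = logger or get_logger()
    t0 = time.perf_counter()
    log.info("stage %s: started", stage)
    try:
        yield
    finally:
        log.info("stage %s: finished in %.2fs", stage, time.perf_counter() - t0)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2 expression values, genes x samples, with a YES/NO group label."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in expression matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise FormatError(f"samples missing from group annotation: {missing}")
        bad = {s: g for s, g in self.groups.items() if g not in (YES, NO)}
        if bad:
            raise FormatError(f"group labels must be YES/NO, got {bad}")
        labels = [self.groups[s] for s in self.sample_ids]
        if YES not in labels or NO not in labels:
            raise FormatError("both YES and NO groups must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")

    def group_columns(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sample_ids)
                         if self.groups[s] == group], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression(path, groups_path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a two-column sample->YES/NO TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell at gene {df.index[i]!r}, sample {col!r}: {raw!r}"
                ) from None
    gdf = pd.read_csv(groups_path, sep="\t", header=None, comment="#",
                      names=["sample", "group"], dtype=str)
    groups = dict(zip(gdf["sample"], gdf["group"].str.upper()))
    missing = [s for s in df.columns if s not in groups]
    if missing:
        raise FormatError(f"samples missing from group file: {missing}")
    return ExpressionMatrix(list(df.index), list(df.columns), values,
                            {s: groups[s] for s in df.columns})


def write_expression(matrix: ExpressionMatrix, path, groups_path,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.to_frame().to_csv(fh, sep="\t", float_format="%.10g")
    with open(groups_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for s in matrix.sample_ids:
            fh.write(f"{s}\t{matrix.groups[s]}\n")


# ---------------------------------------------------------------------------
# Promoters (FASTA)
# ---------------------------------------------------------------------------

@dataclass
class PromoterRecord:
    """One promoter sequence in TSS-relative, 0-based, half-open coordinates."""

    gene_id: str
    sequence: str
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            raise FormatError(
                f"promoter {self.gene_id}: sequence has characters outside ACGTN"
            )
        if len(self.sequence) != self.window_end - self.window_start:
            raise FormatError(
                f"promoter {self.gene_id}: sequence length {len(self.sequence)} "
                f"!= window [{self.window_start}, {self.window_end})"
            )
        if not (self.window_start < 0 <= self.window_end):
            raise FormatError(
                f"promoter {self.gene_id}: window [{self.window_start}, "
                f"{self.window_end}) must straddle the TSS (start < 0 <= end)"
            )

    @property
    def length(self) -> int:
        return self.window_end - self.window_start


def read_promoters(path, default_window: tuple[int, int] | None = None
                   ) -> list[PromoterRecord]:
    """Read promoter FASTA; headers are ``gene_id [window_start window_end]``.

    Records without explicit coordinates get a window ending at the TSS
    (``[-len, 0)``), so plain FASTA works out of the box.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = rec.description.split()
        seq = str(rec.seq)
        if len(fields) >= 3:
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"promoter {rec.id}: non-integer window coordinates "
                    f"{fields[1]!r} {fields[2]!r}"
                ) from None
        else:
            start, end = -len(seq), 0
            _ = default_window  # plain FASTA anchors at the TSS
        out.append(PromoterRecord(rec.id, seq, start, end))
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    ids = [p.gene_id for p in out]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate gene ids in promoter FASTA")
    return out


def write_promoters(promoters: Sequence[PromoterRecord], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.gene_id,
                  description=f"{p.gene_id} {p.window_start} {p.window_end}")
        for p in promoters
    ]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.description}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(str(rec.seq)[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Motif libraries (TRANSFAC / JASPAR dialects)
# ---------------------------------------------------------------------------

def read_motifs(path, mss_cutoff: float = 0.75, css_cutoff: float = 0.70):
    """Parse a TRANSFAC- or JASPAR-format PFM file into MotifModels.

    The dialect is auto-detected: a JASPAR file starts records with ``>``,
    a TRANSFAC file carries ``AC``/``P0`` blocks terminated by ``//``.
    """
    from .motif_scan import MotifModel  # deferred: avoids a module cycle

    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        dialect = "jaspar"
    elif "P0" in text or "PO" in text:
        dialect = "transfac"
    else:
        raise FormatError(f"{path}: neither TRANSFAC nor JASPAR dialect recognized")

    import io as _io
    try:
        records = bio_motifs.parse(_io.StringIO(text), dialect)
    except Exception as exc:  # biopython raises bare ValueError/KeyError
        raise FormatError(f"{path}: failed to parse as {dialect}: {exc}") from exc

    out = []
    for rec in records:
        counts = np.array([list(rec.counts[b]) for b in "ACGT"], dtype=float).T
        if counts.shape[0] < 4:
            raise FormatError(
                f"motif {getattr(rec, 'name', '?')}: fewer than 4 positions"
            )
        if np.any(counts < 0):
            raise FormatError("negative count in motif matrix")
        if np.any(counts.sum(axis=1) <= 0):
            raise FormatError("zero-sum position in motif matrix")
        if dialect == "transfac":
            motif_id = rec.get("AC") or rec.get("ID") or rec.name or "motif"
            tf_name = rec.get("ID") or rec.get("NA") or motif_id
        else:
            motif_id = rec.matrix_id or rec.name
            tf_name = rec.name or motif_id
        out.append(MotifModel.from_counts(motif_id, tf_name, counts,
                                          mss_cutoff=mss_cutoff,
                                          css_cutoff=css_cutoff))
    if not out:
        raise FormatError(f"{path}: no motifs found")
    return out


def write_motifs_transfac(motif_list, path) -> None:
    """Write motifs as TRANSFAC blocks.

    The count columns carry the raw (pre-pseudocount) frequencies at full
    precision, so write -> read round-trips are lossless; the TRANSFAC
    dialect accepts fractional counts.
    """
    with open(path, "w") as fh:
        fh.write("VV  upstreamkit motif library\nXX\n//\n")
        for m in motif_list:
            fh.write(f"AC  {m.motif_id}\nXX\nID  {m.tf_name}\nXX\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(m.raw_freqs, start=1):
                fh.write(f"{i:02d}      "
                         + "      ".join(f"{c:.10g}" for c in row) + "\n")
            fh.write("XX\n//\n")


def write_motifs_jaspar(motif_list, path) -> None:
    with open(path, "w") as fh:
        for m in motif_list:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{c:.10g}" for c in m.raw_freqs[:, bi])
                fh.write(f"{base}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# Signaling network
# ---------------------------------------------------------------------------

@dataclass
class SignalingNetwork:
    """Directed, typed molecular network.

    ``graph`` is a :class:`networkx.MultiDiGraph` whose edges carry ``sign``
    (+1/-1) and ``kind`` (SIGNALING/TRANSCRIPTION) attributes and whose nodes
    carry ``kind`` in {PROTEIN, COMPLEX, TF}.  ``gene_of`` maps a molecule to
    the gene encoding it (partial).
    """

    graph: nx.MultiDiGraph
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n, data in self.graph.nodes(data=True):
            kind = data.get("kind", "PROTEIN")
            if kind not in NODE_KINDS:
                raise FormatError(f"node {n}: unknown kind {kind!r}")
        for u, v, data in self.graph.edges(data=True):
            if data.get("kind") not in EDGE_KINDS:
                raise FormatError(f"edge {u}->{v}: unknown kind {data.get('kind')!r}")
            if data.get("sign") not in (+1, -1):
                raise FormatError(f"edge {u}->{v}: sign must be +1/-1")
            if data["kind"] == "TRANSCRIPTION":
                if self.graph.nodes[u].get("kind") != "TF":
                    raise FormatError(
                        f"TRANSCRIPTION edge {u}->{v}: source must be a TF node"
                    )
                if v not in self.gene_of:
                    raise FormatError(
                        f"TRANSCRIPTION edge {u}->{v}: target carries no gene"
                    )

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def node_kind(self, node: str) -> str:
        return self.graph.nodes[node].get("kind", "PROTEIN")

    def edges(self) -> list[tuple[str, str, int, str]]:
        return sorted((u, v, d["sign"], d["kind"])
                      for u, v, d in self.graph.edges(data=True))

    def signaling_digraph(self) -> nx.DiGraph:
        """Collapse SIGNALING edges to a simple DiGraph (first sign wins)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.graph.nodes(data=True))
        for u, v, d in self.graph.edges(data=True):
            if d["kind"] == "SIGNALING" and not g.has_edge(u, v):
                g.add_edge(u, v, sign=d["sign"])
        return g

    def transcription_targets(self, tf: str) -> set[str]:
        return {v for _, v, d in self.graph.out_edges(tf, data=True)
                if d["kind"] == "TRANSCRIPTION"}


_SIGN_TOKENS = {"+": 1, "+1": 1, "1": 1, "-": -1, "-1": -1}


def read_network(path, nodes_path=None) -> SignalingNetwork:
    """Read a ``source<TAB>target<TAB>sign<TAB>kind`` edge list.

    With a companion node table (``node<TAB>kind[<TAB>gene]``) node kinds and
    gene assignments are explicit and dangling endpoints are an error;
    without one, undeclared endpoints default to PROTEIN nodes.
    """
    declared: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    if nodes_path is not None:
        ndf = pd.read_csv(nodes_path, sep="\t", header=None, comment="#",
                          names=["node", "kind", "gene"], dtype=str)
        for _, row in ndf.iterrows():
            kind = str(row["kind"]).upper()
            if kind not in NODE_KINDS:
                raise FormatError(f"node {row['node']}: unknown kind token {kind!r}")
            declared[str(row["node"])] = kind
            if isinstance(row["gene"], str) and row["gene"] and row["gene"] != "nan":
                gene_of[str(row["node"])] = str(row["gene"])

    graph = nx.MultiDiGraph()
    for n, k in declared.items():
        graph.add_node(n, kind=k)

    edf = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["source", "target", "sign", "kind"], dtype=str)
    for _, row in edf.iterrows():
        u, v = str(row["source"]), str(row["target"])
        sign_tok = str(row["sign"]).strip()
        if sign_tok not in _SIGN_TOKENS:
            raise FormatError(f"edge {u}->{v}: unknown sign token {sign_tok!r}")
        kind = str(row["kind"]).strip().upper()
        if kind not in EDGE_KINDS:
            raise FormatError(f"edge {u}->{v}: unknown kind token {kind!r}")
        for endpoint in (u, v):
            if endpoint not in graph:
                if declared:
                    raise FormatError(
                        f"edge {u}->{v}: endpoint {endpoint!r} not in node table"
                    )
                graph.add_node(endpoint, kind="PROTEIN")
        graph.add_edge(u, v, sign=_SIGN_TOKENS[sign_tok], kind=kind)
    return SignalingNetwork(graph, gene_of)


def write_network(network: SignalingNetwork, path, nodes_path=None) -> None:
    with open(path, "w") as fh:
        for u, v, sign, kind in network.edges():
            fh.write(f"{u}\t{v}\t{'+1' if sign > 0 else '-1'}\t{kind}\n")
    if nodes_path is not None:
        with open(nodes_path, "w") as fh:
            for n in sorted(network.graph.nodes):
                gene = network.gene_of.get(n, "")
                fh.write(f"{n}\t{network.node_kind(n)}\t{gene}\n")


# ---------------------------------------------------------------------------
# Small table helpers shared by the pipeline stages
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
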