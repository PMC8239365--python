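"""Per-motif binding-site enrichment in yes- versus no-promoters.

For each motif the yes/no ratio compares occurrences per promoter between the
two sets (with a Haldane-Anscombe 1/2 pseudocount), and significance comes
from an exact binomial upper tail: conditioning on the total occurrence count
n = occ_yes + occ_no, under the null each occurrence falls into the yes set
with probability p0 equal to the yes share of scannable positions (the
"length-proportional" null), so

    p_binom = P[Binomial(n, p0) >= occ_yes],

summed exactly in log space.  A per-promoter presence/absence variant is
available as an alternative null.  P-values are BH-adjusted across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust
from .formats_io import get_logger
from .motif_scan import MotifModel

_log = get_logger(__name__)


@dataclass
class EnrichmentRecord:
    motif_id: str
    tf_name: str
    occ_yes: int
    occ_no: int
    n_yes: int
    n_no: int
    L_yes: int
    L_no: int
    ratio: float
    p_binom: float
    p_adj: float = 1.0


def binom_tail(k: int, n: int, p0: float) -> float:
    """Exact upper tail P[X >= k], X ~ Binomial(n, p0), via log-space summation.

    k <= 0 returns 1 (the whole mass); p0 on the boundary degenerates to the
    point masses at 0 or n.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p0 <= 0.0:
        return 0.0
    if p0 >= 1.0:
        return 1.0
    i = np.arange(k, n + 1)
    logterms = (gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
                + i * np.log(p0) + (n - i) * np.log1p(-p0))
    return float(min(1.0, np.exp(logsumexp(logterms))))


def dedupe_hits(hits: pd.DataFrame,
                motif_list: Sequence[MotifModel]) -> pd.DataFrame:
    """Collapse overlapping same-gene, same-motif hits to the strongest one.

    The scanner deliberately keeps every passing offset on both strands; for
    occurrence counting those overlapping matches are one physical site, and
    counting them separately would violate the independence the binomial
    null assumes.  Greedy selection by descending MSS keeps the best
    representative of each overlap cluster.
    """
    if not len(hits):
        return hits
    length_of = {m.motif_id: m.length for m in motif_list}
    kept = []
    for (gene, motif), sub in hits.groupby(["gene", "motif"], sort=False):
        L = length_of.get(motif)
        if L is None:
            continue
        taken: list[tuple[int, int]] = []
        for row in sub.sort_values(["mss", "start"],
                                   ascending=[False, True]).itertuples():
            s, e = int(row.start), int(row.start) + L
            if all(e <= ts or s >= te for ts, te in taken):
                taken.append((s, e))
                kept.append(row.Index)
    return hits.loc[sorted(kept)]


def enrich(hits: pd.DataFrame,
           yes_genes: Sequence[str],
           no_genes: Sequence[str],
           motif_list: Sequence[MotifModel],
           scannable: pd.DataFrame,
           null_model: str = "length",
           dedupe: bool = True) -> list[EnrichmentRecord]:
    """Per-motif yes/no enrichment records, sorted by (p_binom, -ratio).

    ``scannable`` is the gene x motif exposure table from
    :func:`upstreamkit.motif_scan.scannable_positions`.  ``null_model`` is
    "length" (occurrence counts split proportionally to scannable length,
    the default) or "presence" (promoters with >=1 hit split proportionally
    to promoter counts).  With ``dedupe`` (default) overlapping same-motif
    hits are collapsed before counting.
    """
    yes_set, no_set = set(yes_genes), set(no_genes)
    if not yes_set:
        raise ValueError("yes gene set is empty")
    if yes_set & no_set:
        raise ValueError("yes and no gene sets must be disjoint")
    if null_model not in ("length", "presence"):
        raise ValueError(f"unknown null model {null_model!r}")
    if dedupe:
        hits = dedupe_hits(hits, motif_list)

    n_yes = len(yes_set)
    n_no = len(no_set)
    sc = scannable.set_index(["gene", "motif"])["n_positions"]

    records = []
    for m in motif_list:
        sub = hits[hits["motif"] == m.motif_id] if len(hits) else hits
        in_yes = sub[sub["gene"].isin(yes_set)] if len(sub) else sub
        in_no = sub[sub["gene"].isin(no_set)] if len(sub) else sub
        occ_yes, occ_no = len(in_yes), len(in_no)
        L_yes = int(sum(sc.get((g, m.motif_id), 0) for g in yes_set))
        L_no = int(sum(sc.get((g, m.motif_id), 0) for g in no_set))

        ratio = ((occ_yes + 0.5) / max(n_yes, 1)) / ((occ_no + 0.5) / max(n_no, 1))
        if null_model == "length":
            total = L_yes + L_no
            p0 = L_yes / total if total > 0 else 0.5
            p_binom = binom_tail(occ_yes, occ_yes + occ_no, p0)
        else:
            k = in_yes["gene"].nunique() if occ_yes else 0
            kn = in_no["gene"].nunique() if occ_no else 0
            p0 = n_yes / max(n_yes + n_no, 1)
            p_binom = binom_tail(k, k + kn, p0)
        records.append(EnrichmentRecord(m.motif_id, m.tf_name, occ_yes, occ_no,
                                        n_yes, n_no, L_yes, L_no,
                                        float(ratio), float(p_binom)))

    padj = bh_adjust([max(r.p_binom, np.nextafter(0.0, 1.0)) for r in records])
    for r, a in zip(records, padj):
        r.p_adj = float(a)
    records.sort(key=lambda r: (r.p_binom, -r.ratio, r.motif_id))
    return records


def rank_tfs(records: list[EnrichmentRecord],
             p_cut: float = 0.05,
             ratio_cut: float = 1.0) -> list[EnrichmentRecord]:
    """Candidate TFs: p_adj < p_cut and ratio > ratio_cut, ordered by p_binom
    (ties: larger ratio, then lexicographic motif id).  This list seeds the
    composite-module motif pool."""
    kept = [r for r in records if r.p_adj < p_cut and r.ratio > ratio_cut]
    kept.sort(key=lambda r: (r.p_binom, -r.ratio, r.motif_id))
    if not kept:
        _log.warning("no motif passes p_adj<%g and ratio>%g; candidate TF "
                     "list is empty", p_cut, ratio_cut)
    return kept


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.motif_id, r.tf_name, r.occ_yes, r.occ_no, r.n_yes, r.n_no,
          r.L_yes, r.L_no, r.ratio, r.p_binom, r.p_adj) for r in records],
        columns=["motif", "tf", "occ_yes", "occ_no", "n_yes", "n_no",
                 "L_yes", "L_no", "ratio", "p_binom", "p_adj"])
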