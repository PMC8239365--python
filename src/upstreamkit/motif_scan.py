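"""MATCH-style PWM scanning of promoter sequences.

A motif is scored against every offset of a promoter on both strands with the
information-weighted, min-max-normalized matrix similarity score

    MSS = (Current - Min) / (Max - Min),
    Current = sum_i I(i) * f(i, s_i),

where ``f`` is the pseudocount-regularized frequency matrix, ``I(i) =
sum_b f(i,b) ln(4 f(i,b))`` is the per-position information vector, and
Min/Max substitute the per-position minimum/maximum frequency.  The core
similarity score (CSS) is the same quantity restricted to the 5 consecutive
most informative positions.  MSS is 1 exactly on the consensus sequence and 0
on the anti-consensus; a hit is emitted when both scores pass their cutoffs.

Hits never overlap an N base, and reverse-strand matches are reported by the
TSS-relative coordinate of their 5' end on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import PromoterRecord

PSEUDOCOUNT = 0.001
CORE_LENGTH = 5
DEFAULT_MSS_CUTOFF = 0.75
DEFAULT_CSS_CUTOFF = 0.70

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


def regularize(freqs: np.ndarray, eps: float = PSEUDOCOUNT) -> np.ndarray:
    """Spread a total pseudocount mass eps over the four bases of each
    position and renormalize, so no frequency is exactly zero."""
    f = np.asarray(freqs, dtype=float)
    f = f + eps / 4.0
    return f / f.sum(axis=1, keepdims=True)


def information_vector(freqs: np.ndarray, eps: float = PSEUDOCOUNT) -> np.ndarray:
    """I(i) = sum_b f(i,b) ln(4 f(i,b)) on the regularized matrix; in [0, ln 4]."""
    f = regularize(freqs, eps)
    return np.sum(f * np.log(4.0 * f), axis=1)


def core_start(info: np.ndarray, core_len: int = CORE_LENGTH) -> int:
    """Start of the ``core_len`` consecutive positions maximizing summed info.

    Ties resolve to the leftmost window; motifs shorter than the core use the
    whole matrix (core_start 0).
    """
    L = len(info)
    if L <= core_len:
        return 0
    sums = np.convolve(info, np.ones(core_len), mode="valid")
    return int(np.argmax(sums))  # argmax is leftmost on ties


@dataclass
class MotifModel:
    """A PFM with its MATCH scoring state (information vector, core, cutoffs)."""

    motif_id: str
    tf_name: str
    freqs: np.ndarray            # L x 4, rows sum to 1 after regularization
    info: np.ndarray = field(default=None)  # type: ignore[assignment]
    core_start: int = -1
    mss_cutoff: float = DEFAULT_MSS_CUTOFF
    css_cutoff: float = DEFAULT_CSS_CUTOFF
    raw_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]
    _regularized: bool = False

    def __post_init__(self) -> None:
        if not self._regularized:
            if self.raw_freqs is None:
                f = np.asarray(self.freqs, dtype=float)
                self.raw_freqs = f / f.sum(axis=1, keepdims=True)
            self.freqs = regularize(self.freqs)
            self._regularized = True
        elif self.raw_freqs is None:
            self.raw_freqs = self.freqs
        if self.info is None:
            self.info = np.sum(self.freqs * np.log(4.0 * self.freqs), axis=1)
        if self.core_start < 0:
            self.core_start = core_start(self.info)
        if not (0.0 <= self.mss_cutoff <= 1.0 and 0.0 <= self.css_cutoff <= 1.0):
            raise ValueError("cutoffs must lie in [0, 1]")

    @classmethod
    def from_counts(cls, motif_id: str, tf_name: str, counts: np.ndarray,
                    mss_cutoff: float = DEFAULT_MSS_CUTOFF,
                    css_cutoff: float = DEFAULT_CSS_CUTOFF) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 4:
            raise ValueError("counts must be an Lx4 matrix with L >= 4")
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("zero-sum position in count matrix")
        return cls(motif_id, tf_name, counts / sums,
                   mss_cutoff=mss_cutoff, css_cutoff=css_cutoff)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def core_slice(self) -> slice:
        return slice(self.core_start,
                     min(self.core_start + CORE_LENGTH, self.length))

    def consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmax(self.freqs, axis=1))

    def anti_consensus(self) -> str:
        return "".join("ACGT"[b] for b in np.argmin(self.freqs, axis=1))

    def reverse_complement(self) -> "MotifModel":
        """Mirror the matrix; the core is mirrored too (not recomputed) so
        forward/reverse scanning is exactly strand-symmetric even when the
        information profile has ties."""
        rc_freqs = self.freqs[::-1, :][:, [3, 2, 1, 0]]
        rc_core = self.length - (self.core_start + min(CORE_LENGTH, self.length))
        return MotifModel(self.motif_id, self.tf_name, rc_freqs,
                          info=self.info[::-1].copy(), core_start=max(rc_core, 0),
                          mss_cutoff=self.mss_cutoff, css_cutoff=self.css_cutoff,
                          raw_freqs=self.raw_freqs[::-1, :][:, [3, 2, 1, 0]],
                          _regularized=True)


@dataclass(frozen=True)
class SiteHit:
    """One PWM match; ``start`` is the forward-strand 5' end, TSS-relative."""

    gene_id: str
    motif_id: str
    start: int
    strand: str
    mss: float
    css: float


def encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in sequence], dtype=np.int8)


def _window_scores(codes: np.ndarray, freqs: np.ndarray, info: np.ndarray,
                   core: slice) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mss, css, valid) for every offset of ``codes`` against one matrix."""
    L = freqs.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        empty = np.empty(0)
        return empty, empty, np.empty(0, dtype=bool)
    # Extend with an N column so windows touching an N score NaN-free but are
    # flagged invalid via the mask below.
    weighted = info[:, None] * freqs              # L x 4
    weighted = np.concatenate([weighted, np.zeros((L, 1))], axis=1)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)  # n x L
    pos = np.arange(L)
    cur = weighted[pos, win].sum(axis=1)
    valid = ~(win == 4).any(axis=1)

    lo = (info * freqs.min(axis=1)).sum()
    hi = (info * freqs.max(axis=1)).sum()
    mss = (cur - lo) / max(hi - lo, 1e-12)

    cpos = pos[core]
    ccur = weighted[cpos, win[:, core]].sum(axis=1)
    clo = (info[core] * freqs[core].min(axis=1)).sum()
    chi = (info[core] * freqs[core].max(axis=1)).sum()
    css = (ccur - clo) / max(chi - clo, 1e-12)
    return mss, css, valid


def scan(promoter: PromoterRecord, motif: MotifModel,
         mss_cutoff: float | None = None,
         css_cutoff: float | None = None) -> list[SiteHit]:
    """All passing hits of one motif in one promoter, both strands.

    A promoter shorter than the motif yields an empty list.  Hits are sorted
    by (start, strand).
    """
    mss_cut = motif.mss_cutoff if mss_cutoff is None else mss_cutoff
    css_cut = motif.css_cutoff if css_cutoff is None else css_cutoff
    codes = encode(promoter.sequence)
    # the minus strand scans the reverse-complemented sequence with the
    # forward matrix, so forward/reverse arithmetic is identical and strand
    # symmetry holds bit-exactly
    codes_rc = _COMPLEMENT[codes][::-1]
    L_seq, L_m = len(codes), motif.length
    hits: list[SiteHit] = []
    for strand, c in (("+", codes), ("-", codes_rc)):
        mss, css, valid = _window_scores(c, motif.freqs, motif.info,
                                         motif.core_slice)
        keep = valid & (mss >= mss_cut) & (css >= css_cut)
        for off in np.nonzero(keep)[0]:
            off = int(off)
            fwd_off = off if strand == "+" else L_seq - (off + L_m)
            hits.append(SiteHit(promoter.gene_id, motif.motif_id,
                                promoter.window_start + fwd_off, strand,
                                float(mss[off]), float(css[off])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_all(promoters: Sequence[PromoterRecord],
             motif_list: Sequence[MotifModel],
             mss_cutoff: float | None = None,
             css_cutoff: float | None = None) -> pd.DataFrame:
    """Hit table over all promoters and motifs.

    Columns: gene, motif, tf, start, strand, mss, css; deterministically
    ordered by (gene, motif, start, strand).  Empty inputs yield an empty
    table with the same columns.
    """
    tf_of = {m.motif_id: m.tf_name for m in motif_list}
    rows = []
    for p in promoters:
        for m in motif_list:
            for h in scan(p, m, mss_cutoff, css_cutoff):
                rows.append((h.gene_id, h.motif_id, tf_of[h.motif_id],
                             h.start, h.strand, h.mss, h.css))
    df = pd.DataFrame(rows, columns=["gene", "motif", "tf", "start",
                                     "strand", "mss", "css"])
    return df.sort_values(["gene", "motif", "start", "strand"],
                          kind="mergesort").reset_index(drop=True)


def calibrate_cutoffs(motif_list: Sequence[MotifModel],
                      target_rate: float = 1e-3,
                      n_bp: int = 50_000,
                      gc: float = 0.5,
                      seed: int = 0,
                      floor: float = DEFAULT_MSS_CUTOFF
                      ) -> list[MotifModel]:
    """Per-motif MSS cutoffs calibrated to a common background hit rate.

    A single global cutoff makes occurrence counts incomparable across
    matrices of different length and information profile (a permissive
    8-mer can emit an order of magnitude more chance hits than a sharp
    14-mer).  Following the MATCH profile idea, each motif's cutoff is set
    to the (1 - target_rate) quantile of its MSS distribution on random
    GC-matched background, never below ``floor``.  The default target of
    1e-3 per scanned position-strand corresponds to the classic "about one
    chance site per kilobase" futility rate.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=n_bp, p=probs).astype(np.int8)
    codes_rc = _COMPLEMENT[codes][::-1]
    out = []
    for m in motif_list:
        scores = []
        for c in (codes, codes_rc):
            mss, _, _ = _window_scores(c, m.freqs, m.info, m.core_slice)
            scores.append(mss)
        q = float(np.quantile(np.concatenate(scores), 1.0 - target_rate))
        out.append(replace(m, mss_cutoff=max(floor, min(q, 0.999)),
                           _regularized=True))
    return out


def scannable_positions(promoters: Sequence[PromoterRecord],
                        motif_list: Sequence[MotifModel]) -> pd.DataFrame:
    """Count of scorable offsets (both strands, N-free) per gene x motif.

    This is the exposure used by the length-proportional enrichment null.
    """
    rows = []
    for p in promoters:
        codes = encode(p.sequence)
        is_n = codes == 4
        for m in motif_list:
            n = p.length - m.length + 1
            if n <= 0:
                count = 0
            else:
                win_has_n = np.convolve(is_n.astype(int),
                                        np.ones(m.length, dtype=int),
                                        mode="valid") > 0
                count = 2 * int((~win_has_n).sum())
            rows.append((p.gene_id, m.motif_id, count))
    return pd.DataFrame(rows, columns=["gene", "motif", "n_positions"])
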