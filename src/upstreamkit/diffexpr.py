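"""Two-group moderated differential expression with empirical-Bayes shrinkage.

For each gene g the log2 fold change is the YES-group mean minus the NO-group
mean (YES = short-term survivors in the motivating application; the sign
convention is stated in every output header).  Residual variances are shrunk
toward a common prior by the standard moderated-t construction

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

with the prior degrees of freedom d0 and prior variance s0^2 estimated by
method of moments on log s_g^2 (closed form via trigamma inversion).  The
moderated t follows a t distribution with d0 + d_g degrees of freedom, and
p-values are Benjamini-Hochberg adjusted across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .formats_io import NO, YES, ExpressionMatrix, get_logger

DEFAULT_ALPHA = 0.05
DEFAULT_LFC = 0.5
FALLBACK_D0 = 4.0

UP = "UP"
DOWN = "DOWN"
NS = "NS"

_log = get_logger(__name__)


@dataclass
class DEResult:
    gene_id: str
    log2fc: float
    t_mod: float
    df: float
    p: float
    p_adj: float
    direction: str


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) from per-gene sample variances.

    Works on z = log s^2: Var(z) = trigamma(dg/2) + trigamma(d0/2), so d0
    comes from inverting the trigamma function on the excess variance.  When
    the moment equation has no root (observed spread no larger than the
    chi-square sampling noise) a fixed fallback d0 = 4 is used.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        return FALLBACK_D0, float(np.mean(s2)) if np.mean(s2) > 0 else 1e-12
    e = np.log(pos) - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, dg / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
    else:
        d0 = FALLBACK_D0
    s02 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


def moderated_de(matrix: ExpressionMatrix,
                 alpha: float = DEFAULT_ALPHA,
                 lfc: float = DEFAULT_LFC,
                 d0: float | None = None,
                 s02: float | None = None) -> list[DEResult]:
    """Moderated two-group t-test per gene.

    ``d0``/``s02`` override the estimated prior (``d0=np.inf`` gives the
    common-variance limit, ``d0=0`` the ordinary per-gene t).  Each group
    needs at least 2 samples.
    """
    yi = matrix.group_columns(YES)
    ni = matrix.group_columns(NO)
    n1, n2 = len(yi), len(ni)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >=2 samples (YES={n1}, NO={n2})")

    x1 = matrix.values[:, yi]
    x2 = matrix.values[:, ni]
    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    dg = float(n1 + n2 - 2)
    # pooled within-group variance per gene
    s2 = (((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) +
          ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)) / dg

    est_d0, est_s02 = fit_variance_prior(s2, dg)
    d0 = est_d0 if d0 is None else float(d0)
    s02 = est_s02 if s02 is None else float(s02)

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s02)
    else:
        s2_mod = (d0 * s02 + dg * s2) / (d0 + dg)
    s2_mod = np.maximum(s2_mod, 1e-300)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t_mod = log2fc / se
    df = d0 + dg
    p = 2.0 * stats.t.sf(np.abs(t_mod), df)
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    p_adj = bh_adjust(p)

    out = []
    for i, g in enumerate(matrix.gene_ids):
        if p_adj[i] < alpha and log2fc[i] > lfc:
            direction = UP
        elif p_adj[i] < alpha and log2fc[i] < -lfc:
            direction = DOWN
        else:
            direction = NS
        out.append(DEResult(g, float(log2fc[i]), float(t_mod[i]), float(df),
                            float(p[i]), float(p_adj[i]), direction))
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; input must lie in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_degs(results: list[DEResult],
                alpha: float = DEFAULT_ALPHA,
                tau: float = DEFAULT_LFC,
                no_lfc_max: float = 0.1,
                no_cap_factor: int = 10,
                seed: int = 0) -> tuple[list[str], list[str]]:
    """Split genes into the promoter yes set (UP) and the background no set.

    The no set is the expression-matched background: non-significant genes
    with |log2FC| < ``no_lfc_max``, capped at ``no_cap_factor`` times the yes
    set by seeded subsampling so downstream scanning stays bounded.
    """
    if not results:
        raise ValueError("empty DE result list")
    yes = [r.gene_id for r in results
           if r.p_adj < alpha and r.log2fc > tau]
    if not yes:
        _log.warning("no significantly upregulated genes at "
                     "alpha=%g, lfc>%g; yes set is empty", alpha, tau)
    ns_pool = [r.gene_id for r in results
               if r.direction == NS and abs(r.log2fc) < no_lfc_max]
    cap = max(no_cap_factor * max(len(yes), 1), 1)
    if len(ns_pool) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(ns_pool), size=cap, replace=False)
        ns_pool = [ns_pool[i] for i in sorted(idx)]
    no = [g for g in ns_pool if g not in set(yes)]
    return yes, no


def de_table(results: list[DEResult]):
    """DE results as a DataFrame (log2FC = YES mean - NO mean)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.t_mod, r.df, r.p, r.p_adj, r.direction)
         for r in results],
        columns=["gene", "log2fc", "t_mod", "df", "p", "p_adj", "direction"])
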