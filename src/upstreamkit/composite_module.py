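"""Composite-module discovery by a seeded genetic algorithm.

A composite module is a small set of motifs, each with its own score
threshold theta and weight w, plus a window width W.  A promoter's module
score is the best window placement:

    score = max over windows [s, s+W) of sum_m w_m * max(0, best_mss_m - theta_m)

where best_mss_m is the highest matrix-similarity score of motif m among
hits whose 5' end falls inside the window.  The module objective ("fitness")
is the Welch t-statistic of module scores between yes- and no-promoters minus
a complexity penalty lambda*k; a Mann-Whitney alternative is pluggable.

The GA uses tournament selection (size 3), uniform crossover on motif slots,
mutation (motif swap / theta jitter +-0.05 / weight jitter xU(0.8,1.25) /
window jitter +-50) and elitism, and is fully deterministic under its seed.
Module significance is assessed by label permutation with thresholds and
weights refit per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d

from .formats_io import PromoterRecord, get_logger

_log = get_logger(__name__)

THETA_GRID = tuple(np.round(np.arange(0.70, 0.951, 0.05), 2))
W_GRID = tuple(range(100, 601, 50))
DEFAULT_W = 300
DEFAULT_LAMBDA = 0.1
VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class ModuleMotif:
    motif_id: str
    theta: float
    weight: float


@dataclass
class CompositeModule:
    """A fitted composite module; weights are normalized to sum to 1."""

    motifs: list[ModuleMotif]
    window_W: int
    fitness: float = float("nan")
    p_perm: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.motifs) < 2:
            raise ValueError("a composite module needs at least 2 motifs")
        total = sum(m.weight for m in self.motifs)
        if total <= 0:
            raise ValueError("module weights must be positive")
        if abs(total - 1.0) > 1e-9:
            self.motifs = [ModuleMotif(m.motif_id, m.theta, m.weight / total)
                           for m in self.motifs]

    @property
    def k(self) -> int:
        return len(self.motifs)

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    def to_dict(self) -> dict:
        return {"window_W": self.window_W, "fitness": self.fitness,
                "p_perm": self.p_perm,
                "motifs": [{"motif_id": m.motif_id, "theta": m.theta,
                            "weight": m.weight} for m in self.motifs]}

    @classmethod
    def from_dict(cls, d: dict) -> "CompositeModule":
        mod = cls([ModuleMotif(m["motif_id"], m["theta"], m["weight"])
                   for m in d["motifs"]], int(d["window_W"]))
        mod.fitness = float(d.get("fitness", float("nan")))
        mod.p_perm = float(d.get("p_perm", float("nan")))
        return mod


@dataclass
class RegulatoryScore:
    gene_id: str
    score: float


# ---------------------------------------------------------------------------
# Fast promoter/hit index
# ---------------------------------------------------------------------------

def _sliding_max(x: np.ndarray, W: int) -> np.ndarray:
    """out[..., s] = max(x[..., s:s+W]) for s = 0..L-W (left-aligned)."""
    L = x.shape[-1]
    if W >= L:
        return x.max(axis=-1, keepdims=True)
    y = maximum_filter1d(x, size=W, axis=-1, mode="constant", cval=-np.inf)
    # origin 0 centers the window: y[i] = max(x[i - W//2 : i - W//2 + W])
    return y[..., W // 2: W // 2 + (L - W + 1)]


class PromoterHitIndex:
    """Dense per-position best-MSS arrays with cached windowed maxima.

    ``A[g, m, i]`` is the best MSS of a hit of motif m whose 5' end sits at
    local position i of promoter g (-inf where no hit starts), which makes a
    module evaluation a handful of vectorized array operations.
    """

    def __init__(self, hits: pd.DataFrame,
                 promoters: Sequence[PromoterRecord],
                 motif_ids: Sequence[str]):
        self.genes = [p.gene_id for p in promoters]
        self.gene_pos = {g: i for i, g in enumerate(self.genes)}
        self.motif_ids = list(motif_ids)
        self.motif_pos = {m: i for i, m in enumerate(self.motif_ids)}
        self.window_start = {p.gene_id: p.window_start for p in promoters}
        self.lengths = np.array([p.length for p in promoters])
        Lmax = int(self.lengths.max()) if len(promoters) else 0
        self.A = np.full((len(self.genes), len(self.motif_ids), Lmax),
                         -np.inf)
        if len(hits):
            sub = hits[hits["gene"].isin(self.gene_pos)
                       & hits["motif"].isin(self.motif_pos)]
            for gene, motif, start, mss in zip(sub["gene"], sub["motif"],
                                               sub["start"], sub["mss"]):
                g = self.gene_pos[gene]
                m = self.motif_pos[motif]
                i = int(start) - self.window_start[gene]
                if 0 <= i < Lmax and mss > self.A[g, m, i]:
                    self.A[g, m, i] = mss
        self._wincache: dict[tuple[int, int], np.ndarray] = {}

    def windowed(self, m_idx: int, W: int) -> np.ndarray:
        key = (m_idx, W)
        if key not in self._wincache:
            self._wincache[key] = _sliding_max(self.A[:, m_idx, :], W)
        return self._wincache[key]

    def module_scores(self, module: CompositeModule) -> np.ndarray:
        """Per-promoter module score, vectorized over all indexed genes."""
        acc = None
        for mm in module.motifs:
            m_idx = self.motif_pos.get(mm.motif_id)
            if m_idx is None:
                continue
            contrib = mm.weight * np.maximum(
                0.0, self.windowed(m_idx, module.window_W) - mm.theta)
            acc = contrib if acc is None else acc + contrib
        if acc is None:
            return np.zeros(len(self.genes))
        return acc.max(axis=-1)


def module_score(promoter_hits: pd.DataFrame, module: CompositeModule,
                 promoter: PromoterRecord) -> float:
    """Reference single-promoter score: explicit enumeration of every window
    start (the vectorized index must agree with this exactly)."""
    L = promoter.length
    W = min(module.window_W, L)
    best = {mm.motif_id: np.full(L, -np.inf) for mm in module.motifs}
    if len(promoter_hits):
        for motif, start, mss in zip(promoter_hits["motif"],
                                     promoter_hits["start"],
                                     promoter_hits["mss"]):
            if motif in best:
                i = int(start) - promoter.window_start
                if 0 <= i < L and mss > best[motif][i]:
                    best[motif][i] = mss
    out = 0.0
    for s in range(0, L - W + 1):
        total = 0.0
        for mm in module.motifs:
            b = best[mm.motif_id][s:s + W].max()
            total += mm.weight * max(0.0, b - mm.theta)
        out = max(out, total)
    return out


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------

def welch_t(yes_scores: np.ndarray, no_scores: np.ndarray) -> float:
    """Welch t-statistic with variance floored at 1e-12 (degenerate inputs)."""
    y = np.asarray(yes_scores, dtype=float)
    n = np.asarray(no_scores, dtype=float)
    v1 = max(np.var(y, ddof=1) if y.size > 1 else 0.0, VAR_FLOOR)
    v2 = max(np.var(n, ddof=1) if n.size > 1 else 0.0, VAR_FLOOR)
    return float((y.mean() - n.mean()) / np.sqrt(v1 / y.size + v2 / n.size))


def mannwhitney_stat(yes_scores: np.ndarray, no_scores: np.ndarray) -> float:
    """Normal-approximation z of the Mann-Whitney U (pluggable alternative)."""
    from scipy.stats import rankdata

    y = np.asarray(yes_scores, float)
    n = np.asarray(no_scores, float)
    ranks = rankdata(np.concatenate([y, n]))
    u = ranks[: y.size].sum() - y.size * (y.size + 1) / 2.0
    mu = y.size * n.size / 2.0
    sd = np.sqrt(max(y.size * n.size * (y.size + n.size + 1) / 12.0, VAR_FLOOR))
    return float((u - mu) / sd)


FITNESS_FUNCTIONS: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "welch": welch_t,
    "mannwhitney": mannwhitney_stat,
}


def fitness(module: CompositeModule,
            yes_scores: np.ndarray, no_scores: np.ndarray,
            lam: float = DEFAULT_LAMBDA,
            stat: str = "welch") -> float:
    """Discrimination statistic minus the complexity penalty lambda * k."""
    return FITNESS_FUNCTIONS[stat](yes_scores, no_scores) - lam * module.k


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class CMAConfig:
    k_max: int = 6
    n_modules: int = 2
    pop: int = 200
    gens: int = 100
    p_mut: float = 0.3
    p_cross: float = 0.7
    seed: int = 0
    lam: float = DEFAULT_LAMBDA
    theta_grid: tuple = THETA_GRID
    w_grid: tuple = W_GRID
    w_init: int = DEFAULT_W
    fitness_stat: str = "welch"
    tournament: int = 3
    # additional modules (beyond the best one) are kept only if their
    # fitness clears this floor; on the Welch-t scale 3.0 demands strong
    # discrimination, guarding against overfit leftover-motif modules
    min_fitness: float = 3.0


# chromosome = (tuple of (motif_id, theta, weight) sorted by motif_id, W)
Chromosome = tuple[tuple[tuple[str, float, float], ...], int]


def _chrom_to_module(chrom: Chromosome) -> CompositeModule:
    motifs, W = chrom
    return CompositeModule([ModuleMotif(m, t, w) for m, t, w in motifs], W)


def _normalize(chrom: Chromosome) -> Chromosome:
    motifs, W = chrom
    total = sum(w for _, _, w in motifs)
    return (tuple(sorted((m, round(t, 6), w / total) for m, t, w in motifs)),
            int(W))


def _random_chrom(pool: Sequence[str], cfg: CMAConfig,
                  rng: np.random.Generator) -> Chromosome:
    k = int(rng.integers(2, min(cfg.k_max, len(pool)) + 1))
    ids = list(rng.choice(list(pool), size=k, replace=False))
    motifs = tuple((m, float(rng.choice(cfg.theta_grid)),
                    float(rng.uniform(0.5, 1.5))) for m in sorted(ids))
    return _normalize((motifs, cfg.w_init))


def _crossover(a: Chromosome, b: Chromosome, pool: Sequence[str],
               cfg: CMAConfig, rng: np.random.Generator) -> Chromosome:
    sa, sb = list(a[0]), list(b[0])
    slots = max(len(sa), len(sb))
    child: dict[str, tuple[str, float, float]] = {}
    for i in range(slots):
        options = [s[i] for s in (sa, sb) if i < len(s)]
        gene = options[int(rng.integers(len(options)))]
        child.setdefault(gene[0], gene)
    while len(child) < 2:
        unused = [m for m in pool if m not in child]
        m = str(rng.choice(unused))
        child[m] = (m, float(rng.choice(cfg.theta_grid)),
                    float(rng.uniform(0.5, 1.5)))
    if len(child) > cfg.k_max:
        keep = list(rng.choice(sorted(child), size=cfg.k_max, replace=False))
        child = {m: child[m] for m in keep}
    W = a[1] if rng.random() < 0.5 else b[1]
    return _normalize((tuple(child.values()), W))


def _mutate(chrom: Chromosome, pool: Sequence[str], cfg: CMAConfig,
            rng: np.random.Generator) -> Chromosome:
    motifs, W = list(chrom[0]), chrom[1]
    op = int(rng.integers(4))
    i = int(rng.integers(len(motifs)))
    m, t, w = motifs[i]
    if op == 0:  # motif swap
        unused = [x for x in pool if x not in {mm[0] for mm in motifs}]
        if unused:
            motifs[i] = (str(rng.choice(unused)), t, w)
    elif op == 1:  # theta jitter
        t2 = t + float(rng.choice([-0.05, 0.05]))
        t2 = min(max(t2, cfg.theta_grid[0]), cfg.theta_grid[-1])
        motifs[i] = (m, t2, w)
    elif op == 2:  # weight jitter
        motifs[i] = (m, t, w * float(rng.uniform(0.8, 1.25)))
    else:  # window jitter
        W = min(max(W + int(rng.choice([-50, 50])), cfg.w_grid[0]),
                cfg.w_grid[-1])
    return _normalize((tuple(motifs), W))


def _evolve(index: PromoterHitIndex, yes_mask: np.ndarray, no_mask: np.ndarray,
            pool: Sequence[str], cfg: CMAConfig,
            rng: np.random.Generator) -> tuple[Chromosome, float, list[float]]:
    cache: dict[Chromosome, float] = {}

    def evaluate(ch: Chromosome) -> float:
        if ch not in cache:
            mod = _chrom_to_module(ch)
            scores = index.module_scores(mod)
            cache[ch] = fitness(mod, scores[yes_mask], scores[no_mask],
                                lam=cfg.lam, stat=cfg.fitness_stat)
        return cache[ch]

    population = [_random_chrom(pool, cfg, rng) for _ in range(cfg.pop)]
    fits = [evaluate(c) for c in population]
    history: list[float] = []
    for _ in range(cfg.gens):
        order = int(np.argmax(fits))
        elite, elite_fit = population[order], fits[order]
        history.append(elite_fit)
        nxt, nxt_fits = [elite], [elite_fit]

        def tournament() -> Chromosome:
            idx = rng.integers(len(population), size=cfg.tournament)
            best = max(idx, key=lambda j: (fits[j], -j))
            return population[int(best)]

        while len(nxt) < cfg.pop:
            p1, p2 = tournament(), tournament()
            child = (_crossover(p1, p2, pool, cfg, rng)
                     if rng.random() < cfg.p_cross else p1)
            if rng.random() < cfg.p_mut:
                child = _mutate(child, pool, cfg, rng)
            nxt.append(child)
            nxt_fits.append(evaluate(child))
        population, fits = nxt, nxt_fits
    best_i = int(np.argmax(fits))
    history.append(fits[best_i])
    return population[best_i], fits[best_i], history


def run_cma(hits: pd.DataFrame,
            promoters: Sequence[PromoterRecord],
            yes_genes: Sequence[str],
            no_genes: Sequence[str],
            motif_pool: Sequence[str],
            config: CMAConfig | None = None
            ) -> tuple[list[CompositeModule], pd.DataFrame, list[list[float]]]:
    """Fit up to ``n_modules`` motif-disjoint composite modules.

    Returns (modules, per-promoter score table, per-module best-fitness
    histories).  Identical seed gives identical results.
    """
    cfg = config or CMAConfig()
    pool = sorted(dict.fromkeys(motif_pool))
    if len(pool) < 2:
        raise ValueError("motif pool must contain at least 2 motifs")
    keep = [p for p in promoters if p.gene_id in set(yes_genes) | set(no_genes)]
    index = PromoterHitIndex(hits, keep, pool)
    yes_mask = np.array([g in set(yes_genes) for g in index.genes])
    no_mask = np.array([g in set(no_genes) for g in index.genes])
    if not yes_mask.any() or not no_mask.any():
        raise ValueError("both promoter sets must be non-empty")

    ss = np.random.SeedSequence(cfg.seed)
    modules: list[CompositeModule] = []
    histories: list[list[float]] = []
    remaining = list(pool)
    for child_seed in ss.spawn(cfg.n_modules):
        if len(remaining) < 2:
            break
        rng = np.random.default_rng(child_seed)
        chrom, fit, hist = _evolve(index, yes_mask, no_mask, remaining,
                                   cfg, rng)
        if modules and fit < cfg.min_fitness:
            break  # secondary module does not discriminate; stop here
        mod = _chrom_to_module(chrom)
        mod.fitness = fit
        modules.append(mod)
        histories.append(hist)
        remaining = [m for m in remaining if m not in set(mod.motif_ids)]

    score_cols = {"gene": index.genes}
    combined = np.zeros(len(index.genes))
    for i, mod in enumerate(modules, start=1):
        s = index.module_scores(mod)
        score_cols[f"score_module{i}"] = s
        combined = combined + s
    score_cols["score_combined"] = combined
    return modules, pd.DataFrame(score_cols), histories


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def _refit_fitness(index: PromoterHitIndex, motif_ids: Sequence[str], W: int,
                   yes_mask: np.ndarray, no_mask: np.ndarray,
                   cfg: CMAConfig) -> float:
    """Refit thresholds (grid coordinate ascent) and weights (proportional to
    each motif's marginal separation) for a fixed motif set, then score.

    The same procedure is applied to observed and permuted labels, so the
    permutation p-value is exchangeable under the null.
    """
    thetas = {m: cfg.theta_grid[len(cfg.theta_grid) // 2] for m in motif_ids}
    weights = {m: 1.0 / len(motif_ids) for m in motif_ids}

    def module_with(th: dict, wt: dict) -> CompositeModule:
        return CompositeModule([ModuleMotif(m, th[m], wt[m])
                                for m in motif_ids], W)

    def score(th: dict, wt: dict) -> float:
        mod = module_with(th, wt)
        s = index.module_scores(mod)
        return fitness(mod, s[yes_mask], s[no_mask], lam=cfg.lam,
                       stat=cfg.fitness_stat)

    for _ in range(2):
        for m in motif_ids:
            best_t, best_f = thetas[m], -np.inf
            for t in cfg.theta_grid:
                thetas[m] = t
                f = score(thetas, weights)
                if f > best_f + 1e-12:
                    best_t, best_f = t, f
            thetas[m] = best_t
    # marginal separation per motif at the fitted thresholds
    for m in motif_ids:
        m_idx = index.motif_pos[m]
        contrib = np.maximum(0.0, index.windowed(m_idx, W) - thetas[m]
                             ).max(axis=-1)
        sep = contrib[yes_mask].mean() - contrib[no_mask].mean()
        weights[m] = max(sep, 0.05)
    total = sum(weights.values())
    weights = {m: w / total for m, w in weights.items()}
    return score(thetas, weights)


def permutation_significance(module: CompositeModule,
                             hits: pd.DataFrame,
                             promoters: Sequence[PromoterRecord],
                             yes_genes: Sequence[str],
                             no_genes: Sequence[str],
                             n_perm: int = 199,
                             seed: int = 0,
                             config: CMAConfig | None = None) -> float:
    """Label-permutation p-value for a fitted module's composition.

    p = (1 + #{permuted fitness >= observed}) / (n_perm + 1); the module's
    motif set and window are fixed while thresholds/weights are refit for the
    observed and for every permuted labeling.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    cfg = config or CMAConfig()
    yes_set, no_set = set(yes_genes), set(no_genes)
    keep = [p for p in promoters if p.gene_id in yes_set | no_set]
    index = PromoterHitIndex(hits, keep, module.motif_ids)
    labels = np.array([g in yes_set for g in index.genes])
    n_yes = int(labels.sum())

    observed = _refit_fitness(index, module.motif_ids, module.window_W,
                              labels, ~labels, cfg)
    rng = np.random.default_rng(seed)
    n_ge = 0
    n = len(index.genes)
    for _ in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_yes, replace=False)] = True
        f = _refit_fitness(index, module.motif_ids, module.window_W,
                           perm, ~perm, cfg)
        if f >= observed - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (n_perm + 1)


def regulatory_scores(modules: Sequence[CompositeModule],
                      hits: pd.DataFrame,
                      promoters: Sequence[PromoterRecord]
                      ) -> list[RegulatoryScore]:
    """Per gene, the best (max over modules) module score of its promoter."""
    motif_ids = sorted({m for mod in modules for m in mod.motif_ids})
    index = PromoterHitIndex(hits, promoters, motif_ids)
    best = np.zeros(len(index.genes))
    for mod in modules:
        best = np.maximum(best, index.module_scores(mod))
    return [RegulatoryScore(g, float(s)) for g, s in zip(index.genes, best)]
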