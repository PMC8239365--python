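import itertools

import numpy as np
import pandas as pd
import pytest

from upstreamkit.composite_module import (CMAConfig, CompositeModule,
                                          ModuleMotif, PromoterHitIndex,
                                          fitness, module_score,
                                          permutation_significance,
                                          regulatory_scores, run_cma, welch_t)
from upstreamkit.formats_io import PromoterRecord


def prom(gene, length=600):
    return PromoterRecord(gene, "A" * length, -length + 50, 50)


def hit_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "motif", "tf", "start",
                                       "strand", "mss", "css"])


def hit(gene, motif, start, mss):
    return (gene, motif, "tf_" + motif, start, "+", mss, mss)


def random_instance(rng, n_genes=6, n_motifs=3, length=600):
    proms = [prom(f"g{i}", length) for i in range(n_genes)]
    rows = []
    for p in proms:
        for m in range(n_motifs):
            for _ in range(int(rng.integers(0, 6))):
                start = int(rng.integers(p.window_start, p.window_end - 12))
                rows.append(hit(p.gene_id, f"M{m}", start,
                                float(rng.uniform(0.7, 1.0))))
    return proms, hit_frame(rows)


# --- module score ----------------------------------------------------------

def test_score_zero_without_hits():
    mod = CompositeModule([ModuleMotif("M0", 0.8, 0.5),
                           ModuleMotif("M1", 0.8, 0.5)], 300)
    assert module_score(hit_frame([]), mod, prom("g")) == 0.0


def test_score_single_motif_arithmetic():
    mod = CompositeModule([ModuleMotif("M0", 0.8, 1.0),
                           ModuleMotif("M1", 0.99, 1e-9)], 300)
    hits = hit_frame([hit("g", "M0", -100, 0.9)])
    # one hit at theta + 0.1 with (normalized) weight ~1 scores ~0.1
    assert module_score(hits, mod, prom("g")) == pytest.approx(0.1, abs=1e-6)


def test_vectorized_index_matches_bruteforce_enumeration():
    rng = np.random.default_rng(17)
    for _ in range(8):
        proms, hits = random_instance(rng)
        k = int(rng.integers(2, 4))
        mod = CompositeModule(
            [ModuleMotif(f"M{m}", float(rng.choice([0.7, 0.8, 0.9])),
                         float(rng.uniform(0.2, 1.0))) for m in range(k)],
            int(rng.choice([100, 250, 400])))
        index = PromoterHitIndex(hits, proms, [f"M{m}" for m in range(3)])
        vec = index.module_scores(mod)
        for p, got in zip(proms, vec):
            ref = module_score(hits[hits["gene"] == p.gene_id], mod, p)
            assert got == pytest.approx(ref, abs=1e-9)


def test_widening_window_never_decreases_score():
    rows = [hit("g", "M0", -500, 0.95), hit("g", "M1", 60, 0.95)]
    p = PromoterRecord("g", "A" * 700, -600, 100)
    narrow = CompositeModule([ModuleMotif("M0", 0.8, 0.5),
                              ModuleMotif("M1", 0.8, 0.5)], 300)
    wide = CompositeModule(narrow.motifs, 700)
    s_narrow = module_score(hit_frame(rows), narrow, p)
    s_wide = module_score(hit_frame(rows), wide, p)
    # 560 bp apart: narrow window sees one motif, wide window both
    assert s_narrow == pytest.approx(0.5 * 0.15, abs=1e-9)
    assert s_wide == pytest.approx(2 * 0.5 * 0.15, abs=1e-9)
    assert s_wide >= s_narrow


# --- fitness ---------------------------------------------------------------

def test_fitness_identical_distributions_is_minus_penalty():
    mod = CompositeModule([ModuleMotif("a", 0.8, 0.5),
                           ModuleMotif("b", 0.8, 0.5)], 300)
    scores = np.array([0.3, 0.4, 0.5, 0.6])
    assert fitness(mod, scores, scores.copy(), lam=0.1) == \
        pytest.approx(-0.1 * 2, abs=1e-9)


def test_fitness_perfect_separation_closed_form():
    mod = CompositeModule([ModuleMotif("a", 0.8, 0.5),
                           ModuleMotif("b", 0.8, 0.5)], 300)
    yes, no = np.ones(20), np.zeros(20)
    expected_t = 1.0 / np.sqrt(1e-12 / 20 + 1e-12 / 20)
    assert fitness(mod, yes, no, lam=0.1) == \
        pytest.approx(expected_t - 0.2, rel=1e-12)


def test_welch_t_matches_scipy_on_nondegenerate_data(rng):
    from scipy import stats

    a, b = rng.normal(1, 1, 30), rng.normal(0, 2, 25)
    assert welch_t(a, b) == pytest.approx(
        stats.ttest_ind(a, b, equal_var=False).statistic, rel=1e-9)


def test_irrelevant_motif_does_not_help_on_average():
    rng = np.random.default_rng(5)
    deltas = []
    for _ in range(20):
        proms = [prom(f"g{i}") for i in range(20)]
        yes = [p.gene_id for p in proms[:10]]
        no = [p.gene_id for p in proms[10:]]
        rows = [hit(g, "M0", -200, float(rng.uniform(0.92, 1.0)))
                for g in yes]
        rows += [hit(g, "M1", int(rng.integers(-500, 0)),
                     float(rng.uniform(0.7, 1.0)))
                 for g in (yes + no) for _ in range(rng.integers(0, 2))]
        index = PromoterHitIndex(hit_frame(rows), proms, ["M0", "M1"])
        ymask = np.array([g in set(yes) for g in index.genes])
        # same size k=2 (equal penalty); in `good` the irrelevant motif is
        # neutralized by a near-zero weight, in `plus` it contributes
        good = CompositeModule([ModuleMotif("M0", 0.9, 1.0),
                                ModuleMotif("M1", 0.7, 1e-9)], 300)
        plus = CompositeModule([ModuleMotif("M0", 0.9, 1.0),
                                ModuleMotif("M1", 0.7, 0.5)], 300)
        s_good = index.module_scores(good)
        s_plus = index.module_scores(plus)
        deltas.append(
            fitness(plus, s_plus[ymask], s_plus[~ymask])
            - fitness(good, s_good[ymask], s_good[~ymask]))
    assert np.mean(deltas) <= 0


# --- genetic algorithm -----------------------------------------------------

def exhaustive_two_motif_optimum(index, ymask, cfg):
    """Brute force over motif-pair threshold grid with uniform weights."""
    best = -np.inf
    for t0, t1 in itertools.product(cfg.theta_grid, repeat=2):
        mod = CompositeModule([ModuleMotif("M0", t0, 0.5),
                               ModuleMotif("M1", t1, 0.5)], cfg.w_init)
        s = index.module_scores(mod)
        best = max(best, fitness(mod, s[ymask], s[~ymask], lam=cfg.lam))
    return best


def test_ga_reaches_exhaustive_optimum_on_tiny_instances():
    ok = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        proms = [prom(f"g{i}") for i in range(16)]
        yes = [p.gene_id for p in proms[:8]]
        no = [p.gene_id for p in proms[8:]]
        rows = []
        for g in yes:
            rows.append(hit(g, "M0", -300, float(rng.uniform(0.85, 1.0))))
            rows.append(hit(g, "M1", -250, float(rng.uniform(0.85, 1.0))))
        for g in no:
            if rng.random() < 0.4:
                rows.append(hit(g, "M0", -300, float(rng.uniform(0.7, 0.9))))
        hits = hit_frame(rows)
        cfg = CMAConfig(k_max=2, n_modules=1, pop=40, gens=25, seed=seed)
        modules, _, _ = run_cma(hits, proms, yes, no, ["M0", "M1"], cfg)
        index = PromoterHitIndex(hits, proms, ["M0", "M1"])
        ymask = np.array([g in set(yes) for g in index.genes])
        opt = exhaustive_two_motif_optimum(index, ymask, cfg)
        assert opt > 0
        if modules[0].fitness >= 0.99 * opt:
            ok += 1
    assert ok >= 9


def test_ga_deterministic_under_seed(small_bundle):
    from upstreamkit.motif_scan import scan_all

    b = small_bundle
    proms = b.promoters
    yes = b.manifest.promoter_yes_genes
    no = b.manifest.promoter_no_genes
    hits = scan_all(proms, b.motifs)
    pool = [m.motif_id for m in b.motifs]
    cfg = CMAConfig(pop=30, gens=10, seed=42)
    m1, s1, h1 = run_cma(hits, proms, yes, no, pool, cfg)
    m2, s2, h2 = run_cma(hits, proms, yes, no, pool, cfg)
    assert [m.to_dict() for m in m1] == [m.to_dict() for m in m2]
    pd.testing.assert_frame_equal(s1, s2)
    assert h1 == h2


def test_ga_best_fitness_monotone_under_elitism(small_bundle):
    from upstreamkit.motif_scan import scan_all

    b = small_bundle
    hits = scan_all(b.promoters, b.motifs)
    cfg = CMAConfig(pop=25, gens=15, seed=3)
    _, _, histories = run_cma(hits, b.promoters,
                              b.manifest.promoter_yes_genes,
                              b.manifest.promoter_no_genes,
                              [m.motif_id for m in b.motifs], cfg)
    for hist in histories:
        assert all(a <= b_ + 1e-12 for a, b_ in zip(hist, hist[1:]))


def test_ga_needs_at_least_two_motifs():
    with pytest.raises(ValueError, match="at least 2"):
        run_cma(hit_frame([]), [prom("g")], ["g"], ["g2"], ["M0"],
                CMAConfig())


def test_modules_are_motif_disjoint():
    rng = np.random.default_rng(2)
    proms, hits = random_instance(rng, n_genes=16, n_motifs=6)
    yes = [p.gene_id for p in proms[:8]]
    no = [p.gene_id for p in proms[8:]]
    # disable the secondary-module quality gate: this checks disjointness
    cfg = CMAConfig(k_max=3, n_modules=2, pop=25, gens=8, seed=1,
                    min_fitness=-np.inf)
    modules, _, _ = run_cma(hits, proms, yes, no,
                            [f"M{i}" for i in range(6)], cfg)
    assert len(modules) == 2
    assert not (set(modules[0].motif_ids) & set(modules[1].motif_ids))


# --- permutation significance ----------------------------------------------

def test_perfect_module_attains_minimal_permutation_p():
    proms = [prom(f"g{i}", 400) for i in range(20)]
    yes = [p.gene_id for p in proms[:10]]
    no = [p.gene_id for p in proms[10:]]
    rows = []
    for g in yes:
        rows.append(hit(g, "M0", -200, 1.0))
        rows.append(hit(g, "M1", -180, 1.0))
    mod = CompositeModule([ModuleMotif("M0", 0.9, 0.5),
                           ModuleMotif("M1", 0.9, 0.5)], 300)
    p = permutation_significance(mod, hit_frame(rows), proms, yes, no,
                                 n_perm=199, seed=0)
    assert p == pytest.approx(1 / 200)


def test_permutation_requires_enough_permutations():
    mod = CompositeModule([ModuleMotif("M0", 0.9, 0.5),
                           ModuleMotif("M1", 0.9, 0.5)], 300)
    with pytest.raises(ValueError, match="19"):
        permutation_significance(mod, hit_frame([]), [prom("a"), prom("b")],
                                 ["a"], ["b"], n_perm=5, seed=0)


# --- regulatory scores -----------------------------------------------------

def test_regulatory_scores_take_best_module():
    proms = [prom("g1"), prom("g2")]
    rows = [hit("g1", "M0", -100, 0.95), hit("g2", "M1", -100, 0.95)]
    m1 = CompositeModule([ModuleMotif("M0", 0.9, 0.5),
                          ModuleMotif("MX", 0.9, 0.5)], 300)
    m2 = CompositeModule([ModuleMotif("M1", 0.8, 0.5),
                          ModuleMotif("MY", 0.9, 0.5)], 300)
    out = {r.gene_id: r.score for r in
           regulatory_scores([m1, m2], hit_frame(rows), proms)}
    assert out["g1"] == pytest.approx(0.5 * 0.05, abs=1e-9)
    assert out["g2"] == pytest.approx(0.5 * 0.15, abs=1e-9)
    # zero iff no module motif passes its threshold
    rows0 = [hit("g1", "M0", -100, 0.85)]
    out0 = {r.gene_id: r.score for r in
            regulatory_scores([m1], hit_frame(rows0), proms)}
    assert out0["g1"] == 0.0 and out0["g2"] == 0.0
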