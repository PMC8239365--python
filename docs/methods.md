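# Methods

This note documents the statistical models, scoring conventions, parameter
defaults and design choices behind `upstreamkit`, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and formats

Promoter coordinates are TSS-relative, 0-based, half-open `[start, end)`;
the TSS (first transcribed base) is position 0, negative is upstream.  The
default window is `[-1000, +100)` (length 1100); both the window and every
threshold below are config-exposed, not hard-coded.  FASTA headers carry
`gene_id window_start window_end`; plain FASTA defaults to a window ending
at the TSS.  Motif libraries parse in the TRANSFAC and JASPAR dialects
(via Biopython); `N` bases are allowed in sequences and no reported site
may overlap one.

## Moderated differential expression

For gene *g* with group sizes *n₁* (yes) and *n₂* (no), `log2FC` is the
yes-mean minus the no-mean (so positive values are up in the case group —
stated in every output header).  The pooled within-group variance `s²g`
(dg = n₁+n₂−2 df) is shrunk toward a prior:

    s̃²g = (d₀·s₀² + dg·s²g) / (d₀ + dg)

with `(d₀, s₀²)` estimated by method of moments on `log s²g` using the
standard chi-square log-moment identities; `d₀` comes from inverting the
trigamma function on the excess variance of the log variances (Newton
iteration).  When the moment equation has no root — the observed spread of
log-variances does not exceed chi-square sampling noise, as happens for
homoskedastic simulated data — a fixed fallback `d₀ = 4` is used, keeping
the degrees of freedom finite and the test honest.  The moderated t has
`d₀+dg` df; `d₀ → ∞` recovers the common-variance t and `d₀ = 0` the
per-gene t (both verified numerically in the tests).  P-values are
two-sided and BH-adjusted (statsmodels).  Zero-variance genes are handled
by shrinkage; no division by zero can occur.

DEG selection defaults to adjusted p < 0.05 and |log2FC| > 0.5.  The
promoter *no set* is an expression-matched background: non-significant
genes with |log2FC| < 0.1, capped at 10× the yes set by seeded
subsampling.  The cap keeps scanning bounded; the |log2FC| criterion makes
the background conservative (genes confidently unchanged).

## MATCH-style scanning

Frequencies are regularized by spreading a total pseudocount mass
ε = 0.001 across the four bases of each position and renormalizing.  The
information vector is I(i) = Σ_b f(i,b)·ln(4f(i,b)) ∈ [0, ln 4]; the core
is the 5 consecutive positions with maximal summed information (leftmost
on ties).  For a window s:

    MSS = (Current − Min) / (Max − Min),  Current = Σᵢ I(i)·f(i, sᵢ)

with Min/Max substituting the per-position min/max frequency; CSS is the
same restricted to the core.  MSS is exactly 1 on the consensus and 0 on
the anti-consensus, and is invariant to rescaling all counts.  The minus
strand is scored by scanning the reverse-complemented sequence with the
forward matrix, which makes strand symmetry bit-exact; reverse hits are
reported at their forward-strand 5′ coordinate.  Overlapping hits are
deliberately retained by the scanner (downstream stages decide).

**Cutoffs.**  The global defaults are mss ≥ 0.75 and css ≥ 0.70.  A single
global MSS cutoff, however, makes occurrence counts incomparable across
matrices: at ~1.2 bits/position an 8-mer emits an order of magnitude more
chance hits per kilobase than a 14-mer.  The pipeline therefore calibrates
a per-motif cutoff — the (1 − r) quantile of the motif's MSS distribution
on seeded GC-matched random background, with target rate r = 10⁻³ per
scanned position-strand (the classic "about one chance site per kilobase"
futility rate) — floored at the 0.75 default so calibration only ever
tightens.  Fixed-cutoff scanning remains available
(`calibrate_cutoffs: false`).

## Motif enrichment

Occurrence counts are first deduplicated: overlapping same-gene, same-motif
hits collapse to the strongest one, since they represent one physical site
and counting them separately would violate the independence the binomial
null assumes.  For motif *m* with occ_yes/occ_no deduplicated occurrences,
the ratio is Haldane–Anscombe-corrected occurrences per promoter:

    ratio = ((occ_yes + ½)/n_yes) / ((occ_no + ½)/n_no)

Significance conditions on n = occ_yes + occ_no: under the
length-proportional null each occurrence falls in the yes set with
probability p₀ = L_yes/(L_yes + L_no), where L counts N-free scannable
offsets on both strands, and

    p_binom = P[Binomial(n, p₀) ≥ occ_yes]

is computed by exact log-space tail summation (cross-checked against the
regularized incomplete beta to 1e-10).  A per-promoter presence/absence
null is available as an alternative (`null_model: presence`).  P-values
are BH-adjusted across the library.  Candidate TFs pass adjusted p < 0.05
and ratio > 1; for GA seeding the pipeline pads this list with the next
best-ranked motifs up to `pool_min` (default 5) — the significance filter
is advisory for seeding, since the GA applies its own selection pressure
and a pool below two motifs is a hard failure mode on marginal data.

## Composite modules

A module is k motifs (2 ≤ k ≤ 6), each with threshold θ ∈ grid
{0.70, 0.75, …, 0.95} and positive weight (normalized to sum 1), plus a
window width W ∈ {100, …, 600} bp (default start 300).  A promoter's score
is the best window placement:

    score = max over [s, s+W) of Σ_m w_m · max(0, best MSS of m in window − θ_m)

where a hit belongs to a window if its 5′ end lies inside.  The objective
("fitness") is the Welch t of yes vs no scores minus λ·k (λ = 0.1);
variances are floored at 1e-12 for degenerate inputs, and a Mann–Whitney
z alternative is pluggable.  The GA uses tournament selection (size 3),
uniform crossover on motif slots, mutation (motif swap / θ ± 0.05 /
weight ×U(0.8, 1.25) / W ± 50), elitism, population 200 and 100
generations by default; it is bit-reproducible under its seed, and the
best fitness is non-decreasing across generations.  Up to `n_modules`
(default 2) motif-disjoint modules are fitted sequentially; modules beyond
the best are kept only if their fitness clears 3.0 on the t scale — with a
padded pool the disjointness constraint would otherwise force a module
onto leftover noise motifs (observed fitness 0.5–2 vs 13–21 for a real
planted module), and t ≥ 3 is a conservative strong-evidence cut given GA
selection bias.

Module evaluation is vectorized: per-position best-MSS arrays per
(gene, motif) with cached left-aligned sliding-window maxima, verified
exactly against explicit window enumeration.

**Significance** is by label permutation (default 199 permutations):
module composition and window fixed, thresholds re-optimized by grid
coordinate ascent and weights refit (proportional to each motif's marginal
yes-vs-no separation, floored and normalized) for the observed and every
permuted labeling alike, so p = (1 + #{perm ≥ obs})/(n_perm + 1) is
exchangeable — and empirically uniform — under the null.  The per-gene
**regulatory score** is the max over fitted modules of the module score;
it is 0 iff no module motif passes its threshold anywhere.

## Master regulators

Candidates are network nodes from which ≥ m_min (default 2) module TFs are
reachable within r (default 4) directed SIGNALING steps (BFS on the
reversed graph; distances verified against independent all-pairs shortest
paths).  The default network score is distance-discounted coverage,

    mr_score(c) = Σ_{t reached} (r − d(c,t) + 1)/r · 1/|TF_module| ∈ (0, 1],

(closed forms: 1.0 for a hub one step from every TF; 0.5 for a chain
reaching one TF at d = r = 2); a pure-coverage alternative is provided.
A positive feedback loop is recorded when a reached TF t also transcribes
the gene encoding candidate c — evidence either a TRANSCRIPTION edge
t → gene(c) or a module-threshold-passing site for t's motif in that
gene's promoter (both kinds labeled).  A loop is labeled positive iff the
product of signaling-edge signs along the shortest path is +1;
negative-product loops are reported but flagged.  Final ranking averages
three descending component ranks — log2FC of the encoding gene, its
regulatory score, and mr_score (ties share average ranks; final ties break
by node id) — and the output table reports both the network-reachable TF
count and the promoter-site-supported TF count, since either reading of
"TFs regulated" is defensible.

## Synthetic studies and what they show

Generator defaults define the benchmark conditions: 2000 genes × (20 yes +
20 no) samples, baseline N(7, 1), noise σ = 0.5, 150 up / 100 down planted
genes with effects U(0.6, 1.5); a 20-motif library (lengths 8–14,
tempered-Dirichlet PFMs at 1.2 ± 0.2 bits/position); 50 yes + 200 no
promoters of 1100 bp at GC 0.5, with a 3-motif module implanted with
probability π = 0.9 inside a random 300 bp window (high-affinity draws,
MSS ≥ 0.9, random strand, non-overlapping) and Poisson(1) decoy sites from
non-module motifs in the no set; a 300-node signaling network whose
planted regulator reaches the module TFs at distances cycling 1,2,3, with
distractor hubs reaching at most ⌈k/2⌉ TFs and background edges kept out
of the planted wiring so reachability is guaranteed by construction.
Cross-links encode the feedback premise: module target genes are the
largest-effect planted UP genes, the regulator's gene the largest of all,
and every module TF carries a transcription edge to the regulator.
Artifacts draw from independent child seed streams, so changing one
artifact's parameters leaves the others bit-identical.

The generator emulates the *statistical* structure of a two-group
microarray study — it does not model probe effects, batch structure,
correlated genes, CpG composition, or motif co-occurrence biology.
Passing the planted-truth suite therefore demonstrates that the chain of
inferences is correct and well-calibrated at realistic effect sizes, not
that any particular biological cohort would yield the same regulators.

## Scales used by tests and the acceptance script

Null calibration uses 2000 genes × 20 seeds; permutation-uniformity 200
(tests) / 100 (script) repetitions of a 14-promoter null at 99
permutations; planted-truth recovery runs the full generator defaults over
20 seeds (tests) / 10 seeds (script) with a GA budget of population 60 ×
40 generations — the planted signal is strong and this desk-scale budget
recovers it; the pop 200 × gens 100 defaults remain for real data.  DEG
recall is measured at fixed effect 1.0 (at effect 0.6 the log2FC > 0.5
selection itself removes genes, so recall against U(0.6, 1.5) effects
conflates estimation with the explicit fold-change filter).  The
determinism check reruns the file-based pipeline twice on an 800-gene
study and compares all outputs byte-for-byte.

## Known limitations

* The moderated-test fallback `d₀ = 4` is ad hoc (though conservative);
  limma-style robust estimation of the prior is not implemented.
* The GA objective treats promoters as exchangeable; no positional,
  orientation or spacing constraints between sites.
* Signaling-edge signs label loops but do not enter candidate scoring.
* Multi-factor and paired designs, count-based (RNA-seq) models, and
  genome-wide (non-promoter) scanning are out of scope.
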