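# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `cneaccel`. It describes what the code does and why the
open design questions were settled the way they were; every empirical claim
here is one the test suite or `scripts/acceptance.py` computes.

## Substitution model and likelihoods

All likelihood computation uses a single HKY85 model: stationary base
frequencies π over {A,C,G,T} and a transition/transversion ratio κ. The rate
matrix is normalised to one expected substitution per site at stationarity,
so branch lengths are in substitutions/site and branch *scales* are
dimensionless rate multipliers. HKY was chosen as the minimal model that
distinguishes transitions from transversions; the neutral model behind the
original phastCons/phyloP-style analyses is not uniquely determined by their
published descriptions, so the model is isolated behind one class
(`HKYModel`) and can be supplied from a config dict or fitted from
presumed-neutral columns (`fit_neutral_model`: empirical frequencies with a
+1 pseudocount, κ by grid search plus bounded refinement).

Transition probabilities come from the spectral decomposition of the
similarity-transformed symmetric rate matrix — exact for any reversible
model, no Padé approximation, no hand-derived closed form to maintain.

Column likelihoods use Felsenstein pruning, vectorised across columns.
Conventions:

- `N` and gap are missing data: partial vector of ones, marginalised.
- Columns missing in *every* species are pinned to log-probability exactly 0
  (probability 1), avoiding −∞ and spurious float residue.
- Partial vectors are rescaled per internal node by their column maximum and
  the log-scalers accumulated, so long elements never underflow; the
  reported log value is exact up to float rounding (checked to 1e−10 against
  exhaustive internal-state enumeration on trees with ≤ 5 leaves).

## Conserved-segment HMM

Two states, conserved (all branches × ρ) and nonconserved (scale 1).
Parameters and defaults:

| parameter | meaning | default | why |
|---|---|---|---|
| ω | expected conserved-segment length (columns) | 12 | the phastCons setting used for nematode CNE detection |
| γ | target coverage | 0.3 | same source |
| ρ | conserved branch scale | 0.3 | typical conserved-element rate reduction; recoverable from data (`estimate_rho`) |

μ = 1/ω and ν = μγ/(1−γ) make the stationary conserved probability exactly
γ; the initial state distribution is that stationary pair, consistent with
the coverage interpretation. Segment calling uses the Viterbi path rather
than posterior thresholding: deterministic output, and ties in backtracking
are resolved toward the nonconserved state so marginal columns never extend
an element. Posterior probabilities from forward–backward are retained as a
diagnostic (they must sum to 1 per column to 1e−12). ρ is estimated once per
dataset by maximising the total forward likelihood over a geometric grid in
(0,1] refined by bounded scalar minimisation — per-chromosome estimation
offers no benefit at the scales involved and would add nondeterminism in
block ordering.

## Catalog filters

All interval arithmetic is 0-based half-open; GFF3 input is converted on
read. The filter semantics are pinned by tests:

- "longer than 10 bp" is strict: length 10 is dropped, 11 kept.
- "more than twice as long" is strict: a projection of exactly 2× survives.
- "aligned redundantly" means the species projection comprises ≥ 2 disjoint
  genomic intervals after merging per-block projections.
- Nearest-gene assignment uses gene bodies (not TSSs — no strand rule is
  implied by a "closest neighbor" definition), ignores strand, and breaks
  distance ties by leftmost gene start then lexicographic id. Signed
  distances are 0 on overlap, positive when the gene starts downstream of
  the element.
- The enrichment universe is all kept CNEs of the focal species; the
  contrast is accelerated vs all other kept elements.

Only + strand alignment rows are supported; the generator emits forward
strand alignments, and reverse-strand MAF handling is out of scope.

## Acceleration LRT

Null: one free global scale r ∈ [10⁻³, 10] shared by all branches (this
absorbs element-wide rate variation, so conserved-but-slow elements are not
mistaken for accelerated ones). Alternative: additionally one shared λ ≥ 1
multiplying every target branch — the three hermaphrodite terminal branches
jointly, or one terminal branch in per-species mode (the sexual-system
transitions are terminal-lineage events, so "the branch of species X" is its
terminal edge). A joint run with a single target is algebraically the
single-branch test and the code paths coincide exactly.

Optimisation is a coarse geometric grid followed by bounded golden-section
refinement, alternating between r and λ for three rounds; there is no
randomness, and the alternative is initialised at the null optimum so
lnL₁ ≥ lnL₀ by construction. Since λ is tested on its boundary, the
statistic 2(lnL₁−lnL₀) is referred to ½χ²₀ + ½χ²₁: p = ½·P(χ²₁ ≥ stat) when
λ̂ > 1, else 1. BH correction is applied within each run (the joint run, and
each species' run separately), mirroring how the per-run FDR statements are
made. Measured on ≥ 1000 simulated null elements (λ = 1, 30–100 columns)
the empirical P(p < 0.05) sits within 3 binomial standard errors of 0.05.

## Nucleotide diversity

Per segregating site the unbiased estimator 2p(1−p)·n/(n−1), p the
alternate-allele frequency among the n ≥ 2 non-missing haplotypes; this is
algebraically the mean pairwise difference, asserted numerically against an
all-pairs oracle. The denominator is the full element length by default;
where callable length is known it can be supplied per element (the choice
between the two is not determined by the source workflows, and full length
is the simpler, reproducible reading). Multiallelic and non-SNP records are
dropped with a logged count. Class summaries use only elements strictly
longer than 50 bp and flag classes with ≤ 10 elements.

## Differential expression stand-in

The original workflow calls sex-biased genes with TCC/edgeR; that exact
stack is deliberately not reproduced. The caller here is a self-contained
negative-binomial procedure chosen to be *calibratable*:

1. median-of-ratios size factors (geometric-mean reference over genes
   nonzero in all samples; upper-quartile fallback, logged);
2. per-gene method-of-moments dispersion from pooled within-group variance,
   **moderated** toward the across-gene 10–90% trimmed mean with prior
   weight equivalent to 20 degrees of freedom, then floored at 0.01 and
   capped at 10. With 4 replicates the raw per-gene estimate is noisy enough
   to make the exact test anticonservative (measured ~0.09 at nominal 0.05);
   the trimmed mean is used for pooling because the median of a ~χ²₆-scaled
   estimate is biased low and a plain mean is outlier-sensitive. With
   moderation the null rate measures ~0.045–0.06 across dispersions
   0.01–0.5;
3. an exact-style conditional test on group total pseudo-counts: totals of k
   replicates are NB(k·μ̂₀, α/k); conditioning on the grand total, the
   p-value sums the probabilities of splits no more probable than observed
   (a likelihood-ratio χ² fallback handles totals beyond 2·10⁵).

Externally computed DE labels can be passed straight into
`classify_sex_bias`/`transition_association`, bypassing the stand-in.

Classes are XX-biased / XO-biased / Non at q < 0.01 with direction from the
fold change. The 3×3 ortholog transition table tests each cell with a 2×2
Fisher exact test (two-sided by default; a one-sided switch exists since the
original per-cell sidedness is not stated), odds ratios use the
Haldane–Anscombe +0.5 correction on zero margins (p-values remain
uncorrected), and BH runs across the nine cells. The 2×3 association of
neighbor status with class uses an exact multivariate-hypergeometric
enumeration up to 2000 observations and the χ² test of independence above
that.

## Synthetic data

The generator is the package's definition of its study conditions, not a
tuning surface:

- **Tree**: a packaged 11-taxon topology mimicking the *Caenorhabditis*
  phylogeny with the three hermaphrodite terminals marked and *C. niphades*
  as the outgroup/reference. Branch lengths are round numbers (terminals
  0.18–0.2, outgroup 0.35, total ≈ 2.9 substitutions/site) in the realistic
  deep-divergence range for the genus and chosen for test power rather than
  copied from any published estimate.
- **Alignment**: root sequence from the stationary frequencies, evolved
  down the tree with the same HKY transition matrices the inference uses —
  simulation/inference self-consistency is itself a test. Planted conserved
  stretches scale all branches by ρ = 0.3; planted accelerated stretches
  additionally scale target branches by λ = 5. Elements (default 40 per
  20 kb, lengths 30–120 bp) and CDS intervals are laid out without overlap;
  alignments are gap-free (no indel evolution).
- **Population**: site-independent segregating variants — a site segregates
  with probability θ·a_n (Watterson's harmonic factor, n = 48 haplotypes),
  derived-allele count from the neutral 1/k spectrum, so expected per-site
  π equals the local θ (0.004 outside elements, reduced 5× inside). No
  linkage or coalescent genealogy: π contrasts and densities are the only
  signals consumed downstream, and that independence is a documented
  limitation — the synthetic data cannot exercise LD-aware methods.
- **Expression**: gene means from a Gamma(2, 50) (≈100 counts), NB
  dispersion 0.1, 4 replicates per sex/stage, 10% XX-biased and 10%
  XO-biased genes at fold 4 per species (one class per species, applied to
  both stages), and neighbor flags at base rate 0.1 boosted to odds ratio 3
  in the configured transition cell(s).

Everything is driven by one `numpy` generator seeded from the config; the
same seed yields byte-identical outputs.

What passing tests on these data do **not** show: robustness to alignment
error, indels, GC-biased gene conversion, rate variation across sites within
a state, linked selection, or expression-count artefacts (batch effects,
length biases) — none of which the generator emulates.

## The deterministic fixture

`cneaccel.fixture.make_fixture()` builds a hand-sized constructed dataset
(2 kb reference, 8 planted stretches, 4 genes, 8 haplotypes, 24 expression
samples) in which every planted stretch exercises one filter rule and every
downstream number is pencil-and-paper checkable; the flanking columns of
each stretch are set to a fixed maximally divergent pattern so segment
boundaries are exact by construction. The frozen expected outputs and the
hand arithmetic live in `tests/data/fixture/`.

## Known limitations

- One shared λ across target branches in joint mode (a per-branch-λ variant
  is a config switch away conceptually but not implemented); conservation
  (deceleration) calling is out of scope.
- No reverse-strand MAF support; no per-chromosome ρ.
- The DE stand-in approximates, but is not, TCC/edgeR; absolute DEG counts
  from it are not comparable to published ones, only its calibration and
  the downstream contingency structure are.
- Brute-force oracles bound the exactness guarantees: pruning to 5 leaves,
  HMM paths to 12 columns, exact Fisher to N ≤ 60.
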