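# Methods

This note records the statistical models, default parameters, numerical
choices, and known calibration properties of `phyloexpr`. Units: branch
lengths and tree depth T in Myr (the bundled primate tree has T = 74);
expression in log2-CPM; α in 1/Myr; σ² in (log2-CPM)²/Myr.

## 1. Evolutionary models

Each gene's species-mean expression **x** (one value per tip) is modeled as a
multivariate normal over the tips of a rooted time tree.

**Brownian motion (BM).** Mean x₀·**1**; covariance V_ij = σ²·t_a(i,j), with
t_a the time from the root to the most recent common ancestor of tips i, j.
Two free parameters (x₀, σ²).

**Ornstein–Uhlenbeck (OU), root-conditioned.** dx = −α(x−θ)dt + σ dW with the
root state fixed at the root regime's optimum, x(0) = θ_root. Tip means are
the Hansen weights applied to the regime optima: a branch segment [t_b, t_e]
on tip i's root path contributes e^{−α(d_i−t_e)} − e^{−α(d_i−t_b)} to its
regime's weight and the root contributes e^{−α·d_i}; rows telescope to 1.
The covariance is

    V_ij = σ²/(2α) · e^{−α((d_i−t_a)+(d_j−t_a))} · (1 − e^{−2α·t_a}).

As α → 0 this converges to the BM covariance (implemented via `expm1`, so the
limit is numerically exact to ~1e-9), and the Hansen weights converge to the
root-regime indicator. **Root conditioning is what makes BM ⊂ OU1 ⊂
OU-regime an exactly nested ladder**; the common stationary-root variant
(available via `stationary_root=True`) does not nest BM and is not used in
the likelihood-ratio tests.

**OU1 vs OU-regime.** OU1 uses a single optimum (3 parameters: α, σ², θ).
OU-regime paints each branch with one of K regimes (2 + K parameters); a
"focal clade" painting assigns every branch whose descendant tips all lie in
the focal set to the focal regime, with the root in the background regime.

## 2. Maximum-likelihood fitting

Given α, the optima enter linearly, so they are profiled out by generalized
least squares (Cholesky solves; rank-deficient designs — e.g. a regime whose
weights vanish as α → 0 — fall back to least squares). With no within-species
variances, σ² concentrates analytically (σ̂² = q/n, floored at 1e-12; fits at
the floor are flagged `degenerate`). With within-species variances s²ᵢ/nᵢ on
the diagonal, σ² is optimized numerically over log σ².

α is maximized over a 41-point grid: a near-zero boundary point at 1e-9/T
(recovering BM to < 1e-5 in lnL) plus 40 log-spaced points on [1e-3/T,
1e2/T], followed by bounded Brent refinement in log α between the best grid
point's neighbors (xatol 1e-7). The grid bounds cover phylogenetic
half-lives from ~700·T down to T/144; α outside that range is statistically
indistinguishable from BM or from white noise at 18 tips. Likelihoods carry
all constants, so AIC = 2k − 2lnL and BIC = k·ln(n_tips) − 2lnL are
comparable across models. Covariance/weight structures are cached per α and
shared across genes fitted on the same tree.

Fitting 2000 genes under BM + OU1 on an 18-tip tree takes ≈ 30 s on one CPU.

## 3. Hypothesis tests and classification

**LRT.** Λ = 2(lnL_alt − lnL_null), p from χ²_df: df = 1 for OU1 vs BM, K for
OU-regime vs BM, K−1 for OU-regime vs OU1. The nested-fit contract is
enforced: Λ < −1e-6 raises an error (small negatives from optimizer
round-off are clamped to 0).

**Multiple testing.** Benjamini–Hochberg step-up q-values, implemented
directly (q_(i) = min_{j≥i} p_(j)·m/j).

**Stabilizing-vs-drift classification.** OU1-vs-BM at q < 0.05;
`aic_bic_pass` additionally requires the OU fit to win on both AIC and BIC.

**Calibration properties (measured on the bundled 18-tip tree).**
- OU1 vs BM: testing α on its boundary makes χ²₁ *conservative* — on 2000
  all-BM genes the stabilizing fraction at q < 0.05 is ~0 (well below 0.05).
- OU-regime vs BM: χ²_K is *anti-conservative* at this tip count — the null
  rejection rate at p < 0.05 is ≈ 12%, and the realized false-discovery
  proportion in mixed panels (50 planted shifts + 150 BM nulls, q < 0.05)
  averages ≈ 0.14–0.16 over 20 seeds, above the nominal 0.10. This was
  diagnosed as a finite-sample failure of the χ² reference itself, not of the
  optimizer: the BM likelihood is closed-form exact, nesting violations are
  zero, and both LRT components individually exceed their χ²₁ quantiles.
  Parametric-bootstrap calibration would fix it but is outside the declared
  χ²-based procedure; the corresponding acceptance test is left failing.

## 4. Outlier expression scoring

For genes preferred by OU1 (q < 0.05) whose back-transformed optimum is at
least 5 CPM, a focal species is scored as Z = (x_focal − θ̂)/√(σ̂²/(2α̂)),
with a two-sided normal p; the operative flag is |Z| > 2 and p < 0.05
(q-values are reported alongside). By default the focal species participates
in the fit. For measuring *planted* outlier magnitudes, the `leave_one_out`
flag refits the moments on the pruned tree: with the focal tip included, a
4-SD planted shift inflates σ̂² and drags θ̂ toward the outlier, attenuating
the measured mean |Z| to ≈ 2.9; leave-one-out recovers ≈ 4.2, matching the
planted effect. The null flag rate of the default (focal-included) workflow
is ≈ 0.05–0.07.

## 5. Normalization

TMM scaling factors follow the standard construction: M/A values on genes
positive in both libraries, double rank-trimming (30% on M, 5% on A, rank
rule floor(n·trim)+1 … n−floor(n·trim)), inverse-asymptotic-variance weights
w = (L_s−y_s)/(L_s y_s) + (L_r−y_r)/(L_r y_r), factor 2^(weighted mean M),
renormalized to unit geometric mean. The automatic reference library is the
one whose upper-quartile CPM is closest to the mean. Note that because the
weights depend on library depth, scaling a single library's counts by c
changes factors by O(1e-3) rather than exactly zero (uniform scaling of all
libraries is absorbed exactly); this is inherent to asymptotic-variance
weighting. log2-CPM uses a prior count of 0.5 on effective (TMM-scaled)
library sizes. Expression filtering requires count ≥ 1 and CPM > 1 in every
sample by default.

## 6. Distances, ordination, trees

- **Distance**: RMS log2 fold change over a fixed gene set (the 500 most
  variable by default).
- **PCoA**: classical (Torgerson) scaling; negative eigenvalues are counted
  and reported, never corrected; percent variance is over positive
  eigenvalues only.
- **Hull areas**: convex-hull area per group on an ordination plane, plus
  area relative to the largest group; degenerate groups get 0 with a warning.
- **NJ**: canonical Saitou–Nei with deterministic smallest-(row, col)
  tie-breaking; negative branch-length estimates are clamped to zero with the
  deficit moved to the sibling edge. Exact on additive matrices (topology and
  path lengths to 1e-9).
- **Bootstrap**: genes resampled with replacement; support of each full-data
  bipartition is the fraction of replicate trees containing it.

## 7. Trait correlation

ECV (ml) converts to brain mass at **1.036 g/ml**; the regression trait
defaults to log10 mass because mass spans > 2 orders of magnitude across
primates. PCA is run on the species-mean matrix restricted to the top-500
most variable genes, column-centered (unscaled by default — profiles share
log2-CPM units), with the sign convention that each loading vector's
largest-magnitude element is positive. Each PC is regressed on the trait by
OLS (adjusted R², AIC); the reported PC minimizes single-predictor AIC, and a
joint model's R² is reported alongside.

## 8. Synthetic-data generator

Species means are drawn exactly from the model-implied multivariate normal
(eigendecomposition square root), replicates add N(0, s²) noise, and counts
are Gamma–Poisson (negative binomial; dispersion 0 → Poisson) around
μ = 2^x·L/1e6. A truth table records every gene's generative spec and its
noiseless species means. Defaults: 50% OU genes, α = 0.03/Myr (αT ≈ 2.2),
σ² = 0.2, optima ~N(5, 2²), replicate SD 0.25, NB dispersion 0.05, library
size 2e7. Planted structures:

- **Regime shifts** (power studies): hominoid focal clade, αT = 3,
  stationary variance 0.25, Δθ = 2 — i.e. a 4-SD optimum shift. Recall of
  the regime-DE test under these conditions is ≥ 0.95; recall degrades for
  younger/smaller focal clades (Hansen weights scale like 1 − e^{−α·clade
  age}) and for larger stationary variances.
- **Outlier shifts**: +4 stationary SDs added to one species' means.
- **Trait modules**: per-species offsets slope·standardized(log10 mass) added
  to k randomly chosen genes; verification uses 25 of 500 genes at slope 2
  over a quiet stationary-OU background (αT = 3, stationary variance 0.25,
  replicate SD 0.1), where the selected PC captures ≥ 20 of the 25 planted
  genes in its top-50 loadings.

The bundled 18-species primate tree (5 hominoids, 4 cercopithecoids, 4
platyrrhines, 5 strepsirrhines; depth 74 Myr) uses literature-anchored
divergence times; phenogram-recovery checks are sensitive to the shortest
internal edges, so realistic calibrations matter.

## 9. Verification strategy

Every non-trivial computation is tested against an independent oracle:
explicit `scipy.stats.multivariate_normal` densities for all three model
likelihoods; Euler–Maruyama SDE path simulation for the OU covariance;
brute-force enumeration for MWU, rank trims, intersections, and hull areas
(gift wrapping); statsmodels `multipletests` for BH; scikit-bio for NJ and
PCoA cross-checks; and closed-form hand calculations for 2-tip likelihoods,
TMM on an 8-gene toy, and the 4-taxon NJ example. Planted-signal experiments
(`scripts/acceptance.py`) verify end-to-end recovery: FDR calibration on null
panels, OU parameter recovery (αT = 2, θ = 5, σ² = 1: median θ̂ within 5%,
α̂ within 2×, stationary variance within 30%), regime-DE recall, outlier
magnitudes, phenogram recovery (RF 0 in 20/20 noise-free seeds), and
trait-module enrichment (hypergeometric p < 1e-6).
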