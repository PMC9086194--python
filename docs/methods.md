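# Methods

## The selection problem

Immune-repertoire studies compare groups of subjects through the usage of
V/J gene-segment pairs: per sample, the fraction of unique clonotypes whose
receptor was formed from each VJ combination. Such matrices are wide
(hundreds to ~1,000 VJ combinations) and short (tens of subjects), and the
usage of neighboring gene segments is often correlated. Any single feature
selector applied to data like this is unstable: small perturbations of the
cohort change the selected set substantially. `repsel` implements an ensemble
strategy that (i) pools several classical selectors, (ii) groups correlated
candidates, and (iii) filters the groups through a permutation benchmark
inside a group-lasso logistic regression.

## Pipeline

**Base selectors.** Six selectors are provided: information gain (univariate
filter, equal-frequency discretization into 10 bins), correlation-based
feature selection (CFS, greedy best-first search over the merit
`k r̄_fy / sqrt(k + k(k−1) r̄_ff)`), SVM-RFE (recursive elimination of the
lowest average squared linear-SVM weight over 5 stratified folds, dropping
10% of survivors per round until 2× the target size remains, then one at a
time), Boruta (shadow-feature testing against random-forest importances with
sequential two-sided binomial tests at α = 0.01, unadjusted; Confirmed and
Tentative features form the subset), Vita (5-fold cross-validated permutation
importance with an empirical null built by mirroring the non-positive
importances about zero; features beating every null value — empirical p = 0 —
are selected), and the lasso (ℓ1 logistic regression on the grid
10^(−10, −9.9, …, 10), λ chosen by 5-fold cross-validated binomial deviance).
Vita's importance uses the drop in held-out correct-class *probability*
rather than accuracy: on held-out folds of 10–20 subjects an accuracy-based
importance is quantized to steps of 1/|fold| and ties destroy the empirical
null, while the probability scale stays continuous.

Each selector emits a standardized output: a subset, an ordered subset, or a
full ranking. Subsets convert to rankings by tying selected features at rank
1 (or at ranks 1..k for ordered output) and tying unselected features at rank
G. The aggregated rank of a feature is the best position it achieved across
selectors; a feature ranked 1st by one selector and 10th by another
aggregates to 1.

**Candidate expansion and blocks.** The candidate set is the union of all
base-selected features, expanded by one (non-transitive) correlation pass:
any feature whose |Pearson correlation| with a base-selected feature exceeds
ρ_T joins, carrying the worst rank G unless a selector picked it too.
Candidates are partitioned by complete-linkage hierarchical clustering on the
distance 1 − |corr|, cut just below height 1 − ρ_T, which guarantees every
within-block pair satisfies |corr| > ρ_T. One pass (rather than transitive
closure) is deliberate: closure under a moderate threshold can swallow most
of the matrix.

**Group lasso and the permutation benchmark.** On the candidate matrix X
(p columns in B blocks) a logistic regression with a per-block ℓ2 penalty is
fitted:

    Q_λ(β) = −l(β) + λ Σ_b s_b ‖β_b‖₂ .

The penalty rescaling is `s_b = (min aggregated rank in block b) × sqrt(L_b)`.
The rank factor gives top-ranked blocks the lightest penalty. The sqrt(L_b)
size factor is the standard group-lasso multiplier: for a block of L
coherently correlated columns the gradient norm grows like sqrt(L), so
sqrt(L) weighting makes a block's entry point reflect its per-member signal
strength rather than its size. A linear-in-L factor would handicap a
10-member causal block by ~sqrt(10) relative to any singleton, letting
chance-correlated noise singletons (which the base selectors preferentially
admit) dominate the race; measured on the benchmark scenarios, the
linear variant inverts the method's intended behavior (sensitivity drops
to ~1/3 and FDR roughly quadruples), so sqrt is the package's design choice.

Each permutation round draws a row permutation π, builds the augmented design
X_A = (X, X_π) — the permuted copy preserves between-feature correlation but
is independent of the outcome — and fits the penalty path over the 2B blocks,
pseudo blocks inheriting the original weights so the race is symmetric. With
R_b = sup{λ : block b nonzero} as block importance, the benchmark
T_π = max over pseudo blocks of R_b, and the round selects
S_π = {b ≤ B : R_b > T_π} (ties lose). Over K rounds, blocks selected in at
least a fraction τ of rounds (inclusive boundary) form the final feature set.
When the candidate partition is given independently of the outcome, a null
round selects each original block with probability about 1/(B+1) — the
chance it outranks the maximum of B exchangeable pseudo blocks — so with
typical candidate sets (B ≳ 20) a single round is already conservative.
When the candidates are chosen by the base selectors this exchangeability is
partially broken; see Known limitations.

Defaults: ρ_T = 0.75, K = 50, τ = 0.5, base roster
(information gain, SVM-RFE, Vita, Boruta). With `no_base_learners` the rank
matrix is constant and every feature is a candidate, giving a stand-alone
permutation-assisted selector.

## Solver

The path solver is block-coordinate proximal descent with a per-block
quadratic majorization of the logistic loss (curvature bound
λ_max(X_bᵀX_b)/4), an unpenalized intercept, internally standardized columns,
warm starts down a 100-point geometric grid from λ_max (computed so that all
blocks are exactly zero at the top) to 10⁻³ λ_max, and an active-set strategy
with vectorized KKT screening of inactive blocks. Convergence is declared
when the largest parameter change in a sweep falls below `tol` times the
parameter scale, or — in the slow-crawl regime that partial separation
induces, where the fixed majorization curvature is far looser than the true
one — when after 2,000 sweeps the residual sits within three orders of
magnitude of `tol` (block entry/exit is decided by KKT screening and is
unaffected by the last decimals). The path is truncated once the deviance
ratio exceeds 0.999 (the usual path-solver convention — beyond saturation
entry order is meaningless). Exhausting the iteration cap raises a numerical
error naming the offending λ.

Two numerical shortcuts matter for the permutation loop. First, the fit stops
at the first grid point where any pseudo block is nonzero: T_π is by
definition that grid value, and every selection decision (strictly earlier
entry) is already determined. Second, permutation rounds use a relative
tolerance of 1e-5 — block entry is detected by KKT screening and is
insensitive to the last decimals of the coefficients.
The grid-based R_b values reproduce the selection decisions of a
bisection-refined sup{λ} on random small instances (tested), and the solver's
coefficients agree with an independent full-gradient proximal (ISTA)
implementation to 1e-4 on a three-block fixture.

## Simulation design

Six latent bases x₁..x₆ ~ iid Uniform(0,1) per subject; outcome
logit P(Y=1) = β₀ + β₁x₁ + β₂x₂ + β₃x₃ with β₀ = 0; observable proxies
v_i(j) = x_i + (0.01 + 0.5(j−1)/(g_i−1))·ε, ε ~ Normal(0, sd 0.3), fresh per
entry, g_i = 10; remaining features iid Uniform(0,1). The 30 proxies of
x₁..x₃ are causal, the 30 proxies of x₄..x₆ correlated decoys, the rest
noise; the latent bases are withheld from the feature matrix. Eight
registered scenarios cross n ∈ {50, 100}, G ∈ {600, 1200} and effect families
(−9, 6, 3) (prevalence 0.5 exactly, by symmetry of the linear predictor) and
(−14, 12, −6) (prevalence ≈ 0.26 by Monte Carlo; the registry keeps β₀ = 0
since this lands within the intended 0.25 band). The noise scale is read as a
standard deviation of 0.3: an sd of sqrt(0.3) would make even the closest
proxy only weakly correlated with its base, defeating the design's
"highly correlated group" structure. Noise is drawn per entry, the only
reading that produces the intended within-group correlation decay
(corr(x_i, v_i(j)) strictly decreasing in j, verified at n = 50,000).

What the generator does not emulate: compositional structure (real usage rows
sum to 1 and are non-negative), zero inflation of rare VJ pairs, and
between-sample depth variation. Passing benchmarks on this generator
demonstrates the selection machinery under correlated-group logistic signal,
not robustness to repertoire-specific artifacts.

## Evaluation

FDR = false positives / selected (0 for empty selections), sensitivity =
recovered causal / 30, precision = 1 − FDR, F1 = harmonic mean (0 when both
terms are 0). Stability is the Jaccard index between the selections made
independently on the two members of a simulated replicate pair, averaged
across pairs (two empty selections count as 1 — consistently selecting
nothing is perfectly stable). Empirical power is the per-causal-variable
selection frequency across replicates. For real data the weighted relative
frequency WRF_j = Σ_f 1{j ∈ S_f}/|S_f| scores features across CV folds, and
the headline set is features selected in ≥ 2 of 5 folds (configurable).
Classification feeds the selected features into eight classifiers (SVM with
linear/polynomial/RBF kernels, KNN, random forest, XGBoost, ridge- and
lasso-penalized logistic regression) with small CV-tuned grids
(C ∈ {0.1, 1, 10} for SVMs, k ∈ {3, 5, 7} for KNN, C ∈ {0.01..10} for the
penalized regressions); accuracy uses the classifier's 0.5-cutoff label rule
and AUC midrank-tied continuous scores.

## Problem sizes and compute knobs

The benchmark harness and test suite run the full method at reduced
replication: 20 replicate pairs per scenario (vs. hundreds for a
publication-grade study) over 3 master seeds, random forests of 50 trees and
a Boruta cap of 20 iterations inside the ensemble's base roster. These are
compute knobs, not method parameters: K, τ, ρ_T, the λ grid and the
generator's distributions are never scaled. The library defaults are 500
trees and 100 Boruta iterations.

## Numerical and degenerate-input choices

- Zero-variance columns: treated as uncorrelated in expansion/blocking and
  never enter the group-lasso path (their gradient is identically zero).
- Constant labels, empty tables, mismatched dimensions: rejected with typed
  errors at the module boundary.
- Boruta's binomial test is unadjusted: with a Bonferroni correction at
  G ≥ 600 neither confirmation nor rejection can resolve within a practical
  iteration budget, leaving everything Tentative (and Tentative features are
  kept per the decision-set contract, which would flood the candidate set).
- The lasso selector's CV loop touches only the informative stretch of the
  λ grid: values above the data's λ_max all yield the intercept-only model
  (one representative is evaluated) and values below 10⁻⁴ λ_max a saturated
  one.
- Gene calls: allele suffixes (`*01`) are stripped; ambiguous comma-separated
  calls resolve to the first listed gene; clonotype identity is the raw
  allele-level call pair, so two alleles of one gene are distinct clonotypes
  sharing a gene-level VJ feature.
- log2 usage ratios impute 0 for pairs absent at both timepoints, with a
  per-sample pseudocount defaulting to the reciprocal of the smaller
  unique-clonotype count of the two timepoints.

## Known limitations

The permutation benchmark calibrates against the feature-correlation
structure, not against the selection bias of the base learners. Because the
top-k selectors always emit their best-scoring features, the candidate set
contains the features with the strongest *chance* association with the
outcome, and their entry values R_b — fixed functions of the data, while only
T_π varies across rounds — beat the benchmark persistently. Under a global
null (outcome independent of all features) the final selection is therefore
not empty but retains a handful of winner's-curse features (measured: median
3–7 features at n = 50, G = 200, both at reduced and at full base-learner
compute settings), and this same mechanism is what keeps the method's FDR
small-but-nonzero in the signal scenarios. Exchangeability does hold, and the
selection rate is the expected ~1/(B+1) per round, when the candidate
partition is given rather than chosen by data-dependent selectors — the test
suite verifies both regimes.

Only binary outcomes are implemented; the likelihood sits behind a single
interface so continuous/multiclass/survival extensions would replace one
term. Row permutation is the only pseudo-variable construction offered. The
CFS search is greedy best-first, not exhaustive. P-values, confidence
intervals or formal FDR guarantees for the final selected set are not
provided — the permutation benchmark controls inclusion behaviorally, not
inferentially.
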