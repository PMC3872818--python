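# Methods

## Model

The core object is the constrained bilinear model

E = A · P + ε,

with E the targets × conditions matrix of log2 fold changes (or log2
expression), A the targets × TFs control-strength matrix whose support —
which entries may be nonzero — is fixed in advance by a regulatory network,
and P the TFs × conditions matrix of hidden TF activities.  The model
assumes (i) log-linear superposition of regulatory influences, (ii) a known,
sparse connectivity, and (iii) additive Gaussian error on the log2 scale.
Neither A nor P is sign- or scale-identified individually: for any
invertible diagonal D, (A D)(D⁻¹ P) reproduces E.  The package resolves
this by normalizing each column of A to unit Euclidean norm and fixing the
sign so that fitted control strengths maximally agree with the signed prior
network (fallback: first nonzero of each column positive).  Reported TFAs
are therefore unitless, comparable across runs only under the same
convention.

### Identifiability

The decomposition is essentially unique (up to the diagonal above) when
three structural criteria hold: (1) the support pattern admits a
full-column-rank A; (2) for every TF, deleting its column and the rows of
its support leaves a pattern that still admits full column rank on the
remaining TFs; (3) there are at least as many conditions as TFs.  Criteria
1–2 are checked numerically by generic rank: the pattern is instantiated
with i.i.d. standard-normal nonzeros at a fixed seed, twice, and the
numerical rank (SVD, tolerance 1e-8 × largest singular value) is taken.
Generic rank equals structural rank with probability one, and the test
suite verifies exact agreement with an independent maximum-bipartite-
matching computation of structural rank on hundreds of random patterns.
`reduce_to_identifiable` repairs failing patterns greedily: among TFs
failing criterion 2, the lowest-degree column (ties by index) is removed
and the check repeated; it never raises, returning an empty pattern if
nothing identifiable remains.

### Fitting

`fit_nca` alternates exact least-squares half-steps: the P-step solves
min‖E − A P‖² (+ ridge·‖P‖² when ridge > 0) in closed form; the A-step
solves each gene's row independently over its allowed support, so entries
off the support are exactly zero by construction, not by thresholding.
Each half-step minimizes the same objective over one block, so the
objective is monotone non-increasing; `residual_trace` records its square
root per half-step (equal to the Frobenius residual when ridge = 0).
Iteration stops when the relative objective change drops below `tol`
(default 1e-6) or the residual falls below `tol`·‖E‖ (the exact-fit limit),
with `max_iter` = 500 as a backstop.  A is initialized from the signed
prior network (sign × 1.0) when available — sign-consistent starts both
speed convergence and anchor the sign convention — otherwise with uniform
±[0.5, 1.5] values at the given seed.

When criterion 3 fails (fewer conditions than TFs) the P-step is singular;
the fit then applies an automatic Tikhonov ridge of
1e-3 × mean diag(A₀ᵀA₀), computed once from the initial A and logged
prominently.  This makes the under-determined case runnable and stable
while being explicit that the returned TFAs are the minimum-norm-flavored
solution of a non-unique problem.  Ridge-regularized fits on flat valleys
progress slowly near the optimum; drivers on such instances use
`tol` = 1e-4, well below the noise scale of the data they fit.

## Differential expression

Per ecotype, each gene is tested heat vs control with the two-sided
pooled-variance t-test.  The pooled test is the default because at
triplicate sample sizes it holds its nominal level exactly under a
Gaussian equal-variance null, whereas the Welch variant (available via
`equal_var=False`) is measurably conservative (empirical level ≈ 0.0055 at
nominal 0.01 with 3 + 3 replicates).  Significance is a raw p ≤ α cut-off
(α = 0.01 default); no multiple-testing correction is applied by default,
matching the raw-cutoff convention of classical ecotype-panel array
analyses, with Benjamini–Hochberg available as an option.  Genes whose two
arms are both constant receive p = 1 so constant probes never surface.
Direction is the sign of the log2 fold change (heat mean − control mean);
exact-zero fold changes carry no direction and are counted in totals only.

The genotype × treatment interaction is the standard two-factor
fixed-effects ANOVA with interaction, computed by the closed-form balanced
decomposition vectorized across genes (on a balanced design all
sums-of-squares types coincide).  Empty cells raise with the offending
(ecotype, treatment) named; unequal replicate counts also raise, since the
closed form requires balance and the emulated design is fully balanced.
The test suite cross-checks the per-gene p-values against statsmodels OLS
with type-II sums of squares.

## Network construction

Edges are thresholded on the absolute Pearson correlation — both signs
qualify, since repression edges (negative r) are half the point of a
signed network.  By default profiles are the per-ecotype log2 fold-change
vectors (10 points in the emulated design); correlating across raw sample
columns is a config option (`corr_axis="samples"`).  Constant profiles
have undefined correlation and are dropped with a warning.  TF self-pairs
and TF–TF pairs are excluded so the regulator and target layers stay
disjoint, which is what the downstream decomposition assumes.  TFs with no
surviving edge are dropped (logged), so every TF in a returned network is
connected.

## Reporting

A TF's "responsive" ecotypes are those where its activity's robust z-score
(median/MAD, MAD scaled by 1.4826) reaches `threshold_z` (default 2.0) in
absolute value — a deliberately assumption-light reading of "highly
active", exposed as a parameter.  When the MAD is zero (a majority of
conditions exactly at the median), conditions off the median are called
responsive; constant rows therefore classify as "none".  Clustering uses
d = 1 − Pearson r with average linkage (UPGMA); bootstrap support resamples
condition columns with replacement and counts how often each internal
node's leaf set recurs — resampling conditions rather than genes because
support should reflect stability of the profile structure across
conditions.  Over-representation is the one-sided hypergeometric upper
tail with Bonferroni adjustment over the number of sets tested.

## Synthetic data

Three generators provide ground truth:

* `generate_connectivity` rejection-samples Bernoulli(density) patterns
  (empty rows/columns topped up) until criteria 1–2 pass, with a
  100-attempt budget — rejection rather than repair keeps the accepted
  patterns unbiased draws from the identifiable set.
* `simulate_nca_instance` draws A's nonzeros uniform on ±[0.5, 1.5]
  (bounded away from zero so support recovery is well-posed), P i.i.d.
  standard normal, and adds Gaussian noise of standard deviation
  `noise_sd` on the log2 scale.
* `simulate_ecotype_experiment` emulates the array design: shared per-gene
  baselines (Normal(7, 2) log2 units), a `prevalence` fraction of genes
  planted as responders — each in one ecotype plus Binomial(n−1, 0.05)
  further ecotypes, so most planted responses are ecotype-specific — with
  log2 shifts Normal(0, `effect_sd`) and replicate noise
  Normal(0, `replicate_sd`).  Defaults used throughout the tests mirror
  the emulated design: 10 ecotypes, 3 replicates per arm, effect_sd 1.5,
  replicate_sd 0.3.
* `simulate_regulated_experiment` composes the two: target fold changes
  are A·P from a planted decomposition, TF genes respond with their own
  activity row (transcript level as activity proxy), and both are embedded
  into a replicated control/heat design.

What the generators do *not* emulate: probe-level intensity distributions,
RMA normalization artifacts, correlated (batch) noise, heavy-tailed
per-gene variances, and the biological coupling between a TF's transcript
and its activity.  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated model, not
robustness to everything real arrays do.

## Problem sizes and numerical choices

The test and acceptance workloads use a 60-gene × 5-TF × 20-condition
instance for recovery (noise-free and noise 0.1 over 20 seeds), a
10,000-gene × 10-ecotype × 3-replicate null for calibration (3 binomial
standard errors around α), 100 random patterns (≤ 20 genes, ≤ 6 TFs) for
the identifiability oracle, 50 × 50 instances for the network oracle, and
one 1294-target × 35-TF × 10-condition instance — the study network's
dimensions — as the under-determined smoke test.  The analysis drivers run
a 300-target × 12-TF scaled-down version of the same design.  All floats
are written with 17 significant digits and read back with round-trip float
parsing, so every file format is lossless.

## Known limitations

* The under-determined (conditions < TFs) TFA estimates depend on the
  ridge and initialization; only the identifiable regime carries a
  uniqueness guarantee.
* The greedy identifiability reduction is not minimal — it may remove more
  TFs than strictly necessary on adversarial patterns.
* Correlation-thresholded networks inherit all confounding of co-expression:
  an edge is evidence of shared response, not of direct binding.
* The balanced-ANOVA implementation deliberately rejects unbalanced
  designs rather than silently switching SS types.
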