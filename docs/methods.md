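# Methods

## Model and hypotheses

Data are an m × N matrix of numeric expression values with samples assigned
to p = q + 1 groups, one of which is the reference. For feature j and
experimental group i the pairwise null is H_ij: μ_ij = μ_0j, tested with
the many-to-one statistic

    T_ij = (x̄_ij − x̄_0j) / ( s_j · sqrt(1/n_i + 1/n_0) ),

where s_j² pools the within-group variance across all p groups
(df = Σ n_g − p). Under the per-feature global null the vector
(T_1j, …, T_qj) is central multivariate t with correlation
r_ik = sqrt(λ_i λ_k), λ_i = n_i/(n_i + n_0); a balanced design gives
r_ik = ½. The working assumptions are normal within-group errors with a
common variance per feature and complete data (missing values are rejected,
never imputed — the df bookkeeping assumes complete columns). Comparison
index i always means "experimental group i minus reference", so "up" means
higher in the experimental group.

## The three-step procedure and its error rate

A directional call at (j, i) is false if H_ij is true or if the declared
sign disagrees with the true sign of μ_ij − μ_0j. The mdFDR is the
expectation of the proportion of false calls among all calls (0 when no
calls are made). The procedure:

1. screening p-value p_j = P(max_i |T_i| ≥ max_i |T_ij|) from the joint
   null; Benjamini–Hochberg step-up at level α selects R features;
2. each selected feature's q single-step adjusted p-values
   P_ij = P(max_k |T_k| ≥ |T_ij|) are thresholded at R·α/m (the realized,
   data-dependent R; when R = 0 the stage is skipped);
3. rejected comparisons are signed by T_ij.

Step 2's plain threshold on the already-adjusted p-values is itself an
mdFWER-controlling rule at level R·α/m, which is what the mdFDR guarantee
requires of the within-feature stage. A feature can clear screening with no
pairwise rejection (a near-boundary screening p); such features are
reported as not differentially expressed but kept, flagged, in the audit
table. Under the simulated study conditions this affects well under 5 % of
selected features.

### Variant and comparator pipelines

The within-feature rule is pluggable. The shipped variants apply Holm
(step-down), Hochberg (step-up) or Bonferroni to the q *adjusted* p-values
P_ij at level R·α/m. Feeding the variants the adjusted p-values (rather
than raw two-sided t p-values) is a deliberate design choice: it keeps the
variants inside the same joint-distribution family so that the main
single-step rule dominates them by construction, which reproduces the
documented behaviour of this methodology family (the single-step rule most
powerful, then Hochberg ≥ Holm ≥ Bonferroni). With raw-t inputs Holm and
Hochberg would instead overtake the single-step rule through their later,
larger thresholds — a different (also valid) procedure, but not the one
this package models. The independent comparator pipeline ("guo") uses the
Bonferroni global test min(1, q·min_i p_i) on raw two-sided t p-values for
screening and a Bonferroni rule on the same raw p-values for step 2; it
involves no joint-distribution information and is the conservative baseline
the main method improves on (the adjusted p never exceeds q times the raw
p, strictly beating the Bonferroni bound at every correlation).

## Numerical evaluation of the tail

P(max_i |T_i| ≥ c) is computed from the conditional-independence
representation: given the latent reference variate Z₀ = z and the pooled
scale W = w (W² ~ χ²_df/df),

    P(all |T_i| < c | z, w) = Π_i [ Φ((cw − a_i z)/b_i) − Φ((−cw − a_i z)/b_i) ],

a_i = sqrt(λ_i), b_i = sqrt(1 − λ_i). The z-integral uses 64 Gauss–Hermite
nodes; the w-integral uses generalized Gauss–Laguerre nodes for the χ²
density (40 nodes for df ≥ 30, 96 for 10 ≤ df < 30, 160 below — small df
have heavy tails and need more). Absolute accuracy is ~1e-9 for df ≥ 10
(a few 1e-6 at df = 4). Because the tail is a smooth monotone function of
c for a fixed null model, evaluations go through a cached cubic spline fit
to quadrature values on a step-0.005 grid over c ∈ [0, 15] (~1e-10
interpolation error; direct quadrature beyond the grid). This makes
screening plus pairwise p-values for thousands of features essentially
free and guarantees that every evaluation of the same null model —
screening or pairwise — is numerically identical. Results are clipped to
[0, 1]. Unbalanced designs are supported (λ_i from the group sizes); a
correlation matrix without the product form sqrt(λ_i λ_k) (only reachable
by constructing a null model by hand) falls back to fixed-seed Monte Carlo
(200 000 draws by default) with a reported standard error. Features with
zero pooled variance have undefined statistics: they get screening p = 1
and are never selected.

Ties in sorted p-values (BH, Holm, Hochberg) are broken by stable sort on
the original index; tied values share a threshold, so outcomes are
order-independent. Zero p-values are legal and rejected at any positive
level.

## The synthetic-data generator

`SimulationConfig` defaults encode the study conditions: p = 4 groups
(reference last) of n = 10 samples, m = 1000 features, σ = 1 normal noise,
nominal α = 0.05. A proportion pi1 of features is non-null (m₀ = round
(m·(1−pi1)) nulls); each non-null feature draws an independent U(0, 2.5)
mean for every experimental group, so every non-null feature is truly
non-null, with positive sign, in all q comparisons — effects are modest
relative to σ, so all procedures operate in a low-power regime. Reference
means are always 0. Three noise structures: independent; equicorrelated
across genes within a chip; equicorrelated across chips within a gene —
generated exactly via the shared-factor identity
X = sqrt(ρ)·Z_shared + sqrt(1−ρ)·Z_own.

Scoring is per (feature, comparison) pair: every directional call is one
discovery; calls on null pairs and wrong-signed calls are false; the
realized FDP divides false calls by max(1, all calls), and power divides
correctly-signed calls by the number of non-null pairs. Cell estimates
average 200 independent replications by default (1000 for full-fidelity
runs, via `n_reps`); replication substreams derive from
(seed, structure, pi1, replication index) so all procedures score identical
datasets, making procedure contrasts paired.

What the generator does *not* emulate: heavy-tailed or skewed expression
noise, per-feature variance heterogeneity beyond the pooled model,
negative or mixed-sign effects within a feature, realistic gene–gene
correlation beyond single-factor equicorrelation, and unequal group sizes
(the pipeline supports them; the study design does not use them). Passing
tests therefore certify the procedure's error control and power ordering
under the stated Gaussian conditions, not its behaviour on raw microarray
intensities, which need upstream normalization in any case.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | target mdFDR level |
| `screening` | `dunnett` | `dunnett` (max-\|T\| joint tail) or `bonferroni` (q·min p) |
| `pairwise` | `dunnett` | `dunnett`, `holm`, `hochberg`, `bonferroni` |
| `pairwise_pvalues` | `dunnett` | adjusted (`dunnett`) or `raw` two-sided t inputs to step 2 |
| `SimulationConfig.n_reps` | 200 | replications per simulation cell |
| `SimulationConfig.rho` | 0.0 | equicorrelation of the dependent structures |
| `DunnettNullModel.mc_draws` | 200 000 | Monte-Carlo fallback draws |

## Known limitations

- The mdFDR guarantee is proven under independence of the feature-level
  p-value vectors; under the equicorrelated structures control is verified
  empirically, not analytically.
- Quadrature accuracy degrades below df ≈ 8 (still ~1e-6, far below any
  decision threshold).
- Heteroscedastic (unequal-variance) statistics, one-sided intervals and
  step-down joint-distribution rules are out of scope.
- Duplicate probe sets mapping to one gene are tested as given; no
  aggregation is attempted.
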