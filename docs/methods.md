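# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Differential expression

Per gene, the two-group comparison uses the difference of condition means
on the log2 scale (sign convention: response − nonresponse, stated in
every output header) over a pooled-variance standard error.  Variances are
moderated empirical-Bayes style: the gene-wise sample variances s²g with
d_g = n₁ + n₂ − 2 residual df are assumed to follow a scaled-F marginal
around a prior (d₀, s₀²), estimated by method of moments on log s²g —
the prior df d₀ comes from inverting the trigamma function on the excess
spread of log variances, the prior variance from the mean.  The moderated
statistic uses posterior variance (d₀s₀² + d_g s²g)/(d₀ + d_g) with
d₀ + d_g degrees of freedom.  When the observed spread of log variances is
no larger than its sampling noise the prior df is infinite and every gene
is pooled to s₀² (normal reference distribution).  The implementation was
validated during development against an independent empirical-Bayes
reference implementation on a frozen heteroscedastic fixture (agreement to
~1e-14 in t; the reference values are frozen in the test suite).

Moderation matters here because the motivating cohorts are small and
unbalanced (9 responders vs 44 non-responders); an ordinary t on 9 samples
is dominated by unstable variance estimates.  A `moderation=off` switch
gives the ordinary pooled t (property-tested to 1e-10 against the closed
form).

Gene calls: up if adjusted p < 0.05 (BH step-up) and FC ≥ 1.5; down under
either of two conventions, `reciprocal` (FC ≤ 1/1.5, symmetric on the log
scale, the default) or `half` (literal FC < 0.5).  Both exist because
published fold-change cutoffs are quoted in both forms; the asymmetry is
surfaced as an option rather than silently resolved.  Cross-cohort
intersection defaults to `any_direction` since direction agreement is an
extra assumption; `same_direction` is available.

Degenerate inputs: a gene constant in both groups with equal means gets
t = 0, p = 1; constant with unequal means and no moderation triggers an
epsilon-variance guard (1e-12) and a logged warning rather than a crash.

## Differential co-expression

Pearson correlations are computed per condition over the DEG universe.
With two cohorts the default pooling (`per_dataset_z`) z-scores each gene
within each cohort before concatenating samples, so a per-cohort baseline
offset cannot masquerade as correlation; `concat` pools raw values.  The
generator plants a per-gene batch shift (SD 0.2) between cohorts precisely
to exercise this choice.  Correlation against a constant vector raises an
error in the scalar API and yields an unclassifiable (NONE) pair in the
matrix path — an undefined correlation is never reported as 0.

Classification applies two criteria jointly at τ = 0.7 (a conventional
threshold for calling a gene pair co-expressed; configurable, including a
separate `tau_low` for stricter "no correlation" definitions):

* pattern — |r| ≥ τ in exactly one condition, |r| < τ in the other, giving
  PO/NO (response-only) and OP/ON (nonresponse-only) classes;
* ratio — |(r_R − r_N)/r_R| ≥ 1, with the response-state correlation
  always in the denominator.

Two consequences are worth spelling out (both are asserted by tests):
for PO/NO pairs the ratio is *strictly stronger* than the pattern — it
passes iff r_N ≤ 0 (r_N ≥ 2·r_R > 1.4 being impossible) — so a pair like
(r_R, r_N) = (0.9, 0.1) is NOT differential.  For OP/ON pairs the
denominator is near zero; the guard (ε = 1e-12) returns a PASS sentinel
(+inf) whenever the correlations actually differ, so OP/ON classification
reduces to the pattern alone.  Without that guard no OP/ON edge could ever
be called, which would make the nonresponse network empty by construction.

No per-correlation significance test is applied: the magnitude threshold
is the criterion, by design.

## Networks and hub modules

PONO is the union of PO and NO edges, OPON of OP and ON; both are simple
undirected graphs (duplicate pairs collapse, self-loops are rejected) and
a gene may appear in both.  Centralities: degree, and unnormalized
betweenness on unweighted shortest paths (Brandes accumulation via
networkx), counted per unordered pair and per connected component.
Ranking uses betweenness only ordinally, so normalization is irrelevant.

Hub selection: candidates = (top K by degree) ∩ (top K by betweenness)
with K = 10, ordered by rank-sum, truncated to `module_size` = 5.  All
ties break deterministically (higher degree, then lexicographic gene id),
making selection invariant to node input order.  An empty intersection
falls back to the union with a logged warning.  K and the module size are
stand-ins — the centrality-intersection idea fixes neither — and all three
are exposed on the CLI.

The module correlation matrix packs r_response into the lower triangle and
r_nonresponse into the upper (unit diagonal), the usual split-triangle
module plot; transposition swaps the conditions.

## Regulator overlay and over-representation

TF→target tables (two configurable columns, duplicates dropped and
counted) are intersected with each network's genes; matching is exact but
case-insensitive, with no alias resolution.  Ranking is by raw in-network
target count (ties lexicographic); a hypergeometric-enrichment variant
against the table's own target background is provided because raw counts
favour promiscuous TFs.  Gene-set over-representation uses the
hypergeometric upper tail P(X ≥ k) with BH adjustment across sets; the
universe defaults to the genes on the expression platform, not the genome,
because genes that could never have been observed should not inflate
significance.

## Survival analysis

The Cox partial likelihood (Efron tie handling by default; Breslow
switchable — they coincide without ties, which is tested) is maximized by
Newton iterations with step-halving; convergence at max |score| < 1e-9 or
relative log-likelihood change < 1e-9.  Covariates are z-scored and the
training statistics stored on the model, so indices for new samples use
the training scale.  Monotone likelihood (separation) makes the score
vanish while a coefficient drifts to infinity at roughly one unit per
Newton step; any |β| > 10 on the z scale — a per-SD hazard ratio above
e¹⁰, unreachable at any finite maximum in practice — raises an error
naming the covariate.  Inside the module evaluation this error engages a
small ridge penalty (λ = 0.01) with a logged flag instead, since a
separated fit still defines a usable risk ordering.  The fitter is checked
against lifelines (coefficients and standard errors to 1e-6) and against a
1-D grid-search oracle on a 4-subject fixture whose maximizer satisfies
u² − u − 4 = 0, u = e^β.

Kaplan–Meier estimation and the log-rank test delegate to lifelines and
are pinned by hand-computed product-limit and log-rank values; KM with no
censoring equals the empirical survival function exactly.

### Honest module evaluation

`evaluate_network_prognosis` chains z-scoring → Cox fit → prognostic index
→ median split → KM → log-rank → high-vs-low HR.  The single most
important design decision in this module: with several genes, fitting the
index and testing its median split **on the same samples** is not a valid
test.  The fitted direction β̂ aligns with the outcome even under the
null; in simulations (5 correlated null genes, n = 200) the nominal-5%
log-rank rejected ~37% of the time, and cross-fitted ("pre-validated")
indices still ~10%.  The default is therefore `pi_method="split"`: the
model is fitted on a deterministic half of the samples (alternating sorted
ids) and stratification, KM curves, log-rank and HR are computed on the
held-out half only — measured type-I error ≈ 5%.  `cv` (pooled 5-fold
pre-validated indices; uses all samples, small residual optimism) and
`insample` (the classical workflow; exploration only) remain available and
are flagged in the result.  The `optimal` split variant (cutpoint between
the 20th and 80th PI percentiles maximizing the log-rank statistic) is
additionally optimistic by construction and is gated behind an explicit
flag for the same reason.

Median splits send ties to the low group and are invariant to monotone
transforms of the index (tested).

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

* log2-scale expression, baseline 7.0, residual noise SD σ = 0.5 (typical
  residual variability of RMA-normalized arrays; chosen once, not tuned);
* DEGs as ±δ mean shifts in the response condition (default δ = 1.0 log2
  units, i.e. a 2-fold change);
* correlation blocks drawn from a compound-symmetry multivariate normal —
  chosen over a latent-factor construction so the pairwise correlation is
  exact by design — with ρ_on (default 0.85) in the block's "on" condition
  and ρ_off (default −0.3) otherwise.  ρ_off is negative rather than 0
  because the ratio criterion for PO/NO pairs passes only when the
  off-condition correlation is ≤ 0; planting 0 would lose half the pairs
  to sampling noise.  Compound symmetry bounds negative correlation by
  ρ ≥ −1/(m−1): the on-condition value is validated strictly (error before
  sampling), while ρ_off is clamped into the feasible range with a 5%
  margin (−0.2375 for a 5-gene block) since it only encodes "absent or
  opposite".  Negative *on*-condition plants (NO/ON pairs) therefore use
  2-gene blocks, where ρ = −0.85 is feasible, with sign-flipped ρ_off;
* survival from an exponential proportional-hazards model: event rate
  λ·exp(Σβ_g z_g) with per-gene z-scores, independent exponential
  censoring, and a calibration helper that solves E[c/(c+λᵢ)] = target for
  the censoring rate (default target 30%);
* the cohort-scale fixture: two cohorts of 53 (9/44) and 26 (13/13)
  samples over 2000 genes sharing 100 planted DEGs (the second cohort gets
  a per-gene batch shift, SD 0.2), one 5-gene block per network plus one
  negative pair each, and a separate 200-sample survival cohort in which
  both modules are active with β chosen so exp(ΔE[PI]) between PI halves
  is ≈ 4 (response module) and ≈ 3.7 (nonresponse module).  The two-group
  HR measured on such data is smaller than exp(ΔE[PI]) because of
  within-group heterogeneity (a frailty-type attenuation); the recovered
  values around 2.5–3.6 are the expected behaviour, not a loss of signal.

Every generated object carries the planted truth (DEG ids, pair classes
computed through the *same classification rule the pipeline uses* —
guaranteeing the truth is consistent with the criterion — hub ids, β's),
and fixed seeds make outputs bit-reproducible.

What the generator does **not** emulate: probe-level noise and
probe→gene mapping, RMA artifacts, heavy-tailed or count-distributed
expression, correlated censoring, covariate effects (age, sex), and any
real disease biology.  Passing tests therefore demonstrate that the
pipeline recovers the structure it is designed to detect under its own
model assumptions — not that those assumptions hold in any particular
real dataset.

## Numerical choices and degenerate inputs

* Correlations are clamped to [−1, 1] against round-off; the ratio's
  zero-denominator guard uses ε = 1e-12.
* BH adjustment validates p ∈ [0, 1] and preserves input order
  (permutation-equivariance is property-tested).
* Trigamma inversion uses Newton iteration from a 0.5 + 1/y start;
  excess spread ≤ 0 maps to an infinite prior df.
* Duplicate gene rows collapse to the highest-mean row by default
  (configurable to `mean` or `error`); condition labels beyond the two
  expected ones are rejected unless explicitly dropped.
* All stochastic defaults (problem sizes in tests and the acceptance
  script: 20-seed recovery runs, 500-seed null calibration, 1000-rep
  log-rank calibration at n = 200) were chosen to give stable Monte Carlo
  estimates in seconds-to-minutes on one CPU.

## Known limitations

* The ratio criterion is asymmetric by construction (response in the
  denominator); swapping the phenotype labels changes which pairs pass.
  This mirrors the method being implemented; users who want symmetry can
  run both orientations.
* Hub selection parameters (K = 10, module size 5) are conventions, not
  estimates; sensitivity should be checked on real data.
* The split-sample default halves the effective n of the prognostic
  evaluation; with very few events, `cv` may be preferable despite its
  small optimism.
* No covariate adjustment in the Cox stage, no paired designs, no
  partial-correlation or soft-threshold network variants.
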