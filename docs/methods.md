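# Methods

This note documents the statistical models behind `reopair`, the design
choices made where the procedure is underdetermined, and what the
synthetic cohorts do and do not establish.

## Relative expression orderings

For a lncRNA pair (a, b) and sample j, the REO state is
X_ij = 1 iff expr(a) < expr(b), and 0 otherwise — ties deliberately map to
the "≥" state rather than being broken at random, so the matrix is a
deterministic function of the expression table. Because X depends only on
the within-sample ranking of two transcripts, it is invariant under any
strictly monotone per-sample transform (TPM vs. counts vs. log scale), a
property asserted by tests for both the REO matrix and the downstream risk
scores.

Pairs are enumerated in canonical lexicographic orientation
(a_id < b_id). A fitted or published risk model, however, stores its own
orientation per pair — published signatures name pairs in a particular
order — and scoring respects the stored orientation, flipping X → 1 − X
where it disagrees with the canonical one.

Pairs whose "1" state is rarer than 20% or more common than 80% across
samples are removed before survival screening (boundaries are kept; the
removal rule is strict). A near-constant pair cannot stratify a cohort,
and with binary covariates near-constant columns are also the ones that
produce separation problems in Cox fits.

## Cox fitting

All proportional-hazards fitting in the package (pair screen, stepwise
search, multivariable adjustment) runs on an in-package Newton–Raphson
solver for the Cox partial likelihood with Breslow tie handling by default
and Efron as an option. Two reasons for not delegating these fits:
Breslow ties are the contract throughout (with binary covariates and
near-continuous times few ties are expected, and Breslow is the simplest
consistent choice), and the univariate pair screen fits thousands of
single-binary-covariate models, for which the risk-set sums reduce to
at-risk counts and the whole screen vectorises across pairs — identical
results regardless of the block size used (asserted by test). The solver
is cross-checked in the test suite against lifelines (tie-free data, where
Breslow = Efron) and scikit-survival's Breslow implementation (tied data).

The screen keeps a pair when its Wald p-value, 2Φ(−|β̂/se|), is below
0.005. No multiplicity correction is applied at this stage: the raw cut is
part of the screening design, and the later selection stages shrink the
set further. Pairs whose fit does not converge (complete separation,
vanishing information) are flagged and dropped, and the screen continues.

A simulation-established caveat: when several planted pairs carry hazard
simultaneously, the *marginal* univariate coefficient of each pair is
attenuated relative to its true conditional log-hazard (Cox models are not
collapsible over omitted covariates). Single-pair recovery of β is
therefore tested in the one-pair configuration, and multi-pair power is
tested at the event rates described below.

## Moderated differential expression

Pyroptosis-related lncRNAs are nominated by a limma-style moderated t-test
between the two panel clusters on log2(TPM+1). Per-gene residual variances
s²_g (d = n₁ + n₂ − 2 df) are shrunk toward a common prior s₀² with prior
df d₀ estimated by moment matching on z_g = log s²_g:

    Var(z) = ψ′(d/2) + ψ′(d₀/2),
    E(z)   = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2),

inverting the trigamma function by Newton iteration. The moderated
statistic uses s̃²_g = (d₀ s₀² + d s²_g)/(d₀ + d) with d₀ + d degrees of
freedom. Forcing d₀ = 0 reproduces the ordinary per-gene pooled-variance
t exactly; forcing d₀ = ∞ collapses every gene onto the common prior
variance (both limits are asserted by tests). Selection uses strict
inequalities: |log2FC| > 1 and BH FDR < 5%. The fold-change sign
convention is cluster 1 (the larger cluster) minus cluster 2.

Agreement with the reference empirical-Bayes implementation is established
qualitatively on synthetic data (null uniformity, FDR control, planted-DE
recall), not coefficient-by-coefficient.

## Signature selection

The screened pairs enter an L1-penalised Cox regression
(scikit-survival's coordinate-descent path solver, l1_ratio = 1). Binary
covariates are standardised internally for fitting and coefficients
reported back on the 0/1 scale. The penalty grid is log-spaced (50 values,
alpha_min_ratio 0.01) and the cross-validation loss is the
Verweij–van Houwelingen partial-likelihood deviance,
−2·(logPL_full(β_k) − logPL_train(β_k)) per fold, with ten seeded folds;
the chosen penalty minimises the mean CV deviance. If the active set there
is empty, the smallest penalty with at least one nonzero coefficient is
used instead, with a warning.

The LASSO-selected pairs then seed a bidirectional stepwise search
minimising AIC = −2·logPL + 2·|terms|: starting from the full candidate
model, every single-term drop and add is evaluated and the best
AIC-decreasing move accepted until a local minimum; the model is never
emptied, and a non-convergent starting fit falls back to forward
selection. Stepwise AIC retains a pure-noise term whenever its
likelihood-ratio statistic exceeds 2 — probability ≈ P(χ²₁ > 2) ≈ 0.16 —
so the expected noise-drop rate is ~84%, which is what the tests assert.
Final coefficients come from the unpenalised Breslow-Cox fit on the
selected terms.

## Thresholding and evaluation

Time-dependent ROC curves use the cumulative-case / dynamic-control
construction at horizon t: cases have an event by t, controls survive past
t. The default estimator handles censoring through Kaplan–Meier estimates
of S(t | marker ≥ c) for each observed cutoff c, inverted by Bayes' rule
into sensitivity and specificity; a nearest-neighbour estimator (span
0.25·n^−0.20 in marker rank) is available as an option. With no censoring
before the horizon the KM construction reduces exactly to the empirical
ROC, and its trapezoidal AUC equals the Mann–Whitney statistic — the
oracle test for the implementation. The raw KM sensitivity/specificity
sequence can be locally non-monotone; an isotonic cleanup is applied to
the *reported* curve only, while AUC and Youden maximisation use the raw
values. The AUC is a trapezoidal integral along the cutoff-ordered curve.

The risk threshold is the observed score cutoff maximising Youden's
J = sensitivity + specificity − 1, with ties broken toward the smaller
(more sensitive) cutoff; classification is high risk iff
score ≥ threshold, so a sample exactly at the threshold is high risk.
Horizons are measured at 365.25 days/year.

Multivariable Cox adjustment encodes gender as male = 1, collapses stage
to I–II vs III–IV and grade to G1–G2 vs G3–G4 (configurable), keeps age
continuous, and drops constant or collinear columns (greedy rank check)
with warnings.

## Synthetic cohorts

`generate_cohort` draws, from one integer seed:

* **Subtypes** — each sample is subtype 1 with probability `subtype_prob`
  (default 0.5). The `n_prg` panel genes (default 40) get subtype-specific
  means separated by 2·`noise_sd`, which across 40 genes separates the two
  groups far beyond what Ward clustering needs.
* **Differential lncRNAs** — `n_de_lnc` lncRNAs receive a subtype shift of
  magnitude 1.25–2 on the log2 scale (true |log2FC| > 1).
* **Planted pairs** — each pair's members share a per-sample level
  (baseline uniform on log2 4.5–6, plus shared jitter with sd 3·`noise_sd`)
  and are displaced symmetrically about it by at least 1.5·`noise_sd`
  each, so the ordering equals the latent Bernoulli state Z exactly, with
  no ties, and ties of the *margin* to the noise scale make the pair — not
  either member's marginal level — the carrier of the signal. Pair members
  also get a shared subtype shift so the differential-expression stage can
  nominate them, mirroring how prognostic pairs arise from the DE pool in
  a real cohort. Z has prevalence drawn from `prevalence_range` (default
  0.3–0.7).
* **Survival** — exponential proportional hazards with linear predictor
  Σ β·Z over planted pairs and baseline hazard 1/1500 per day (median OS
  around 2.8 years at β = 0, a plausible HCC scale). Censoring is uniform
  on (0, T_max) with T_max solved numerically so the expected censoring
  fraction matches `censor_rate` (default 0.65, a TCGA-like follow-up).
  A `short_followup_frac` of samples (default 5%) get survival under 30
  days or missing survival to exercise the cohort filter.
* **Clinical covariates** — age, gender, stage, grade drawn independently
  of the hazard, so multivariable adjustment should find the risk score
  and nothing else.

Defaults mirror a 343-sample cohort with a 240/103 train/validation split.
Recovery and power tests use n = 400 cohorts with `censor_rate` 0.40
(~60% events) and planted |β| of 1.2–1.5; at those event rates follow-up
spans roughly three years, so synthetic thresholding and ROC evaluation
use a 3-year horizon (the 5-year default applies to real cohorts and the
published signature). Test replication counts (typically 5–20 seeds) keep
the default suite to about a minute.

What the generator does *not* emulate: TCGA marginal expression
distributions, library-size or batch effects, correlation between
clinical covariates and outcome, non-proportional hazards, and informative
censoring. Passing recovery tests therefore demonstrate correctness of the
pipeline's computations under its own modelling assumptions, not
performance on real cohorts.

## Numerical details and edge cases

* Newton–Raphson Cox fits use step halving on the partial likelihood,
  convergence on both the likelihood change (<1e-9) and the gradient
  norm, and declare divergence (complete separation) beyond |β| = 50;
  the vectorised binary screen caps |β| at 30 and reports such pairs as
  non-converged with p = 1.
* Ward clustering z-scores each panel gene over samples; zero-variance
  genes are excluded with a warning, missing panel genes are dropped with
  a warning. Cluster labels are renumbered by decreasing size (label 1 is
  the larger cluster) for deterministic reporting.
* TPM requires per-transcript effective lengths in kb and refuses
  non-count inputs; inputs that are already TPM skip the step. TPM and RPM
  columns sum to 10⁶ by construction (asserted).
* The 30-day filter retains a sample at exactly 30 days ("less than 30"
  is removed); the miRNA filter removes a miRNA only when its zero
  fraction strictly exceeds 50%.
* The train/validation split is a simple seeded permutation (no
  stratification) followed by a covariate-balance report (rank-sum for
  numeric, chi-square for categorical covariates; degenerate covariates
  flagged, not failed).
* The hypergeometric overlap test is the exact upper tail P(X ≥ k),
  one-sided toward enrichment.
* ceRNA assembly takes interaction edge tables as two-column TSVs
  (database exports); node prognosis is tested by univariate Cox on
  continuous log2(expression + 1) at α = 0.05.

## Known limitations

* The stepwise search finds a local AIC minimum; the exhaustive-subset
  oracle test shows it usually, but not always, attains the global one.
* LASSO-per-fold paths reuse the full-data penalty grid; the solver may
  truncate the small-penalty end of a fold's path, in which case the last
  available coefficients are carried forward.
* The NNE ROC estimator is a plain nearest-neighbour smoother in marker
  rank; it is validated for agreement with the KM estimator on strong
  markers, not against an external implementation.
* The published signature ships with its printed coefficients and
  threshold; applying it requires expression for all 22 lncRNAs under the
  same identifiers.
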