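# Methods

## Setting

The package implements the analysis chain of a stated-preference study
of sheep trait preferences among smallholder farmers: a discrete choice
experiment over binary, effect-coded ram and ewe attributes (6 and 7
attributes respectively), administered as four blocked choice situations
of four designed alternatives plus an opt-out, analysed with a
generalized multinomial logit (G-MNL), and complemented by weighted
rank-preference indices for ranking-survey questions and descriptive
flock-structure ratios.  Because the original survey's raw responses are
not bundled, every estimator is exercised against a synthetic-respondent
generator whose defaults are the study's own published conditions
(370 respondents, the published coefficient estimates as true
parameters, opt-out rates of 0.47%/0.4%).

## Experimental design

Attributes are effect coded +1/−1, so a part-worth is half the utility
gap between an attribute's two levels.  Fractions of the 2^k factorial
are regular designs taken from standard minimum-aberration generator
tables (2^(6−2): E=ABC, F=BCD; 2^(7−3): E=ABC, F=ABD, G=ACD; and
analogues); the achieved resolution is computed exactly by enumerating
the defining contrast subgroup, and resolution IV guarantees main
effects are unaliased with two-factor interactions.  The source study's
design software did not disclose its generators; minimum aberration is
the conventional default and satisfies the same resolution requirement.

Blocking assigns the 16 profiles to 4 equal blocks by seeded randomized
search (2,000 candidate partitions) scored by within-block level
balance.  Each candidate partition also fixes the within-block
presentation order, and candidates are screened by the smallest singular
value of the within-situation-centered design matrix (position dummies
plus attribute codes).  This screen matters: because every respondent
faces the same four fixed choice sets, a presentation order that makes
some ASC-plus-attribute contrast constant within every block leaves that
contrast unidentifiable from choices, no matter the sample size.  Among
identifiable candidates the most balanced one wins, with the larger
minimum singular value as tie-break; everything is reproducible from the
seed.

The opt-out is a flagged pseudo-alternative with no attribute codes.  It
never enters the design algebra, and — matching its treatment in the
analysis — the simulator generates opt-out answers as an exogenous
thinning event (a situation's recorded choice becomes the opt-out with a
small probability) rather than as a utility-bearing option.

The minimum sample size rule N > 500·c/(t·a) returns the smallest
integer exceeding the bound, except that an integer-valued bound is
returned as-is; this convention yields 250 at c=2, t=1, a=4.  The
off-by-one ambiguity of the strict inequality is real but immaterial at
survey scale.

## The G-MNL model and its normalizations

Utility is

    U_int = [ σ_n β + γ η_n + (1 − γ) σ_n η_n ]' x_int + asc_i σ_n + ε_int

* **γ is fixed**, at 0 by default (the usual restriction; the full form
  is coded so other fixed values remain available).
* **Scale normalization.**  σ_n = exp(σ̄ + τ ε0_n) with σ̄ = −τ²/2, so
  E[σ_n] = 1 and β keeps its MNL interpretation.  The location of σ̄ is
  not identified separately from the overall utility scale, and
  published fits often leave the convention implicit; the interpretation
  of τ̂ depends on it, so it is stated here prominently.
* **ASCs are scaled by σ_n** exactly like the attribute part-worths
  (i.e. the ASC dummies are part of the design vector the scale
  multiplies).  The first alternative position is the zero reference.
* **Taste heterogeneity** is independent normal per designated random
  attribute (diagonal Σ); only per-parameter SDs are reported by the
  source study, and nothing in the data would identify correlations of
  a 3-dimensional Σ from four choice situations with any reliability.
* **Nonnegativity.**  σ_η and τ enter the likelihood only through
  sign-symmetric functions, so the unconstrained parameters are
  estimated freely and reported as absolute values; estimates below
  1e−3 are flagged as boundary values.

## Maximum simulated likelihood

Per-respondent choice-sequence probabilities are averaged over D draws
(default 500) of (η, ε0).  Draws are Halton by default: distinct prime
bases per dimension, first 100 points discarded, mapped through the
standard normal quantile, with consecutive blocks of the sequence
allocated to consecutive respondents; a seeded pseudo-random scheme is
available.  All mixing over draws and products over situations are
computed in log space with max-subtraction, so utilities of any
magnitude are safe.

The simulated log-likelihood is maximized by L-BFGS-B with an analytic
gradient (the draw-weighted conditional-logit score; weights are the
softmax of per-draw log path probabilities across draws).  Starting
values are the conditional-logit estimates with small positive
heterogeneity (0.1); when D > 200 a pilot fit with 100 draws refines the
start first — a standard warm-start that roughly halves the expensive
large-D iterations without changing the optimum.  Convergence is
declared at the optimizer's default criteria (ftol 1e−11, gtol 1e−5);
one perturbed restart is attempted before an error carrying the best
iterate is raised.  Same-seed refits are bit-reproducible.

Standard errors come from the central finite-difference Hessian of the
simulated log-likelihood (step 1e−4, draws held fixed, so the surface is
smooth); a non-positive-definite information matrix triggers a warning
and a pseudo-inverse.

Two numerically identical implementations exist: a vectorized numpy
path (the reference) and fused numba kernels that avoid materializing
rows × draws arrays; the kernels are used when numba is importable and
are asserted equal to the reference in the tests.

## Baseline MNL and the IIA test

The conditional logit is fitted by Newton iterations on the analytic
gradient and Hessian (the log-likelihood is globally concave; step
halving guards the line search; runaway coefficients raise a separation
diagnostic naming the offending attribute).  The null model for
McFadden's ρ² = 1 − LL/LL₀ is the ASC-only fit, not equal shares: the
study's printed null log-likelihoods (−1864.1 for 1,473 situations) are
far above −N·ln 4 ≈ −2042, which identifies the ASC-only convention.

The Hausman–McFadden test refits after dropping one alternative
(removing situations where it was chosen and its rows elsewhere) and
forms (b_r − b_f)' (V_r − V_f)⁺ (b_r − b_f) on the common coefficients.
The covariance contrast is projected onto its positive eigenspace
(eigenvalues above a relative tolerance), the degrees of freedom are the
retained rank, and negative eigenvalues — common in finite samples — are
flagged rather than fatal; the statistic is therefore always
nonnegative.  Size calibration is verified by simulation: under an
IIA-satisfying generating process on a design where both the full and
restricted fits are identified (four attributes, four blocks), the
rejection rate at α = 0.05 over 500 replicates of 300 respondents sits
within Monte-Carlo error of the nominal level, and power against strong
scale heterogeneity (τ = 1) approaches 1.

## Ranking indices and descriptives

Indices are computed from the published rank *proportions* (as printed,
2 dp) with weights (4, 3, 2, 1) over ranks 1–4 and normalized to sum to
one.  Because the inputs are rounded, reproduction of printed indices is
asserted to ±0.015 (e.g. the manure row recomputes as 0.155 against a
printed 0.16).  Items structurally absent for one sex (dashes) are
excluded from that sex's denominator.  Flock descriptives divide
category means by the total-flock mean; the breeding ratio is
1 : round(ewes per ram).

The published odds-ratio table reproduces as exp(β) with Wald bounds
exp(β ± z·SE): all 13 odds ratios match to 2 dp, and confidence bounds
match to the printed precision once the 3-dp rounding of the published
coefficients and SEs is allowed for (a ±0.015 band; four upper bounds
differ in the last printed digit for exactly this reason).

## Synthetic data: what it does and does not emulate

The generator draws η_n and σ_n per respondent, adds standard Gumbel
noise, and records the argmax among designed alternatives, with opt-out
thinning as above; every respondent answers all four blocks.  With the
heterogeneity switched off it is exactly the MNL data-generating
process, which the tests exploit (simulated frequencies vs closed-form
probabilities, estimator collapse).  It does **not** emulate: learning
or fatigue across choice situations, attribute non-attendance,
socio-demographic taste shifters (the source study found none
significant), correlated taste deviations, or panel rotation of blocks
across respondents.  Passing recovery tests therefore demonstrates
correctness of the estimator under its own assumptions, not robustness
of the original survey results to violations of those assumptions.

## Problem sizes and numerical defaults

Recovery of the ewe-model truth (the stronger test: τ = 0.7565) uses
2,000 synthetic respondents and D = 500 Halton draws and checks every
mean part-worth, taste SD and τ against the truth at 3 reported SEs; the
MNL-truth shrinkage check uses 600 respondents and D = 100.  The IIA
size simulation uses 500 replicates of 300 respondents.  Smoke and
property tests use 60–400 respondents with 5–100 draws.  Default
tolerances: optimizer gradient norm 1e−5 (MNL 1e−6), finite-difference
step 1e−4, boundary flag 1e−3, orthogonality and resolution checks are
exact integer arithmetic.

## Known limitations

* Only two-level attributes; no D-efficient (non-regular) designs; the
  generator table covers the standard k ≤ 9 cases used here.
* γ is fixed, not estimated; no willingness-to-pay transform (the study
  has no price attribute); no correlated Σ, latent classes, or Bayesian
  estimation.
* The Hausman–McFadden statistic's positive-part projection is one of
  several conventions for indefinite covariance contrasts; with very
  weak designs the test degrades gracefully (conservative) rather than
  failing loudly.
* Simulated-likelihood estimates carry O(1/√D) simulation noise; at the
  default D = 500 this is visible as a small common shift across
  correlated coefficients in any single replication.
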