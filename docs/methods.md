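# Methods

This note documents the modelling and numerical choices behind `baclopk`,
in the spirit of a statistical appendix: what is computed, under which
assumptions, and what the synthetic-data experiments do and do not show.

## Structural and statistical model

One-compartment disposition with first-order oral absorption and first-order
elimination; all parameters are apparent oral quantities (CL/F in L/h, Vd/F
in L, Ka in 1/h) because bioavailability is not estimable from oral data
alone. Computation is carried out in mg and litres (mg/L), converted by the
fixed factor 1000 to the assay unit ng/mL only at the I/O boundary; times
are hours from each subject's first recorded dose.

Multiple dosing is represented by an explicit dosing history over a 72-h
run-in plus the sampling day, summed by superposition, rather than by a
steady-state closed form. At the reference half-life (≈ 4.4 h) 72 h exceeds
16 half-lives, so residual non-stationarity of the troughs is below 1%
(asserted by a test). The removable singularity at Ka = k switches to the
series limit C = D·k·t/V·e^(−kt) within a relative band of 1e−8, keeping the
model continuous in all parameters without catastrophic cancellation; no lag
time is modelled and Ka > k is not enforced.

Between-subject variability is log-normal per parameter with diagonal Ω
(no CL–V correlation; the analysis this package reproduces reports only
diagonal terms). The residual model is exponential, y = f·e^ε. All
likelihood computation therefore works on log-concentrations, where the
residual variance no longer depends on the random effects — the FOCE
"interaction" is exact rather than linearised.

## Likelihood approximation and optimisation

Per subject the marginal likelihood is approximated by a Laplace expansion
around the conditional mode η̂ (the empirical Bayes estimate) with a
Gauss–Newton Hessian:

    OFV_i = n_i·log(2πσ²) + SSR_i/σ² + η̂'Ω⁻¹η̂ + log det(I + Ω·J'J/σ²)

where J is the Jacobian of log-predictions with respect to η at the mode,
available in closed form (including the Ka = k limits; verified against
finite differences and symbolic algebra). The constant convention — the
n·log 2π term is included, and the Jacobian of the log-data transform is
dropped — is fixed, so absolute OFV differs from other implementations by a
data-dependent constant while OFV differences, the only quantities used for
selection, are implementation-independent. On any model linear in η with
Gaussian error the approximation is exact; the test suite exploits this with
closed-form oracles.

The inner problem is solved by damped Gauss–Newton from η = 0, stopping at a
gradient sup-norm of 1e−7 (the mode is then start-independent, which makes
warm starts across outer iterations safe). A numba-compiled per-subject loop
implements the identical algorithm as the vectorised numpy path; their OFVs
agree to ~1e−13 and the numpy path remains the reference implementation.
The outer problem optimises log(θ), log(ω²), log(σ²) — positivity by
construction — with L-BFGS-B, a forward-difference gradient with step 1e−6
(three orders of magnitude above the inner-optimisation noise), and one
polishing restart, which resets the quasi-Newton curvature and reliably
escapes the flat ridges of the Laplace objective near convergence.
Tolerances: relative objective change 1e−9 (1e−7 in the "fast" profile used
for bootstrap/search refits, where the ≤ 0.1% parameter error is negligible
against resampling noise).

Observations below the 5 ng/mL quantification limit are excluded from the
likelihood and counted in the run record. At the generating parameters BLQ
samples are rare (< 10% of scheduled draws; trough concentrations at the
lowest dose group sit in the tens of ng/mL), so the choice of BLQ method has
no leverage here.

Standard errors come from a central finite-difference Hessian of OFV/2 in
the log-parameter space; the square roots of the inverse-Hessian diagonal
are then directly relative SEs (RSE% of θ; halved for ω and σ, which are
reported on the SD scale). A non-positive-definite Hessian is reported with
eigenvalue diagnostics instead of silent output. η-shrinkage is
1 − SD(η̂)/ω (sample SD), clipped to [0, 1]; the variance-ratio form is
available as an option, and comparisons with published shrinkage values are
qualitative only since the reporting convention there is not stated.

## Covariate machinery

Continuous covariates act as powers of the median-centred value (the median
of the analysis dataset, recomputed per dataset); binary covariates as a
multiplier on the indicator level (optimised as its logarithm, hence
positive by construction); the 4-level dose-group covariate as one
multiplier per non-reference level (reference = largest group, ties to the
lowest label; 3 df, backward threshold 16.3). Categorical levels under 10%
prevalence are pooled into their ordinal neighbour before testing; a
covariate that collapses to one level is dropped with a log entry.

Selection is greedy best-first forward inclusion (all candidates tested
against the current model, largest significant OFV drop added, repeat) at
χ²(df, 0.05) — 3.84 for 1 df, 7.81 for the 3-df group candidate — followed
by backward elimination at χ²(df, 0.001). Thresholds are reported rounded
to three significant figures (3.84, 10.8, 16.3), matching the printed
values, and the rounded values are what the comparisons use. The screened
parameter–covariate pairs default to: every collected covariate on CL;
size/composition covariates (WT, BMI, LBM, sex) additionally on V; dosing
covariates (intakes/day, daily dose) additionally on Ka — physiological
plausibility bounds what would otherwise be a combinatorial space.
BMI = WT/HT² and lean body mass by the James equations are computed by the
package (the source analysis does not print its formulas; the choice is
recorded in the output metadata).

## Diagnostics

*NPDE*: per subject, observed and simulated vectors are decorrelated with
the inverse Cholesky factor of the empirical simulated covariance; the
mid-rank of the decorrelated observation among its K simulations, clipped to
[1/(2K), 1 − 1/(2K)], maps through the standard-normal quantile. A singular
covariance falls back to marginal standardisation with a flag.

*pcVPC*: binning on time-after-most-recent-dose with edges
{0,1,2,3,4,6,8,12,24} h (matching the sampling windows); bins with fewer
than 5 observations merge into a neighbour. Observations and simulations
are rescaled by bin-median population prediction; 5/50/95th percentiles are
compared with 95% bands from the across-replicate percentile distribution.
K = 500 replicates by default, overridable for desk-scale checks.

*Bootstrap*: subjects resampled with replacement within dose group
(preserving the 10/15/16/16 design; plain resampling if no group column),
each replicate refitted from the original estimates; percentile 2.5/97.5
CIs from converged replicates; > 20% non-convergence flags the result.
B = 200 by default (the source analysis does not print its B), B ≥ 50
accepted.

## The virtual trial

The generator reproduces the study design: 57 completers in four daily-dose
groups of 10/15/16/16 subjects (<60, 60–120, >120–180, >180 mg/day); group
dose, age, sex and intakes/day drawn from the published group summaries
(truncated normals within the printed min/max; doses rounded to 10 mg and
re-drawn if rounding crosses a group boundary); equal dose splitting per
intake in 10-mg units with the remainder on the first intake; identical
daily schedules with intakes spread evenly over 24 h. Schedules must keep
≥ 4 h between consecutive intakes — the protocol's sampling constraint — so
drawn intake counts whose even spread would violate it (> 6/day) are
redrawn; realised intake counts therefore top out at 6 rather than the
nominal 8, a deliberate resolution in favour of the hard 4-h invariant.

Sampling follows the protocol windows around two consecutive intakes on the
sampling day: pre-dose, 0–1, 1–2, 2–3 h and the late window (two samples
when it is ≥ 2 h wide, one otherwise) after the primary intake; pre-dose,
0–1 and 1–2 h after the secondary intake; plus a next-morning pre-dose
trough — 9 or 10 samples per subject, 513–570 scheduled observations per
57-subject study, bracketing the 522 analysed in the real trial. An optional
per-sample missingness rate (default 0) exists rather than a guess at how
the realised count arose.

Weight, height, creatinine and the liver markers are not tabulated in the
source; defaults are documented, configurable distributions (WT ~
N(75, 15²) kg truncated [45, 130], HT ~ N(170, 10²) cm [150, 200], CREA ~
N(0.9, 0.2²) mg/dL [0.5, 1.6], males shifted +5 kg/+8 cm/+0.1 mg/dL; PT,
bilirubin, AST, ALT from plausible clinical ranges). Creatinine clearance is
recomputed by Cockcroft–Gault and subjects are redrawn while CRCL ≤ 30
mL/min (the exclusion criterion). Because the source analysis found no
covariate effect, these distributions only need to exercise the screen, not
match unpublished marginals — which is also what limits the external meaning
of the covariate-null experiment: it shows the selection machinery is
calibrated under the design, not that no covariate could matter in other
populations. All randomness flows from one master seed through SeedSequence
spawning (one stream for covariates, then four per subject), so a subject's
data do not depend on how many draws earlier subjects consumed.

The generator's truth record (η, ε, noise-free concentrations) makes every
simulated value exactly reconstructable, which the tests use for
cross-module consistency.

## Scale of the test experiments

The acceptance-style experiments state their sizes explicitly as the
package's chosen desk scale: parameter recovery and the covariate-null check
use 20 replicate 57-subject trials (median estimates compared against the
published bootstrap intervals); NPDE calibration uses 100 replicate
15-subject studies at K = 120 plus one full-scale check at K = 500; pcVPC
uses K = 200; bootstrap qualification uses B = 50 with 20 outer replicates
of 24-subject trials for coverage (≥ 85% accepted against the nominal 95%,
reflecting the small-sample undercoverage of percentile intervals) plus a
full-scale containment check. Passing these shows the pipeline is internally
calibrated under the study's design and the published parameter regime; it
does not validate the model against real baclofen data, which are not
distributed with the package.

## Known limitations

No inter-occasion variability, no Ω off-diagonals, no absorption lag, no
mixture models, and no enantiomer-specific kinetics (the racemate is one
analyte). The bootstrap refits use the original estimates as starting
values, which is standard but can understate non-convergence on pathological
resamples. NPDE decorrelation uses the empirical simulated covariance, so K
should comfortably exceed the largest per-subject observation count
(K ≥ 100 recommended). The M1 (exclude-BLQ) likelihood is adequate here
because censoring is rare at the study's dose range; analyses near the
quantification limit would need a censored-likelihood method.
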