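# Methods

This note records the models, the numerical and design choices, and the
limits of what the synthetic cohorts can demonstrate.

## Mass-balance model

Daily amino-acid losses of a dialysis patient are the week-averaged
dialytic removal plus the 24-h urinary excretion:
`(V_dialysate · D_x · n)/7 + UE_x`, with `V_dialysate` the total spent
dialysate volume (L) collected in a tank, `D_x` the pooled-dialysate
concentration (µmol/L), `n ∈ {2, 3}` sessions/week, and
`UE_x = V_urine · U_x` (µmol/24 h, two collections averaged upstream).
Controls lose only via urine. Units are fixed by contract — L, hours, kg,
µmol/L for amino acids, mmol/L (or mmol/24 h) for urea, g/24 h for urinary
protein — and never inferred, because a silent µmol/mmol mix-up is a
1000-fold error. Subjects with a residual diuresis ≤ 0.2 L/24 h carry no
urine collection; all their urinary terms are zero.

Gram conversion uses average molecular masses of the free (non-residue)
molecules (e.g. glycine 75.07, taurine 125.15 g/mol). The residue-mass
convention would understate every species by one water; free-molecule
masses reproduce the cohort-level gram totals implied by the µmol sums
(weighted mean ≈ 125 g/mol), and free amino acids — not peptide residues —
are what the dialysate assay measures.

Group sums are closed by construction: BCAA (leucine, isoleucine, valine)
is a subset of the 9 essential species; essential (9) + non-essential (12)
= total (21). Cysteine (unstable) and aspartic acid (below detection) are
registry entries flagged unreported; requesting them is an explicit error,
never a silent zero, as is any missing panel concentration (an
`impute_zero` opt-in exists for deliberately sparse panels).

## Kinetics

* **Kt/V** (single-pool Daugirdas): `−ln(R − 0.008·t) + (4 − 3.5R)·UF/W`.
  Valid for `R ∈ (0, 1]` with `R > 0.008·t`; outside that domain the
  function raises rather than returning a complex or negative-log value.
  The inverse (urea ratio from a target Kt/V) is solved by bisection to
  1e-12, which the generator uses so that simulated urea ratios and Kt/V
  targets are mutually consistent (round-trip error < 1e-6).
* **Protein intake** (Maroni): `6.25·(0.028·G + 0.031·BW) + UPE` g/24 h,
  where `G` is total urea appearance in mmol/24 h — dialytic
  (`V·Du·n/7`) plus urinary for patients, urinary alone for controls.
  Also returned per kg of post-dialysis weight.
* **Dialytic clearance**: `((V·D_x)/T) / ((P_pre + P_post)/2) · 1000/60`
  mL/min; undefined (None, not zero) when mean plasma is zero. Fractional
  clearance divides by the same patient's dialytic creatinine clearance.

## Cohort statistics

Summaries are mean ± SD for approximately normal variables and
median (Q1; Q3) otherwise. The original analysis judged normality by
inspecting histograms and Q–Q plots, which is not reproducible by code; the
default rule here is Shapiro–Wilk at α = 0.05, and the display form of each
panel analyte is pinned by a preset (plasma: tryptophan, citrulline,
glutamic acid, proline, taurine as median rows; losses: lysine,
phenylalanine, threonine, valine, citrulline, serine, taurine) so table
layout does not depend on a re-derived test. Zero-variance vectors get a
`skewed-degenerate` flag.

Two-group dispatch: pooled-variance t-test (normal), Wilcoxon rank-sum
(skewed; exact null for tie-free samples up to n = 25, otherwise normal
approximation with continuity correction and mid-ranks), chi-squared
without Yates correction (nominal; correction configurable). Paired
dispatch: paired t or signed-rank on the differences; all-zero differences
return statistic 0, p = 1 by convention. Which exact variants produced the
published p-values is unknowable, so p-values are compared only
behaviorally (rank tests agree with exhaustive permutation/sign-flip
enumeration in the test suite), never against printed values.

Derived columns use half-away-from-zero rounding: proportional difference
`(HD − control)/control · 100` to integer percent; HD:control ratio to one
decimal below 2 and to an integer above (the convention recovered from the
published ratio column, where 1.2 and 0.4 coexist with 67 and 450);
intradialytic proportional change `Δ/pre · 100` to integer percent.
Column-mean absolute changes need not equal differences of column means
(pairwise computation); the tables compute both self-consistently.

## Association models

Severe fatigue is a CIS subjective-fatigue score ≥ 35. Predictors enter
logistic models per SD increment (identity path; SD is the sample SD of
the analysis set after any exclusions, recomputed per sensitivity rule) or
per log2 doubling for right-skewed analytes (preset: plasma taurine;
taurine and tryptophan losses). Model 1 adjusts for age, sex, BMI, and
dialysis vintage; model 2 adds hemoglobin, C-reactive protein,
cardiovascular disease, and diabetes. Fitting is maximum likelihood via
IRLS (statsmodels GLM, tolerance 1e-8, max 100 iterations); Wald 95%
intervals (profile likelihood was considered and rejected as the default
because the published intervals' method is unstated and Wald is the common
default); non-convergence, constant outcomes, or separation yield a
flagged result with no estimate. The largest variance inflation factor of
each design is reported. Analyses are complete-case throughout.

Sensitivity rules: (1) drop predictor |z| > 2 outliers; (2) drop
twice-weekly patients; (3) drop vintage > 60 months; (4) drop
BMI < 18.5 kg/m²; (5) drop hemoglobin below the within-sex 5th percentile
of the analysis cohort itself (no external reference population is
assumed). A rule that empties the data returns a documented skip.

Determinants of total losses use OLS on z-scored outcome and predictors
(standardized betas; univariable beta ≡ Pearson r), univariable screening
at p < 0.05, then one joint fit. Probability curves are the inverse logit
of the fitted linear predictor along a grid with covariates held at their
analysis-set means.

## Synthetic cohort generator

The generator's defaults are the study conditions: 59 patients, 33
controls; dialysate volume ~ N(135, 27) L; 95% thrice-weekly; session
length 4 h for 81% (3.5/3 h otherwise); UF ~ N(1.9, 0.9) L; Kt/V target
~ N(1.4, 0.3); residual-diuresis prevalence 0.54 with volume
~ N(0.9, 0.6) L truncated > 0.2; intake targets N-equivalent lognormals
with mean 64 ± 21 (patients) and 84 ± 21 g/24 h (controls).

Every concentration and daily-loss quantity is log-normal (non-negative,
covers both symmetric and heavy-tailed published summaries), moment-matched
to the printed mean ± SD or median (Q1; Q3) per analyte, with an
exchangeable latent correlation ρ = 0.3 within each compartment.
Consequently a mean-parameterized analyte matches its target mean and a
median-parameterized one its target median (within 5% relative at
n = 10⁴, verified in tests); the remaining central value (e.g. the mean of
the very skewed taurine-loss distribution) is implied, not pinned.

Internal consistency is obtained by back-solving machine-side quantities
from sampled targets rather than sampling them independently: dialysate
amino-acid concentrations from the per-analyte daily-loss targets (minus a
control-like urinary component scaled by relative urine volume, capped at
90% of the total so the dialytic part stays positive); dialysate urea from
the Maroni intake target; the urea ratio from the Kt/V target via
Daugirdas inversion; dialysate creatinine from a clearance target
N(137, 68) mL/min. Post-dialysis plasma is predialysis times
(1 + δ_x + ε), with δ_x the published mean proportional change per analyte
and ε ~ N(0, 0.10). Per-analyte loss totals are additionally scaled by
(Kt/V / 1.4)^0.5, a mild positive coupling of losses to dialysis dose that
lets the determinant analysis find the dose effect without materially
moving the marginal targets.

Severe fatigue follows
`logit P = α + β_tau (log2 tau_loss − m) + β_pro z(proline) + β_prot z(intake)`
with the published fully adjusted effect sizes as defaults (ORs 0.64 per
doubling, 2.97 per SD, 0.18 per SD) and α calibrated by solving
`E[expit(α + η)] = 20/59` over a fixed internal Monte-Carlo sample (the
source reports both "20 patients" and "38%", which are inconsistent for
n = 59; the count is targeted). z-scores use the theoretical moments of
the generating distributions, so recovery tests compare like with like.

What the generator does **not** emulate: within-patient longitudinal
structure, realistic between-analyte correlation structure beyond
exchangeability, mechanistic dialyzer transport (per-analyte clearances are
implied by the loss targets and do not match published per-analyte
clearances, e.g. taurine's low clearance), measurement error models, or
missingness. Passing tests therefore demonstrate correctness of the
computational pipeline and recoverability of effects under the stated
statistical structure — not clinical validity on real data.

## Problem sizes and tolerances

Distribution-level checks use n = 10⁴ patients (central values within 5%
of targets; loss-total calibration within 15% of the published 4.0 g/24 h
and 6.7%-of-intake means, a deliberate calibration margin since the
simulated cohort equals the real one only in its configured summaries).
Parameter recovery uses 20 cohorts of n = 2000 (mean recovered log-OR
within 5% of truth); Wald-CI null coverage uses 500 replicates of n = 600
(93–97% band). Formula oracles are 1000 random draws at 1e-9 relative
tolerance; closure identities hold to machine precision. Exact rank tests
are enumerated up to n = 8 (2⁸ sign flips, C(6,3) permutations).
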