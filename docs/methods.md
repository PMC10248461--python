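# Methods

This note documents the statistical procedures `tmbcut` implements, the
assumptions behind them, the synthetic-data model used to test them, and
the numerical and design choices that were genuinely open.

## The three-step procedure

### Step 1 — cancer-type-level cutoff scan

For a candidate universal cutoff *c* (mut/Mb), each cancer type *t*
contributes a point (`p_high_t(c)`, `ORR_t`): the fraction of the type's
cohort with TMB ≥ *c* (boundary inclusive) and the pooled objective
response rate to anti-PD-(L)1 monotherapy. Types enter only with at least
30 cohort cases and at least 10 trial participants. A weighted
least-squares regression of ORR on `p_high` with weights
`w_t = sqrt(n_cohort,t · n_trial,t)` (the geometric mean of the two sample
sizes) yields `R(c) = sign(slope) · sqrt(R²)`; for a single regressor this
equals the weighted Pearson correlation, which the test suite verifies
against an independently coded closed form. The 95% CI uses the Fisher
z-transform with *n* = number of cancer types; correlation CIs of this
kind are conventionally reported without a named method, and Fisher z is
the standard choice. If `p_high` has zero variance across
types (e.g. cutoff 0, where every proportion is 1) the slope is
unidentified and R is reported as 0 with a degenerate flag.

The curve R(*c*) over the cutoff grid is then searched for a structural
break with the Chow test: at each candidate split leaving at least
`min_segment = 3` points per side, OLS lines (k = 2 parameters) are fitted
to the left segment, right segment and pooled data, and

    F = ((SSR_pooled − SSR_left − SSR_right) / k) / ((SSR_left + SSR_right) / (n − 2k))

The candidate maximising F is the breakpoint; ties break toward the
smaller cutoff, a split with zero combined segment SSR keeps infinite F
(flagged), and the p-value from F(k, n−2k) at the maximising split is
descriptive only — no correction for scanning, since the F maximum is used
as a knee detector, not a hypothesis test. An exact-fit tolerance
(1e−12 · n · max|y|²) distinguishes true zero SSR from least-squares float
dust. The implementation is checked against exhaustive brute-force SSR
enumeration on instances up to 30 points at 1e−10 relative tolerance.

### Step 2 — patient-level survival verification

TMB-high status under a cutoff policy (universal *c*, or a per-cancer
quantile — default the 80th percentile, by linear interpolation between
order statistics) enters a Cox proportional-hazards model for overall
survival adjusted for age (continuous) and sex, panel version and cancer
type (dummy-coded, reference = most frequent level; constant columns are
dropped). Missing covariates are handled by complete-case analysis. The
model reports the hazard ratio with Wald CI and Z, and Harrell's C-index.
Preconditions: at least two events in each TMB stratum; non-convergence is
fatal with diagnostics (except inside the scan, below).

The Wald-Z scan refits this model at each grid cutoff, storing Z as
estimated (a protective TMB-high effect gives negative Z; plots may flip
the sign for display). Cutoffs leaving fewer than two events in a stratum,
or at which the partial-likelihood fit does not converge (near-degenerate
strata at extreme cutoffs), are dropped with a warning. The Chow test then
locates the breakpoint of the surviving Z curve — the same code path as
Step 1.

Policy comparisons: (a) C-indices of the universal and percentile models
are compared by a paired patient-level bootstrap — both models are fitted
once, their linear predictors held fixed, patients resampled with
replacement, and the two-sided p taken from the bootstrap distribution of
the C-index difference (refitting inside the bootstrap would test a
different, much more expensive question; holding scores fixed is the
standard compromise); (b) effect homogeneity across cancer types is tested
by a likelihood-ratio test of TMB×cancer-type product terms, chosen over a
Wald test for stability with sparse strata; (c) per-cancer subgroup models
retain age/sex/panel-version and flag strata inestimable when a TMB
stratum has fewer than two events — e.g. a type whose few TMB-high
patients are all alive at last follow-up; (d) a sensitivity analysis
reruns the main fit on microsatellite-stable cases only.

### Step 3 — in-silico panel concordance

A random panel of `size` genes with shared fraction `s` against the
reference contains exactly `k = round(size · s)` reference genes (rounding
half away from zero, so grids are reproducible) drawn uniformly without
replacement, plus `size − k` from the rest of the universe. Its territory
is the summed callable length of its members — TMB denominators are
panel-specific, as in reality. Panel TMB always routes through one code
path (`tmb_from_counts` on a pipeline-filtered count matrix), so a panel
equal to the reference yields κ = 1 exactly.

Cohen's κ = (p_o − p_e)/(1 − p_e) uses the 2×2 table margins for chance
agreement; when p_e = 1 (all margins degenerate the same way) the value is
1 for identical vectors and 0 otherwise, by documented convention. Each
grid cell stores all replicate κ values and the fraction above 0.80;
replicate seeds derive deterministically from (seed, size, shared
fraction, replicate index), so any cell can be recomputed in isolation.
The whole-exome-vs-panel comparison uses a paired t-test on per-sample TMB
differences (zero-variance differences raise a structured error), and a
lower WES cutoff (default 8 vs 10 mut/Mb) is evaluated by the κ between
`WES ≥ 8` and `panel ≥ 10` labels.

Default pipeline filters approximate the three commercial panel vendors'
counting rules, which are proprietary: an MSK-style filter counts the five
nonsynonymous classes; an F1CDx-style filter adds silent mutations with a
configurable excluded-gene hotspot list (default empty); a PGDx-style
filter omits splice-site calls. All are config-overridable and explicitly
labelled approximations.

## The synthetic-data model

Analyses are exercised on generated data whose statistical structure
matches what the method assumes. Every generator is a pure function of
(config, seed); the planted truth is serialised beside each dataset and a
test asserts that no analysis module imports the generator.

**TMB per cancer type.** A two-component mixture: a fraction
`f_t ~ U(0.05, 0.30)` of tumors is *hypermutated* with
TMB = cutoff + Exp(4) mut/Mb, and the rest carry bulk TMB from
LogNormal(μ_t, 0.4) truncated below the true cutoff, with median
exp(μ_t) ~ U(4, 9.5). This makes the planted cutoff a genuine boundary of
clinico-biological impact: below it, between-type variation in bulk
survival decorrelates `p_high(c)` from the response signal; at and above
it, `p_high(c)` is proportional to `f_t` (the hypermutated tail has a
shared shape), so the R curve rises roughly linearly and then plateaus,
with its knee at the cutoff. A smooth shift mixture without the
threshold structure produces an almost rank-preserving family of
`p_high(c)` across cutoffs and hence a curve with no identifiable knee —
design-phase simulations recovered the planted cutoff in under 20% of
replicates under such a model, versus ≈97% for the present one. Samples in
the hypermutated component are labelled MSI-H with probability 0.35 (1%
in the bulk), giving the MSI-high tail its microsatellite correlate
without making the two categories synonymous, so the MSS-only sensitivity
analysis retains a real effect. The bulk medians (4–9.5 mut/Mb) are
deliberately high relative to unselected pan-cancer series; they place
bulk probability mass immediately below the threshold, which both mimics
heavily pretreated advanced-cancer cohorts and keeps the knee sharp.

**Response link.** Per type, ORR = 0.05 + 0.5·p_high(cutoff) + N(0, 0.03²),
clamped to [0, 1] with clamping logged; trial sizes are U(100, 600).

**Survival.** Exponential event times (Weibull behind a config switch)
with baseline hazard 0.06/month, multiplied by the planted HR 0.58 for
TMB ≥ cutoff. Censoring is independent of the event process: censor times
are Uniform(0, L) with the window L solved by bisection so the expected
censored fraction equals the configured 25%. (An earlier scheme that
censored a fixed fraction of subjects uniformly *before their own event*
was informative and biased the Cox HR toward the null by ≈0.15; the
acceptance coverage check is what exposed it.)

**Exome.** 2,000 genes with lognormal callable lengths (mean 2.5 kb), a
~5 Mb scaled-down exome. Per-gene rates are heavy-tailed gamma draws
scaled so the expected nonsynonymous WES TMB is 6.5 mut/Mb; a per-sample
lognormal factor (σ = 0.8, mean 1) creates between-tumor dispersion; the
400 genes designated the reference panel carry rates multiplied by 1.35 —
panels enrich for frequently mutated genes, which is why panel TMB runs
≈2 mut/Mb above whole-exome TMB here and why an 8 mut/Mb WES cutoff agrees
better with a 10 mut/Mb panel cutoff. Variant classes are multinomial per
mutation (58% missense, 18% silent, the rest split among truncating,
splice and in-frame classes, plus a small untranslated-region share that
exercises the unknown-class fallback).

**What passing tests do and do not show.** The generator emulates the
*structure* the analysis assumes — heavy-tailed per-type TMB with a
hypermutated/MSI-H component, a linear ORR link, proportional hazards, and
panel-gene enrichment. It does not emulate inter-gene mutational
signatures, panel-specific artifacts, correlated trial heterogeneity,
non-proportional hazards or cohort selection effects; recovery of planted
truths therefore validates the inference machinery, not the biological
claim on any real cohort.

## Numerical choices and problem sizes

- Default scan grids: 1–20 mut/Mb (Step 1) and 1–15 mut/Mb (Step 2), in
  unit steps. Beyond these ranges the TMB-high strata of realistic cohorts
  hold only a few percent of samples, the statistic curves are dominated
  by sampling noise, and design-phase simulations showed the Chow split
  systematically displaced by the noisy far tail. Both grids are
  arguments everywhere.
- Gene symbols are matched case-sensitively after whitespace stripping; no
  alias resolution (a documented limitation). Unknown MAF
  variant-classification strings map to `other`, never counted, with a
  mapping-audit warning.
- One sample per patient: primary > metastatic > additional metastatic,
  ties broken by smallest sample id — deterministic and idempotent.
- TMB-high is boundary-inclusive (≥) everywhere.
- The tested study sizes — 25 types × 500 samples for the scan, 8 types ×
  250 patients (n = 2,000) for survival, 500-sample exomes, 50–200 panel
  resamples per grid cell — were chosen so the full suite and the
  acceptance script run comfortably on a single CPU; all are config
  parameters, and the resampling default for production use is 1,000.

## Known limitations

- The Chow split reports the first grid point of the right-hand segment;
  on a rounded knee the argmax can land one grid step to either side of
  the true break, which is why recovery guarantees are stated within ±1
  step. Chaining Step 1's estimated breakpoint into Step 2 therefore
  occasionally evaluates the Cox model one step below the true threshold,
  diluting the hazard ratio; the Step-2 report also includes the fit at
  its own recovered breakpoint.
- The C-index comparison holds model scores fixed during the bootstrap;
  it does not propagate refitting variability.
- Commercial panel counting rules and territories are approximations
  supplied via configuration, not vendor-validated values.
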