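# Methods

## Prediction equations and unit conventions

Every registered equation is a linear combination of predictor expressions
drawn from {H²/R, H²/Z, H², H, W, AGE, SEX, R, X, Z}, with optional
post-processing. Two structural variants exist:

- a *hydration postscale* (Wabitsch): the linear combination estimates a
  total-body-water-like quantity and is divided by 0.732, the assumed water
  fraction of lean tissue in healthy adults;
- a *fat-mass form* (Horie): the combination estimates fat mass and the
  equation returns `weight − FM`. Horie's published FM expression contains
  a `+1·W` term, which algebraically cancels against the leading weight;
  it is stored verbatim rather than simplified, so the registry export
  matches the published coefficients. Its resistance coefficient cannot be
  sanity-checked against any printed worked value and is likewise kept
  verbatim.

The canonical internal height unit is **centimetres**. The two Deurenberg
equations were published with height in metres and a 10⁴ scale factor on
the impedance index; they are stored pre-converted
(`a·10⁴·H(m)²/Z ≡ a·H(cm)²/Z`, `b·H(m) ≡ (b/100)·H(cm)`) so there is a
single conversion point and no per-evaluation unit branching. For the
H²/R-family equations published without an explicit height unit
(Houtkooper, Suprasongsin, Lukaski, Sun, Kyle), cm is assumed — the only
reading consistent with the magnitude of the printed coefficients.

Sex is coded male = 1, female = 0 wherever it appears. The 1991 Deurenberg
equation branches on age: below 16.0 years (i.e. up to 15 completed years)
the child coefficient set applies, from 16.0 the adult set; the boundary is
evaluated on age as a real number, a convention this package fixes because
the source publications leave 15.x ages undefined.

Impedance obeys `Z = sqrt(R² + Xc²)`. A subject supplying only R and Xc
gets Z derived; a supplied Z that disagrees with the derived value by more
than 1 % triggers a warning and the supplied (measured) value wins —
measured data are respected, inconsistency is surfaced. Negative or
implausibly high (> 120 kg) FFM predictions are returned and flagged, never
clipped: the validation must see equation failures at full magnitude.

## Validation metrics

For subject *i* with prediction *p* and DXA criterion *d*, the relative
error is `e_i = 100·(p_i − d_i)/d_i` (%). With cutoff *c* (default 5 %,
alternative 2.5 %):

- accurate ⟺ −c ≤ e_i ≤ +c (the boundary counts as accurate; the
  published wording "within ±c %" does not fix the boundary, so the
  inclusive convention is adopted here),
- underestimate ⟺ e_i < −c, overestimate ⟺ e_i > +c,
- bias = mean(e_i) — the mean of per-subject percentage errors, not the
  percentage difference of means,
- RMSE = `sqrt(mean((p_i − d_i)²))` in kg, population denominator n,
- maximum negative/positive error = min/max of e_i.

The best-equation rule is lexicographic: (1) highest % accurate, (2)
smallest |girls − boys| accuracy gap, (3) smallest |bias|, (4) smallest
RMSE. The source criteria state the order but no tie tolerance; this
package uses windows of 2 percentage points at stages 1–2 and 0.5 bias
points at stage 3 (configurable), with the stable table order breaking any
residual exact tie. When a cohort contains a single sex, stage 2 is
skipped. Rendered tables round percentages and kg to one decimal; JSON
reports keep full precision.

Longitudinal agreement (`evaluate_change`) matches subjects by id across
two visits, differences the equation-predicted and DXA-measured FFM
changes, and runs a two-sided paired t-test. When the per-subject
differences have zero variance the t statistic is undefined: the result is
flagged `zero_variance_differences` with p = 1 when all differences are
exactly zero and p = 0 for a constant non-zero difference.

## Equation development

`forward_select` is greedy on explained variance: at each step the
candidate maximising R² joins the model; selection stops when the best
remaining improvement is below ΔR² = 0.01 (configurable). Coefficient
p-values are reported but never drive selection. SEE is
`sqrt(SSE/(n − p − 1))` with p slope terms, and internal accuracy is the
±5 % metric applied to fitted values. Both H²/R and H²/Z are offered as
candidates; they are nearly collinear by construction, and an exactly
rank-deficient design raises a `CollinearityError` naming the terms rather
than silently dropping one. Subgroup stability refits the fixed term set
within girls/boys or within Tanner stage 1 vs ≥ 2 (the
pre-pubertal/pubertal split used in the cohort summary; the grouping name
`tanner_early_late` keeps the labels early/late), skipping groups with
n ≤ p + 2.

## Synthetic cohort generator

The generator emulates an obese-adolescent outpatient cohort at the level
of second moments, with the two-predictor equation as generative truth:

1. sex ~ Bernoulli(61/103 female); age ~ N(14.4, 1.7²) truncated to
   [11, 18] years;
2. height (cm) by sex — girls N(164, 6²), boys N(169, 12²); weight (kg)
   conditionally normal given height with marginal N(94.3, 15.7²),
   correlation 0.5, truncated above 40 kg;
3. the impedance index ZI = H²/Z (cm²/Ω) conditionally normal given
   weight with marginal N(55.2, 9.74²), correlation 0.78;
4. FFM = 0.527·ZI + 0.306·W − 1.862 + ε, ε ~ N(0, 2.85²) kg;
5. BIA fields derived physically: Z = H²/ZI, Xc ~ N(62.6, 7.7²) Ω,
   R = sqrt(Z² − Xc²); subjects violating Z > Xc ≥ 0 (or any truncation
   bound) are rejection-resampled wholesale, capped at 1000 draws each so
   the distributions stay near-normal;
6. Tanner stage: pre-pubertal (stage 1) below age 12.5 with a 0.15
   Bernoulli flip, otherwise a uniform pubertal stage 2–5 — enough
   structure to exercise subgroup code, with no claim to maturation
   physiology.

**Calibration.** The ZI moments (55.2, 9.74) and ZI–weight correlation
(0.78) are not observable summaries; they are moment-matched so the
generative model reproduces the targeted FFM distribution and explained
variances:

    Var(FFM) = 0.527²·9.74² + 0.306²·15.7²
             + 2·0.527·0.306·0.78·9.74·15.7 + 2.85² = 96.02   → sd 9.80 kg
    E[FFM]   = 0.527·55.2 + 0.306·94.3 − 1.862     = 56.08 kg
    R²(FFM ~ ZI)     = Cov(FFM, ZI)²/(Var ZI · Var FFM) = 0.821
    R²(FFM ~ ZI + W) = 1 − 2.85²/96.02                  = 0.915

These identities are re-verified numerically in the test suite. The
generator prioritises the regression structure over the raw electrical
moments: mean impedance *emerges* near 515–530 Ω (Jensen's inequality on
E[H²]·E[1/ZI]) rather than being forced to a target — a documented
approximation.

Follow-up visits add a per-subject FFM change ~ N(1.49, 2.72²) kg over six
months; weight moves by that change plus an independent fat-mass change
~ N(0, 2²) kg (an artifact assumption — fat change is not modelled), and
ZI is re-derived by inverting the generative equation on the new FFM with
a fresh residual, after which Z and R are recomputed (reactance carried
over). This keeps the cross-sectional regression structure valid at both
visits.

**What passing tests do and do not show.** The simulated cohorts share only
moments, one correlation structure, and an exactly linear FFM model with
Gaussian residuals. Real BIA data have skewed residuals,
population-specific hydration, device effects and measurement error in the
DXA criterion, none of which are modelled. Recovery of the generative
coefficients therefore validates the *estimation machinery*, not the
clinical accuracy of any equation; equation rankings on synthetic cohorts
are dominated by which equation matches the generative structure and should
not be read as field performance. Relatedly, with Gaussian residuals of sd
2.85 kg around an FFM near 56 kg, roughly 67 % of predictions fall within
±5 % — an internal-accuracy figure materially above that is not
reproducible under this residual model.

## Numerical and interface choices

- OLS is delegated to statsmodels; rank deficiency is detected on the
  design matrix before fitting. Exact-arithmetic toys (noiseless linear
  cohorts) must recover coefficients to ~1e−9.
- All randomness flows through one `numpy` `default_rng` seeded from
  `CohortParams.seed`; identical parameters and seed give byte-identical
  CSV exports. Replicated-cohort studies derive per-replicate seeds by
  `SeedSequence.spawn`.
- Cohort CSVs are UTF-8, comma-separated, dot-decimal with the header
  `id,sex,age,height_cm,weight_kg,resistance_ohm,reactance_ohm,impedance_ohm,tanner,ffm_dxa_kg,bmi_sds`
  (order-insensitive on read). Rows breaching physical invariants are
  rejected with row-numbered, coded diagnostics; the accounting identity
  n_in = n_used + n_rejected always holds. The 11–18 y inclusion window is
  enforced only for cohorts flagged as study population, otherwise noted.
- Problem sizes in the test and acceptance runs: parameter recovery uses
  one n = 10 000 cohort; unbiasedness uses 200 replicates at the study
  size n = 103; change-agreement checks use n = 2 000. These sizes put
  Monte-Carlo error comfortably inside the assertion tolerances.

## Known limitations

- No Bland–Altman limits of agreement, concordance correlation or
  bootstrap intervals — deliberate non-goals.
- The registry covers equations applicable to a mixed-sex 50 kHz
  hand-to-foot protocol; single-sex, elderly-only and non-50 kHz equations
  are out of scope.
- BMI-SDS is accepted as a precomputed input column only; no growth
  reference is bundled.
- The new-equation development path reproduces structure recovery on
  simulated data; external validation on real cohorts is explicitly out of
  scope.
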