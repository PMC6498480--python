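# Methods

## Measurement-error model

Repeated readings of target-lesion diameters are modelled on the square-root
scale, jointly for the baseline and post-treatment phases:

    (√Y_ijk:b, √Y_ijk:p)ᵀ = μ + α_i + β_j + γ_ij + ε_(ij)k

with lesion effects α_i, reader effects β_j, lesion×reader interactions
γ_ij and residuals ε_(ij)k, each mean-zero bivariate normal with its own
2×2 covariance (Σ_α, Σ_β, Σ_γ, Σ_ε). The square root is used because the
millimetre-scale disagreement between readings grows with lesion size while
the √-scale disagreement is approximately homoscedastic; `recistvar.loa`
reproduces this diagnostically (raw/√/cube-root/log Bland–Altman limits,
with the exact difference-of-powers back-transformation
`D(m, L) = (m^(1/n) + L/2)^n − (m^(1/n) − L/2)^n` at mean `m`, which for
n = 2 collapses to `2√m·L`). The back-transformation assumes the two
transformed measurements straddle `m^(1/n)` symmetrically and applies the
identity to each limit separately; 1.96 (not a t quantile) defines the
limits.

Sessions are treated as exchangeable replicates within (lesion, reader,
phase) — the model has no session term. The patient level is deliberately
omitted: patient-to-patient variation is part of the lesion-to-lesion
variation and does not change the error components of interest. The
residual covariance Σ_ε is the intra-reader error (same reader re-measuring
the same lesion). The inter-reader error of a difference-style reassessment
is

    Σ_inter = Σ_β + Σ_γ + Σ_ε / 2,

reader and interaction effects changing wholesale plus half the
within-reader noise attributable to the averaging of the two sessions'
residuals in the reference reading.

### Trimming

Before fitting, 5% of records per phase (a configurable fraction) are
removed by largest |standardized residual| under the one-phase crossed
model: variance components estimated by moments, effects predicted by
shrinkage of the lesion/reader/cell means (an empirical-BLUP fit — adequate
for ranking outliers), residuals standardized by their SD. Gross errors such
as mis-identified lesion boundaries are orders of magnitude outside the
error distribution and reliably rank at the top. Trimming is a single pass
(not iterated). The removal unit is one measurement record; when a record is
trimmed, its partner record in the other phase is also dropped so the
bivariate fit sees complete pairs.

### Fitting

The Bayesian fit is a blocked Gibbs sampler: effects and the fixed means
have conjugate bivariate-normal full conditionals; each covariance component
has a conjugate inverse-Wishart update with prior IW(ν₀ = 3, 0.01·I) —
proper and diffuse on the √mm scale, where error SDs are O(0.05–0.15) and
lesion SDs O(1–2). Additive confounding between μ and the effect-block means
(and between interaction margins and the main effects) mixes poorly under
plain Gibbs; interweaving translation moves (generalized Gibbs: draw the
group-mean shift from its prior-induced Gaussian and transfer it to the
confounded block) restore mixing, bringing split-R̂ of all 14 scalar
parameters below 1.1 in a few hundred iterations. Defaults: 4 chains,
1,000 warmup + 1,000 retained draws each, seeded; R̂ > 1.1 attaches a
warning (non-fatal). Posterior medians can be collapsed to a point estimate
and any draw serialises to a one-row-per-draw CSV.

`method="moments"` provides a fast frequentist fallback: the crossed
two-way expected-mean-squares decomposition applied to 2×2 cross-product
matrices (within-cell scatter → Σ_ε; interaction contrast → Σ_γ;
lesion/reader margins → Σ_α, Σ_β), assuming a near-balanced design, with
eigenvalue clipping to keep estimates positive semi-definite. It doubles as
an independent oracle for the sampler in the tests. A caveat inherent to the
design, not the estimator: with J readers, between-reader mean squares carry
J − 1 degrees of freedom, so any estimate of Σ_β fluctuates like
χ²_{J−1}/(J−1) (for J = 6, a ±30% band around the truth holds only ~36% of
the time); the reader component should be read as order-of-magnitude
information unless many readers are available.

## Reassessment simulation

A hypothetical second reading of a lesion with first-reading sizes
(Y_b, Y_p) is

    (Y'_b, Y'_p) = ((√Y_b + ε_b)², (√Y_p + ε_p)²),

with (ε_b, ε_p) drawn from the intra- or inter-reader distribution. √-scale
values are clamped at 0 before squaring, so "measured below zero" becomes 0,
never a positive size. Errors are drawn independently across lesions, from
the long-axis model for solid lesions and the short-axis model for lymph
nodes (cross-lesion error correlation is not modelled).

Designation probabilities for a scenario (n_solid, n_lymph, single-lesion
baseline, percent change c, reader mode) are estimated from an artificial
set of 100 burdens sharing that composition and c: baseline sizes from the
empirical log-normal LN(3.55, 0.53²) truncated to the measurable range
(≥ 10 mm; short axis [10, 80] mm — the short-axis size distribution reuses
the long-axis shape as a documented, overridable default); per-lesion
changes c_x ~ N(c, v) with v = 0.17 (long axis) and 0.10 (short axis),
constrained so the burden-weighted mean Σc_x·Y_bx / ΣY_bx equals c exactly.
The constraint is enforced by a uniform shift of the drawn c_x; any change
pushed below −1 (a lesion cannot shrink past disappearance) is clamped
there and the discrepancy redistributed over the remaining lesions
(water-filling, exact in at most n passes). Each burden is perturbed once
and the estimates are

    p_response    = #{c' ≤ −0.30} / n_burdens,
    p_progression = #{c' ≥ +0.20} / n_burdens,

where c' is the second-assessment percent change; a perturbed baseline
burden of exactly 0 is redrawn (counted in the log; never observed at
realistic sizes). Repeating 100 times with error covariances drawn from the
posterior and taking medians gives one probability-table entry; the grid
spans single-lesion baselines 10–150 mm (long) / 10–80 mm (short) at 1 mm,
c ∈ [−1, 1] at 0.01, compositions up to 5 lesions with at most 2 lymph
nodes. Multi-lesion entries are indexed by composition only (burden size is
accounted for only through the lesion count — a known coarseness). Table
lookup rounds c to the table's grid and clamps it to [−1, 1] (changes beyond
+100% are progression with probability ≈ 1, so the clamp is benign); single-
lesion baselines snap to the nearest grid point with a warning outside the
range.

## Trial evaluation

For each evaluable patient, a reassessment designates response (and,
independently, progression) as a Bernoulli event at the tabulated
probability; definitive-progression patients (unequivocal radiologic or
symptomatic progression, death) contribute progression = 1, response = 0,
and are included in both denominators. One repetition's rates are the event
proportions; 1,000 repetitions give the simulated rate distribution — the
Poisson-binomial law of the per-patient probabilities — summarised by its
median and 95% central range (2.5th/97.5th percentiles, linear interpolation
between order statistics). Response and progression events are drawn
independently within a repetition; this affects only joint summaries, not
either marginal rate.

Two coverage validations are provided: (1) per-burden 95% central ranges of
simulated second readings versus actual (or synthetically generated) second
readings, pooled over phases; (2) over bootstrap resamples of patients
(definitive count held fixed), coverage of the first-reading ORR central
range over the second-reading observed ORR of the same resample. The
simulation-study runner generates 50-patient single-lesion trials over
configurable baseline sizes and percent-change distributions, reporting the
observed ORR with a Clopper–Pearson exact 95% CI (avoids boundary
pathologies at 0/100%) next to the reassessed median and central range.

## Synthetic ground truth

`generate_readings` builds √-scale readings additively from known components
and squares them (values floored at 0.1 on the √ scale so every reading
stays a positive measurement); the default shape is 249 lesions × 6 readers
× 2 sessions × 2 phases. The default true components (√mm scale) are, per
axis:

| component   | long axis SD (b, p) | short axis SD | b–p correlation |
|-------------|--------------------|---------------|-----------------|
| lesion α    | 1.5, 1.5           | 1.0, 1.0      | 0.9             |
| reader β    | 0.05, 0.05         | 0.04, 0.04    | 0.7             |
| interaction γ | 0.08, 0.08       | 0.06, 0.06    | 0.5             |
| residual ε  | 0.12, 0.12         | 0.10, 0.10    | 0.5             |

with μ = (5.9, 5.4) long / (4.0, 3.7) short. These were chosen once for
realism: a single re-measurement then shifts a 30 mm burden by under ~10%
(intra) and about ±10% at the 95% level (inter), matching the reported
magnitude of radiologic re-measurement variability, while lesion spread
matches LN(3.55, 0.53²) millimetre sizes. `generate_trial` produces
single-lesion solid trials (log-normal or fixed baselines truncated at
10 mm, normal percent changes; `change_sd = 0` is a point mass). When a true
ORR is specified, patients are a two-component truncated mixture (responders
draw changes ≤ −30%, non-responders > −30%, responder weight = true ORR), so
the observed ORR is an unbiased estimate of the known truth.

What the generators do *not* emulate — and hence what green tests do not
establish about real data: reader-specific systematic bias profiles,
lesion-morphology effects (irregular borders, conglomeration), non-normal
error tails beyond the planted gross outliers, correlated errors across
lesions of one patient, and multi-timepoint designs. Calibration results on
synthetic data show internal consistency of the machinery, not external
validity of any particular fitted error distribution.

## Numerical choices and test scales

Covariance matrices are validated as symmetric PSD (eigenvalue clip at 0
after moment subtraction); 2×2 inverses and Cholesky factors use closed
forms tolerant of zero variances, so exactly-degenerate (zero-error)
scenarios run unperturbed. Category boundaries are compared with a 1e-12
absolute guard so that exact-arithmetic changes such as (21 − 30)/30 land on
the printed cut-offs. CSVs are comma-separated UTF-8 with a header and
decimal points; floats are parsed with round-trip precision so write/read
cycles are bit-exact. All stochastic routines take an explicit
`numpy.random.Generator` (the CLI logs its seed; default fixed).

The test suite and the reproduction script run at reduced but statistically
meaningful scales chosen for desk-scale iteration: error-model checks use
20–220 lesions with 3–6 readers, probability tables use 5–10 posterior
iterations with 500–2,000 burdens per estimate, coverage checks use 200
burdens × 1,000 simulated second readings, and the reproducibility-pattern
comparison uses 20 replicate 50-patient trials per condition. Monte-Carlo
assertions use 3-standard-error tolerances throughout.

## Known limitations

- Multi-lesion probability entries ignore the burden's absolute size.
- The definitive-progression count is held fixed under bootstrap resampling
  and such patients are kept in the ORR denominator.
- The short-axis baseline-size distribution defaults to the long-axis shape.
- The reader variance component is weakly identified with few readers (see
  above); inter-reader error covariances inherit that uncertainty.
- Best-overall-response logic over multiple timepoints, confirmation scans,
  and non-target/new-lesion progression rules beyond the definitive flag are
  out of scope.
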