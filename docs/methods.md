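# Methods

## The CUSUM chart and its endpoint

The chart tracks observed-minus-expected failures over a consecutive case
series: E₀ = 0 and Eₙ = Eₙ₋₁ + (1 − x₀) after a failure, Eₙ₋₁ − x₀ after a
success, so Eₙ = F(n) − n·x₀ with F(n) the cumulative failure count. The
implementation accumulates F(n) in integer arithmetic and forms
F(n) − n·x₀ directly; this keeps every value within one rounding of exact,
whereas a naive running float sum drifts by ~10⁻¹² over a few hundred
cases. x₀ defaults to 0.15 for major complications and 0.05 for poor
outcome (discharge mRS > 2), the benchmark failure rates for comparable
endovascular treatment; both are caller-overridable.

The endpoint is the smallest n ≥ 1 with Eₘ ≤ 0 for every m from n to the
end of the series. Two boundary decisions are deliberate: Eₘ = 0 exactly
counts as "at the expected level" (≤, not <), and a late excursion above
zero voids any earlier candidate — the rate must *stay* at or below the
reference. The ≤ 0 comparison uses an absolute tolerance of 1e−12;
with exact-contract arithmetic this only matters when x₀ has no finite
binary representation. An endpoint may not exist (chart ends positive);
that is reported as absent, not forced.

Per-centre slopes are OLS of Eₙ on n over n = 1..N. The E₀ = 0 origin is a
boundary condition, not an observation, and is excluded. R² is
1 − SSres/SStot with the convention R² = 1 for a residual-free fit to a
constant series. Slope homogeneity across centres is a partial F-test of
the centre×index interaction block in a pooled model with per-centre
intercepts. Two caveats are documented rather than hidden: (i) on
residual-free trajectories the F statistic is degenerate (reported as 0 /
p = 1 when the interaction adds nothing, ∞ / p = 0 when it explains
everything); (ii) a CUSUM series under constant risk is a random walk, so
its regression errors are autocorrelated and the homogeneity p on real
charts is anticonservative — on such data the slope table is the
descriptive product and the F-test a screening device. The nominal-size
guarantee the tests verify is for trajectories with independent errors
around a common slope.

## Group statistics

The trend test over ordered experience groups is the linear-by-linear
association statistic (N − 1)·r², with r the Pearson correlation between
group score (default 1, 2, 3) and the binary outcome over all subjects,
referred to χ²₁, two-sided. This convention reproduces the registry's
printed trend p-values to the third decimal on every outcome row
(e.g. 0.015 for discharge mRS with events 3/1/1 of 40/40/137), which is
how it was selected among the O(1/N)-different variants
(Cochran–Armitage with N instead of N − 1, etc.). The statistic is
invariant to affine rescaling of scores. Pearson χ² on the 2×k table uses
no continuity correction; a margin with zero events everywhere returns
statistic 0 / p = 1 by the identical-proportions convention. Crude odds
ratios use Woolf log-SE intervals with a Haldane 0.5 correction applied
(and flagged) when any cell is zero. Display percentages round half-up to
one decimal, matching journal style; full precision is kept internally.

## Risk models

Logistic fits are maximum likelihood via IRLS (statsmodels GLM, binomial
family), deviance tolerance 1e−8, up to 200 iterations; a fit whose score
vector has max absolute entry below 1e−6 is accepted as converged even if
the deviance rule timed out. Aliased design columns are dropped by a
greedy rank scan and reported. Quasi-separation — any fitted probability
within 1e−10 of 0 or 1 — is flagged; Wald intervals are then unreliable
(profile likelihood is not implemented; with the registry's event counts
the flag fires on the fixture itself, which is why the fixture odds-ratio
table is presented with its wide intervals rather than as inference).

Two covariate codings are exposed: the default "binary" coding (age, sex,
operator as a 4-level fixed effect, giant aneurysm >25 mm, posterior
circulation) and a "continuous" coding (size in mm, 4-level location).
Operator ≡ centre (one surgeon per centre); with four levels a random
effect is not reliably estimable, so operator enters as a fixed effect.
Group odds ratios are Wald exp(β ± 1.96·SE) against group 1; the trend p
comes from the companion model with group as an ordinal score.

The restricted cubic spline uses Harrell's truncated-power
parameterization: k = 4 knots give the linear term plus two nonlinear
terms, each normalized by the squared overall knot span; the basis is
linear beyond the outer knots by construction. Auto-knots sit at the
0.05/0.35/0.65/0.95 quantiles of procedure count, the conventional
placement for four knots. The nonlinearity test is the deviance difference
between the linear-term model and the linear+spline model, referred to χ²
with 2 df. The spline fit is warm-started from the nested linear solution:
the nonlinear directions can be nearly flat in the likelihood when events
are rare in the tails, and a cold IRLS start can wander along them. The
operator sensitivity analysis is an LRT of the group×operator interaction
block, df = (groups−1)(operators−1) minus interaction columns dropped for
operators with no events (flagged).

## Synthetic data

`simulate_operator_sequence` models learning as exponential decay of the
per-case event probability, p(n) = p_plateau + (p_start −
p_plateau)·exp(−(n−1)/scale) — "scale" is the number of cases that closes
~63% of the remaining gap. Decay on the log-odds scale is available by
flag. Defaults encode the registry's conditions: 4 centres of 55/54/54/54
consecutive cases; major complications 0.15 → 0.03 with scale 10 (implied
group means ≈10.4%/5.8%/3.3% against the observed 10.0/7.5/2.9); poor
outcome 0.10 → 0.005 with scale 10 (≈6.5%/2.7%/0.7% vs 7.5/2.5/0.7).
Covariates match the cohort marginals (age 56 ± 11.2, 75.6% female, size
log-normal with mean ≈14.3 mm and SD ≈7.7 mm, location
85.1/1.8/4.1/9.0%). Optional per-covariate log-odds effects shift both
outcome probabilities on the logit scale. One seeded generator drives the
whole call, centres in fixed order: identical config + seed gives
byte-identical output. `simulate_logistic_outcomes` is the calibration
companion: it overwrites an outcome column with draws from an explicit
logistic model over the design columns, so coefficient recovery and test
size can be measured against known truth.

The generator emulates the *structure* of the data — consecutive
single-operator series, monotone risk decay, case-mix covariates — and
deliberately not its clinical texture: no aneurysm-level multiplicity (222
aneurysms in 217 patients), no within-centre case-mix drift (the real
cohort's aneurysm size falls with experience), no correlation between the
two outcome columns, no calendar time. Passing tests therefore certify
the statistical machinery under a clean learning process, not the
clinical findings themselves.

`build_plus_fixture` freezes a 217-patient cohort reproducing every
published group-level outcome count: groups 40/40/137, major complications
4/3/4, poor outcomes 3/1/1, and the component rows (haemorrhagic 2/2/2,
ischaemic 2/2/0, mass effect 0/0/2, dissection 0/0/2, thrombosis 0/0/1).
The component sums exceed the major-complication count by exactly one
double event, which the published text locates on a single patient with
both a haemorrhage and an ischaemic stroke; the group-level arithmetic
forces that patient into group 2, and the fixture encodes it that way.
Three things are *not* identifiable from group-level counts and are fixed
by convention: the per-centre split of the 137 group-3 cases (35/34/34/34),
the placement of events within a group (evenly spaced over the group's
pooled case slots, first event at the first slot, collisions resolved by
shifting to the next free slot), and the covariates (drawn once from a
fixed internal seed with the marginal distributions above). Group
proportions and all contingency statistics are invariant to the placement;
CUSUM endpoints and R² are not, so fixture endpoints are reported as
descriptive, not as a reproduction of the registry's per-centre curves.

## Study sizes used in verification

Calibration studies run at sizes chosen to make their Monte-Carlo error
small relative to the bands being checked: coefficient bias and 95%
Wald coverage over 200 cohorts of n = 10 000 with balanced experience
groups (boundaries scaled to 800/1600 so all three group coefficients are
well identified — under the registry's 10/20 boundaries the 40-patient
reference group, not the estimator, limits precision); nonlinearity-LRT
size over 500 linear-logit cohorts of n = 1 000; endpoint recovery over
100 four-centre cohorts of 60 cases with risk decaying 0.35 → 0.02 at
scale 6, the true learning window taken as the first five time constants
(cases 1–30); slope-homogeneity size over 500 four-trajectory replicates.
Acceptance bands on simulated rates are three binomial standard errors
around the nominal value.

## Known limitations

Reference rates are fixed, not risk-adjusted per case; V-mask/decision
-interval control limits and sequential probability ratio boundaries are
out of scope. Rare events with many covariates flag quasi-separation and
Wald intervals degrade; no Firth penalization is provided. The slope
-homogeneity F-test's size guarantee does not extend to autocorrelated
CUSUM residuals (above). Patient-level registry sequences are not public,
so centre-level endpoint and R² values from the source cohort cannot be
reproduced — the fixture reproduces the group-level table exactly and the
simulator provides ground truth for everything sequential.
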