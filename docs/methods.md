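# Methods

## Model

The population of interest is everyone born in France 1940–1960,
observed as a 2013 cross-section. Each (birth year, sex) cohort is
propagated in one-year cycles through four states: *ARF-free*,
*post-ARF without VHD*, *ARF-VHD*, *dead*. Counts are real-valued
expectations (the model is a cohort expectation calculation, not a
sampling procedure), and the two sexes are modelled separately because
their mortality differs materially.

Within the cycle from year *t* to *t+1* (age *a = t − birth year* at
the start), events are ordered **mortality first, incidence second**,
with incidence evaluated at the new age *a+1* in year *t+1*. The
ordering is a modelling choice the data cannot identify; any fixed
order changes results only at O(q·λ), which is negligible at these
rates (q ≲ 10⁻², λ ≲ 10⁻³). What matters is that the individual-level
simulator uses the *identical* schedule, so the two routes are exactly
comparable.

Transitions:

* All living states die with the period probability q(a, t, sex);
  ARF-VHD patients die with 1 − (1 − q)^HR once a ≥ 20. The hazard
  ratio acts on the hazard scale (−ln(1−q) scaled by HR) rather than
  multiplying q, because a hazard ratio is defined on hazards and the
  multiplicative shortcut can exceed 1. Default HR = 1.5, a
  conservative value inside both published confidence intervals for
  rheumatic-VHD excess mortality. ARF patients *without* VHD carry
  general-population mortality.
* A first ARF episode occurs with λ(a, t) = r_t/100 000 · s(a), applied
  only to the ARF-free state (one episode per person — the quantity
  being tracked is "ever developed ARF"). VHD onset is simultaneous
  with ARF onset for a fixed fraction f of cases (0.50 / 0.40).
  Incidence is identical for boys and girls.

"Alive in 2013" means survivors through the 2012 mortality cycle, i.e.
the state at the start of 2013; the mortality surface ends in 2012, so
no 2013 cycle is attempted.

## Incidence surface

The age shape s(a) is piecewise linear through (3, 0), (5, 1), (15, 1),
(25, 0), zero outside; endpoints 3 and 25 carry exactly zero mass. Over
integer ages its total mass is exactly 16 person-year-equivalents,
which several tests use as a closed form. Reference-rate curves r_t are
piecewise linear between (year, rate-per-100 000) breakpoints and zero
outside their span. The three shipped scenarios — 100→0 over 1940–1986;
a 62.5 plateau to 1950 declining to 0 by 1965; the same shape at 37.5 —
are documented approximations of Danish and English mid-century
surveillance, supplied via config and deliberately *not* treated as
ground truth: every quantitative acceptance check is independent of
their exact values.

## Conditional probability

P(ARF-VHD | VHD ∧ exposure) = P(ARF-VHD)/P(VHD | exposure), requiring
(i) exposure independent of ARF history and (ii) no double-counting of
ARF-VHD patients as drug-induced VHD. The numerator is computed over
the whole surviving cohort, not the exposed subset — exactly what
independence licenses, and verified empirically: the microsimulation
assigns exposure and drug-induced VHD at the 2013 cross-section
(p = 0.16 to exposed survivors without ARF-VHD) and its empirical
conditional probability matches the formula within 3 Monte-Carlo SE at
n = 10⁵. Strictly, the simulated denominator is
prev + (1 − prev)·p rather than p; at prev ≈ 0.3% the difference is an
order of magnitude below the Monte-Carlo error, which is why the
formula passes the oracle check.

The sensitivity grid varies p over {0.16, 0.07, 0.22} (point estimate,
lower bound from suggestive-echo findings in exposed patients, upper
95% limit) and f over {0.50, 0.40}. Two exact algebraic facts give the
grid its internal structure: the alive ARF-VHD *count* is exactly
linear in f (its inflow scales by f, its survival does not depend on
f), and the conditional probability is exactly inversely proportional
to p. The reported *probability* inherits the f-linearity only to
~10⁻⁴ relative, because the alive denominator shifts slightly when
fewer patients carry the excess hazard. Formatted outputs round
half-even to 2 decimals; the 7–22% band is printed (value at p = 0.22,
value at p = 0.07), i.e. (low, high).

## Demographic inputs and backfill

Inputs are period life tables (age = calendar year − birth year,
completed years) and live-birth counts, as plain CSV. Detailed official
mortality starts in 1946, so 1940–1945 is backfilled: ages ≥ 1 copy the
1946 column ("steady between 1941 and 1946"); age 0 comes from a
separate infant-mortality CSV mirroring the separately-available infant
deaths registries. If no infant file is supplied the 1946 age-0 value
is copied and a warning is logged — a convention, flagged as such,
since the historical merge rule is not documented. Lookups above the
table's maximum age reuse the top row, so 1940 cohorts reaching age 72
never hit a gap.

## Synthetic demography

The generator emulates the *structure* of the real inputs: ~800 000
births/year at a 1.05 male/female ratio; mortality
q(x,t,s) = 1 − exp(−μ(x)·m(t)·g(s)) with Gompertz–Makeham
μ(x) = 5·10⁻⁴ + 10⁻⁴·e^{0.095x}, period improvement
m(t) = 0.99^{t−1940}, female multiplier 0.85, and an infant q₀ of 0.05
in 1940 declining with m(t). These give period life expectancies of
62.3/64.5 years (male/female) in 1940 rising to 71.8/73.8 by 2012 — a
plausible mid-century-to-modern trajectory, guarded by a 55–75-year
band test. The Gompertz scale 10⁻⁴ was chosen so that the surface
actually sits in that band; it is configuration, not a calibration to
French data. The generator is fully deterministic (the seed field is
reserved for optional noise), so fixture bundles regenerate
byte-identically.

What the synthetic data does *not* emulate: the baby boom and war-time
birth deficit (births are flat), cohort-specific mortality shocks,
migration, and the exact level of French mortality. Tests passing on it
therefore demonstrate the correctness of the machinery and the model's
structural relations, not the published absolute estimates, which
require the real INSEE extracts as user-supplied input.

## Microsimulation oracle

Life courses are sampled per individual with the engine's exact event
schedule; n individuals are allocated across (birth year, sex) cells by
largest-remainder proportionality to births. Randomness uses
per-cohort, per-purpose generator streams, with uniforms drawn as
(individual × year) matrices in row-major order — growing n appends
individuals without reshuffling earlier life courses, keeping
regression comparisons stable. ARF-VHD and drug-induced VHD are
mutually exclusive by construction. The Monte-Carlo error of the
simulated prevalence scales as n^{−1/2} (checked over n = 10³–10⁵).

## Numerical choices and problem sizes

Conservation (states sum to cohort entries) holds to ~10⁻¹⁶ relative
and is asserted at 10⁻⁶. Deterministic runs over the full 21-cohort ×
2-sex × 73-year surface take ~1 s each; the test suite uses 10⁵
individuals for the main oracle comparison and 6 replicates per size
for the convergence check, keeping the whole suite under two minutes.
Degenerate inputs are defined errors: empty CSVs, probabilities outside
[0, 1], strata with zero survivors, a missing life-table cell (reported
by name). A conditional probability above 1 warns but is not clipped —
it signals an inconsistent numerator/denominator pair rather than a
numerical problem.

## Known limitations

Single ARF episode per person; no remission, surgery, or time-varying
hazard ratio; no migration (foreign-born assumed equivalent);
benfluorex exposure modelled as a cross-sectional flag, not a dosed
history. The published table's absolute values are reproducible only
with the original demographic extracts; what this package guarantees —
and tests — are the model's structural identities and every step of the
computation from inputs to the headline probability.
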