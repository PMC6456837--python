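# Methods

## Stand growth model

The mensuration layer treats an even-aged stand as a sequence of
age-points (t, N, D, H, F). Standing volume uses the classical
form-factor formula

    V(t) = N · (π/4) · (D/100)² · H · F   [m³ ha⁻¹],

i.e. stocking times the volume of the mean tree, where the form factor F
scales the basal-area cylinder down to the true stem shape. Diameters
are taken in cm and converted inside the volume routine; all volumes are
m³. Applied to the packaged stand tables this formula reproduces every
tabulated volume cell within 0.06% — except the post-thinning age-40
cell, where the tabulated 229.50 m³ ha⁻¹ is inconsistent with its own
row attributes (N=530, D=26, H=13, F=0.60 give ≈219.5). The
implementation reproduces the formula and excludes that single cell from
the volume oracle rather than forcing agreement; increment values
derived from the tabulated volume column are still honoured as inputs.

Increments:

* MAI(t) = V(t)/t. Undefined at t ≤ 0 (domain error).
* PAI(t) = (V(t) − V(prev))/Δt, always over the *actual* interval
  between consecutive measurement ages (the tables are irregularly
  spaced: 3, 7, 10, 13, …). The first row of a table has no PAI. PAI may
  be negative if volume declines.
* The MAI culmination (`peak_mai`) returns the earliest age at the
  maximum; the earliest culmination is the economically relevant
  rotation signal. On a unimodal yearly series the culmination age
  coincides, up to the one-interval labelling offset, with the age where
  PAI first drops below MAI (PAI at age t covers the interval ending at
  t, so the first drop can land on the interval just after the peak);
  the property test asserts peak or peak+1.

Computation is carried in full precision; rounding (2 d.p. for
presentation, matching tabulated precision) happens only in writers and
summaries.

## Thinning

Low thinning removes trees whose diameter is *strictly* below
mean(diameters) − offset, with offset defaulting to 2 cm. Boundary trees
are retained — a conservative reading that makes a perfectly homogeneous
stand a no-op. The mean is the unweighted arithmetic mean of the input
list. The fraction of stems removed is exposed as a diagnostic
(`ThinningResult.intensity`, typically 0.2–0.4 in this system) rather
than enforced as a constraint.

The pre/post contrast is age-wise and agnostic about when thinning was
applied: stems removed = N_pre − N_post at each common age (90–340
stems ha⁻¹ across the packaged tables), and the MAI gain at an age is
100·(MAI_post − MAI_pre)/MAI_pre. By default MAIs are recomputed from
the stand attributes; callers can supply tabulated MAIs instead, which
matters only because of the age-40 volume anomaly above (recomputed gain
at age 25: 24.6%; from tabulated values: 24.5%).

## Economic layer

**Nominal rate of return.** i = (Iₙ/V₀)^(1/n) − 1. For fishing
households the survey tabulates only annual net income and operating
cost; the model that reproduces the tabulated monthly NRR column to the
printed decimal — and the only simple assignment found that does — is
gross annual return on operating cost compounded monthly: Iₙ = net +
cost, V₀ = cost, n = 12. All six tabulated rows reproduce to 1 d.p., and
the maximum (11.4%/month at a cost of IDR 10 million) marks the
diminishing-marginal-returns optimum. Ties resolve to the first row.

**Sturges classing.** Class width = R/(1 + 3.332·log₁₀N) for income
range R over N households, rounded to the nearest integer; the class
count is round(1 + 3.332·log₁₀N). Bounds are contiguous closed integer
ranges as conventionally printed for integer incomes (13–16, 17–20, …);
a household at income x is assigned to class floor((x − base)/width),
top class absorbing the maximum, so non-integer incomes cannot fall in a
bounds gap. Empty classes are omitted from summaries. The classing range
defaults to the data min/max but can be given explicitly — necessary for
the packaged survey, which carries each household at its class-median
income (the raw incomes behind the published 13–36 range are not
printed). Totals are conserved exactly across classes.

**Valuation.** Annual wood income = area × standing volume at the
harvest age × stumpage price / rotation years (300 ha × 98.99 m³ ha⁻¹ ×
IDR 500,000 / 20 yr = IDR 742,425,000 in the packaged scenario). Incomes
convert to per person per day over the *full dependent population* (164
people), not the 123-person surveyed subsample — the published
per-person figures only reproduce with the full community denominator —
at 365 days/yr and IDR 13,300 per US$. The overfishing rate is
100·(fishing − wood)/wood on per-person-per-day incomes; it is
scale-invariant, so the currency and denominators cancel. With the
packaged totals it is 45.5%. (The study text elsewhere also quotes
37.3%, for which no derivation from the printed numbers exists; only the
45.5% figure is computed. Likewise the published US$1.43/day conversion
of IDR 18,048 is inconsistent with the stated exchange rate, which gives
1.357; the package reports the computed conversion.) Survey money is
handled in million IDR and scaled by 10⁶ on conversion; valuation
outputs are whole-rupiah floats.

## Synthetic data

The generator's job is statistical shape fidelity, not ecological
process realism (no tides, recruitment or competition):

* D(t) = d_max(1 − e^(−k_d·t))^p_d and H(t) analogous —
  Chapman–Richards-type saturating curves, the standard even-aged
  mensuration form. Defaults d_max = 25 cm, k_d = 0.05 yr⁻¹, p_d = 1.3,
  h_max = 14 m, k_h = 0.055 yr⁻¹, p_h = 1.2 were calibrated once to the
  study stand's endpoints (age-3 and age-40 attributes); under them the
  MAI curve is unimodal with culmination at age 25.
* N(t) = n0·e^(−m·t) rounded to whole stems (n0 = 2600 ha⁻¹,
  m = 0.027 yr⁻¹ matches the observed decline to ~870 by age 40);
  F declines linearly from 0.85 to 0.60 over the age span.
* Tree lists: truncated-at-zero normal diameters; heights from the
  deterministic allometry h = 0.18·d^1.5, which passes near the stand
  table's (D, H) pairs. The within-stand diameter sd is a free parameter
  with no study-anchored default.
* Households: truncated-normal net incomes over 13–36 million IDR yr⁻¹
  (mean 25, sd 6 — spanning the six published classes), operating costs
  a fixed 0.40 fraction of income (the tabulated net/cost ratios run
  ≈0.35–0.48), household sizes uniform on 3–5.

All randomness flows from one integer seed per call through
`numpy.random.default_rng`; there is no global random state. Noise on D
and H is multiplicative with a stated CV and **off by default**, so
noise-free trajectories are exact: refitting the diameter curve by least
squares recovers d_max and k_d to well under 1%. What passing synthetic
tests do *not* show: real stands have measurement error, diameter
distributions that are not normal, mortality that is not memoryless, and
height–diameter scatter; conclusions about real data rest on the
fixture tables, not the generator.

## Numerical and interface choices

* Volumes, rates and currency are double precision throughout; the
  writers round only for presentation (`--round`).
* Stand CSVs are written with shortest-roundtrip float repr and read
  with `float_precision="round_trip"`, so write→read is bit-exact.
* Validation errors from CSV readers name the offending 1-based data
  line.
* The packaged scenario (`run_paper_scenario`, CLI `reproduce`) is fully
  deterministic: it reads the fixture tables, recomputes every headline
  quantity, and logs each against its reference value with relative
  error; the CLI exits non-zero on any mismatch.
* Problem sizes: the whole suite runs on the fixture tables (12 + 7
  rows, 30 households) plus synthetic runs of ≤ 38 ages, 1000 trees and
  50 hypothesis examples per property — seconds end to end.

## Known limitations

* No growth-response model after thinning: post-thinning states are
  data, not dynamics, so thinning schedules cannot be optimised.
* No allometric biomass/carbon, bark/branch partitioning, or
  species-level fishery revenue; no inflation adjustment or real-rate
  conversion.
* The Sturges class count is a rounding of a continuous formula;
  samples whose range is dominated by outliers can produce sparsely
  occupied classes.
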