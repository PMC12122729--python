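# Methods

`riskstrata` asks a quantitative question about prospective risk scoring:
when expected hospital utilization is estimated from the previous year's
condition categories — the way capitated payment models estimate expected
cost — how well does the resulting ranking identify the people who will
actually be hospitalized?  The package implements the full analysis chain
(cohort construction, condition-category mapping, least-squares calibration,
quintile and cumulative-segment evaluation) plus a synthetic claims
generator that stands in for restricted Medicare fee-for-service data.

## The analysis model

For each member of a training population, base-year demographic data and
diagnosis codes are converted to a binary feature vector: one indicator for
the member's (age-band, sex) cell — bands 65–69, 70–74, 75–79, 80–84, 85–89,
90+ crossed with sex — followed by one indicator per hierarchical condition
category (HCC).  HCCs come from a pluggable mapping table of diagnosis-code
→ category assignments plus dominance rules under which a more severe
category zeroes related milder ones; dominance is applied simultaneously to
a fixed point, which is order-independent and idempotent.  The shipped
synthetic table has 79 categories with 2–5 codes each and 12 two-level
dominance pairs; real tables load from the same two-column CSV layout.

Training solves the overdetermined linear system `X_t b ≈ y_t` where `y_t`
is the count of performance-year inpatient admissions, by ordinary least
squares.  Numerically the solve goes through the (small) Gram system with a
Cholesky factorization, falling back to a symmetric pseudoinverse when the
Gram matrix is singular — e.g. a category absent from the training arm —
which yields the minimum-norm solution.  Every solve is checked against the
normal-equation contract `‖Xᵀ(y − Xb)‖∞ ≤ 10⁻⁶ ‖Xᵀy‖∞`.  No explicit
intercept column is used: the demographic cells are exhaustive and mutually
exclusive, so they span a partition of unity and play the intercept's role;
a consequence asserted in the tests is that training fitted values preserve
the observed mean exactly.  Predictions on the held-out study arm,
`ỹ_s = X_s b_t`, may be negative; they are retained unclipped because only
the ranking enters the stratification.

The study arm is ranked by `ỹ_s` and cut into five quintiles (ties broken by
beneficiary id; any remainder when 5 ∤ n goes to the highest-risk quintiles
so the top segment is never empty).  Per quintile we report mean expected
and observed counts, the predictive ratio (mean expected / mean observed), a
95% normal-approximation confidence half-width `1.96·sd/√n` on the observed
mean, and empirical 0.5th/99.5th percentile bounds (nearest-rank) containing
99% of individual outcomes.  Cumulative risk segments union quintiles from
the top (top-20/40/60/80/100%); per segment we report expected and actual
totals and rates (admissions per beneficiary as a percent — a count rate
that can exceed 100% — alongside the distinct any-admission probability, to
keep the two from being conflated), the capture fraction (segment admissions
÷ population admissions), the zero fraction (members with no admissions),
and the count histogram (capped at 15 with an overflow bin in reports; full
tail retained in memory).  Individual-level fit is the ordinary coefficient
of determination `R² = 1 − Σ(y−ỹ)²/Σ(y−ȳ)²` on the study arm.

## Cohort rules

Eligibility per base/performance pairing: age ≥ 65 on January 1 of the base
year; 12 enrolled Part A and Part B months in both years; decedents retained
when death falls in or after the performance year and every year while
living is fully enrolled (prorated to the death month); any Part C
(Medicare Advantage) enrollment or an ESRD flag excludes; dual-eligible
(state buy-in) members are retained.  Age is computed at January 1 and
continuous enrollment is operationalized month-wise because finer
granularity adds nothing at annual outcomes.  The randomized split assigns
each beneficiary a seeded pseudo-random integer; even parity → training arm,
odd → study arm.  The training arm is calibrated on the first pairing
(2017 → 2018 by default) and the study arm evaluated on the second
(2018 → 2019), so arms never share a pairing.  Eligibility is evaluated per
pairing: a member may be eligible for one pairing and not the other.

## The synthetic data-generating process

The generator's latent annual admission rate is multiplicative:

    λ_i = base(cell_i) · Π_k effect_k^{z_ik} · ε_i

with `z_ik` the performance-year-active category indicators — drawn at
category prevalence in the base year (then passed through the dominance
closure, so emitted diagnoses reconstruct the drawn categories exactly) and
carried into the performance year independently with probability
`persistence` — and `ε_i` a unit-mean Gamma(shape r) frailty shared across
years.  Counts are Poisson(λ · exposure) with exposure prorated for in-year
death.  Each admission emits one inpatient claim; base-year categories emit
outpatient and carrier claims whose codes map back to exactly the drawn
categories.  Deaths follow a flat 4%/yr hazard with a uniform in-year month;
Part C (20%) and ESRD (1%) flags mark members the cohort stage will drop.

The fitted model is deliberately misspecified relative to this process —
linear in indicators where the truth is multiplicative, blind to the frailty
and to base-to-performance drift — which is what keeps individual-level R²
low while group-level predictive ratios stay near 1, the phenomenon the
analysis is about.  A property test asserts the monotonicity this implies:
removing frailty noise and drift strictly raises study-arm R².

### Calibration of the shipped defaults

Defaults were frozen by seeded moment matching (`calibrate_defaults`
implements the procedure; the search ran at n = 100k–500k) against five
aggregate targets on the study arm: marginal admission rate ≈ 0.27/person-
year, top-quintile admission rate ≈ 0.69 with ≈ 63% of top-quintile members
experiencing zero admissions, top-quintile capture fraction ≈ 0.51, and
R² ≈ 0.12.  A useful closed-form anchor: a gamma-Poisson stratum with mean
0.689 and zero fraction 0.63 implies a negative-binomial shape of 0.614
(root of `(r/(r+μ))^r = p₀`; `nb_shape_for_zero_fraction` solves this and is
the oracle used in tests and calibration steps).

Frozen values: demographic base rates 0.037/person-year at (F, 65–69) rising
×3.1 over age bands and ×1.15 for men; prevalences log-spaced 0.005–0.20
over 79 categories; effects log-spaced 1.10–2.70 assigned so the rarest
categories carry the largest effects (this produces the small number of
individuals with counts an order of magnitude above their quintile mean);
frailty shape 1.05; persistence 0.95.  Two calibration couplings drove the
final values: the effect spread controls the top-quintile concentration
*and* contributes most of the predictable variance, and persistence turned
out to need to stay high — drift at persistence 0.7 pushes R² well below
0.12 — so the drift injected is mild and the low R² is carried mainly by
frailty and Poisson noise.  Confirmation runs at n = 500,000 with two seeds
gave marginal 26.6–26.8%, top-quintile rate 69.1–70.3%, zero fraction
62.6–62.8%, capture 0.519–0.525, R² 0.106–0.118.

### What the generator does not emulate

Diagnosis codes are synthetic tokens with no ICD semantics; costs, payment
amounts, geographic variation, mid-year Part C switching, transfers/interim
inpatient claims and coding-intensity effects are absent; base-year category
draws are independent across years rather than serially correlated, and the
frailty is time-constant.  Passing tests therefore demonstrate that the
*pipeline* reproduces the documented aggregate geometry of claims data —
skew, weak individual predictability, calibrated group means — not that it
reproduces any particular real population.

## Numerical and reporting choices

Tie-breaks (by beneficiary id) and row/column orderings (lexicographic) are
fixed so identical seeds give byte-identical outputs.  The 95% CI level and
the nearest-rank 99% bounds are conventions chosen where the reported
statistics name no level.  Quintile summaries of sub-five-member populations
report NaN for empty quintiles; a quintile with zero observed mean reports
an undefined (NaN) predictive ratio rather than infinity.  Reports are JSON
with sorted keys (plus CSV companions), identical across reruns except the
timestamp.

Problem sizes in the test suite — 500,000 beneficiaries for the full-scale
calibration checks, 2k–50k for distributional unit tests — were chosen as
the smallest sizes at which each statistic's Monte-Carlo error is
comfortably inside the asserted band.

## Known limitations

Only annual outcome counts are modeled (no month-level weighting of
decedent exposure in training rows); generalized linear alternatives to OLS
are out of scope; the synthetic mapping table cannot reproduce the real
CMS-HCC feature space, though the engine loads licensed tables unchanged.
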