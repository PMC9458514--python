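# Methods

## Model structure

The engine is a time-inhomogeneous monthly Markov cohort model over eight
health states (`engine.HealthState`).  Treated cohorts start in
`NEOADJUVANT`; the untreated comparator starts progression-free (kept in the
`REMISSION_R0` slot) and progresses directly to palliative care, so with the
treatment states unused the engine reduces to a plain illness–death model.
The horizon is 144 monthly cycles (12 years), matching the published design;
state occupancy is conserved to 1e-9 per cycle and the death state is
absorbing (both are tested invariants).

Competing risks within a cycle are ordered deterministically: background
all-cause death (from the packaged life table) is evaluated first, and
disease events apply to the survivors.  This ordering is a convention; it is
documented so the closed-form oracles in the test suite match exactly —
e.g. a remission row with background probability `q` and progression `p`
carries `P(recurrence) = (1-q)·p`.

Treatment pathway conventions:

* **Dropout.** The published cumulative dropout `d` over the 6-cycle
  neoadjuvant phase is applied as a constant per-cycle probability
  `1-(1-d)^(1/6)`.  Non-completers split 50% to second-line therapy, 30% to
  palliative care and 20% to death.  The split is not published; the values
  are an explicit, config-held placeholder (`settings.dropout_split_*`)
  varied implicitly through the dropout excursions of the sensitivity
  analyses.
* **Resection** is a single transitional cycle at month 6; surgical 30-day
  mortality applies there, survivors split R0 : R1 at the published R0 rate.
  Surgical complications and fistula affect cost only, not transitions.
* **30-day neoadjuvant mortality** (0.24) is interpreted as already embedded
  in the survival curves the model is calibrated to, and is not applied on
  top of them (double counting); consequently its one-way sensitivity span
  is ~0 and it is kept only for transcription completeness.
* **Post-recurrence mortality** starts from a base monthly probability
  blending the four published post-recurrence medians: margin-stratified
  (weights R0 rate) and node-stratified (weights lymph-node positivity)
  estimates are each converted by `p = 1-0.5^(1/median)` and averaged, since
  no joint distribution is published.  Calibration scales this base per
  segment (below).
* **Second-line death** comes from the published 9-month median;
  **palliative death** for the treated arms from an assumed 5.1-month median
  (`settings.palliative_median_months`), the gap between the untreated arm's
  published median OS (13) and PFS (7.87).  The untreated arm's
  post-progression mortality is calibrated, not assumed.

## Background mortality

`data/life_table.csv` is an abridged all-cause table (ages 60–72): the
average of male and female annual death probabilities from the 2016 U.S.
Social Security Administration period life table, converted per cycle as
`1-(1-q_annual)^(1/12)` at the attained integer age.  Ages beyond the table
hold the last value (the horizon ends at age 72, so this never triggers in
the base case).

## Calibration

Free parameters per arm: three progression probabilities (remission →
progressed) and three death multipliers (progressed-state disease death,
scaling the blended base above), piecewise-constant on segments with knots
at months {6, 36, 60, 144} (untreated: {0, 36, 60, 144}).  The knots were
placed so that each segment contains exactly one anchor time per endpoint —
the published medians fall between months 24 and 35, then the 5- and
10-year landmarks — giving the fit a near-triangular, identifiable
structure.  An earlier knot at month 24 left two anchors in one segment and
the system over-constrained.

The objective is the unweighted sum of squared survival deviations in
proportion space across all OS and PFS anchors (anchors span [0, 1]
comparably, so no weighting is applied).  Optimisation is bounded
`scipy.optimize.least_squares` (trust-region reflective, tolerances 1e-10)
from five starts — the structured initial guess plus four seeded random
draws — so results are reproducible bit-for-bit given a seed.  `converged`
reflects the optimiser's termination status; exhausted restarts without
convergence are reported, never silent.

Fit quality in the base case: FOLFIRINOX and natural history reach the
anchors to machine precision.  G-nP retains residuals of ~0.003 survival at
its two medians because its published OS–PFS median gap (28.27 − 24.88 =
3.39 months) sits near a structural floor: dropout survivors (second-line
median 9 months) alone keep OS above PFS by roughly that much at the median,
even with post-recurrence death at its upper bound.  The simulated G-nP
medians are within ±0.35 months of the published values.

Identifiability caveat: anchors only inform a segment while the curve
retains mass.  The parameter-recovery suites therefore draw hazards in
ranges (progression 0.01–0.06/month, death 0.03–0.15/month) where survival
at the last anchor (month 120) does not underflow; outside them the final
segment's gradient vanishes and recovery is limited by information, not by
the optimiser.

## Economics

Costs accrue on start-of-cycle occupancy; QALYs and life-years on half-cycle
corrected occupancy (mean of start and end of cycle); everything is
discounted at 3%/year, `(1.03)^(-t/12)`.  Costs are deliberately *not*
half-cycle corrected (the correction is applied to QALYs and unadjusted
life-years only).  Per-state accrual:

* neoadjuvant: chemotherapy per cycle + administration + expected toxicity
  (toxicity rate × per-cycle toxicity cost, plus toxicity rate ×
  hospitalisation-for-toxicity rate × one inpatient month — the
  hospitalisation rate has no published cost line of its own, so a
  hospitalised toxicity is costed as an inpatient PDAC month);
  capecitabine/radiation in the final two cycles plus one chemoradiation
  hospitalisation (config toggle, default on);
* model entry: one endoscopic-ultrasound work-up for the cohort alive at
  entry;
* resection cycle: surgery cost plus rate-weighted inpatient months for
  complications and fistula;
* recurrence: monthly inpatient disease-management cost **plus second-line
  therapy** (drug + rate-weighted toxicity + administration;
  `settings.recurrence_second_line`, default on).  Recurrent patients moving
  to second-line treatment is what makes the second-line cost inputs — the
  only strongly arm-differentiated recurring costs — matter, and it is the
  only accrual mapping consistent with the magnitude and ordering of the
  published per-strategy cost totals;
* second line (dropouts): drug + rate-weighted toxicity + administration;
* palliative: the published palliative-care total amortised over the
  expected sojourn implied by the state's death hazard (mean accrual per
  entrant then equals the published total);
* untreated arm: observation while progression-free, the amortised
  palliative stream after progression.  Streaming the inpatient monthly cost
  over the stable phase as well would make the untreated arm the most
  expensive strategy, contradicting the published totals, so it is not done.

Utilities: progression-free 0.80 (remission and neoadjuvant, the latter plus
chemotherapy disutility and toxicity-rate-weighted toxicity disutility),
surgery-recovery 0.78 for the single resection cycle
(`settings.surgery_recovery_cycles`), progressive 0.73 (recurrence and
second line), palliative 0.14.  A negative net state utility raises an
error rather than being clamped.

The monthly treatment-related adverse-event (TRAE) cost endpoint is reported
as total undiscounted TRAE accrual divided by the number of cycles with any
accrual.  The published derivation of this endpoint is unstated and the
printed magnitudes are not reproducible from the inputs; the endpoint is
reported but not validated.

## Frontier

Strategies are sorted by cost; strictly dominated ones (≥ cost, ≤ QALYs, one
strict) are removed, then extended dominance is applied iteratively
(non-increasing incremental ICERs along the chain).  Exact cost/QALY ties are
flagged and broken by label order.  The optimum at a WTP threshold is the
highest-QALY frontier member whose ICER is below it.  Median survival is
read off the monthly curves by linear interpolation, which places within-
cycle event mass at mid-cycle, consistent with the half-cycle correction.

## Sensitivity analyses

The base calibration is held fixed throughout.  One-way sweeps re-run
the cohort and accounting with a single parameter at each bound; parameters
that are survival medians re-derive the monthly probabilities they feed,
and the published "PDAC recurrence rate" — which is not itself an engine
input — enters as a multiplicative scale on the calibrated progression
hazards (value / base value), giving it the sensitivity role described in
the source analysis.

PSA distributions: beta for probabilities and utilities, gamma for costs,
medians, and disutility magnitudes, all moment-matched with mean at the
base value and standard deviation `(high - low)/3.92` (the range read as an
approximate 95% interval); degenerate ranges are point masses and
infeasible moment matches fall back to uniform.  Mean-anchoring keeps the
PSA centred on the base case (percentile-matching the asymmetric ranges
instead shifts several sampled means far from base and distorts the
acceptability curves).  Parameters are sampled independently, each from its
own seeded substream, so results do not depend on parameter order; the
start age is held fixed (it drives the life-table lookup and is structural).
The CEAC is evaluated on a $0–200k grid in $5k steps by net-monetary-benefit
argmax.

Scenario overrides replace named parameter values and, optionally, survival
anchor sets; arms with replaced anchors are re-calibrated.  The shipped
center-of-excellence file contains *synthetic* placeholder values following
only the published qualitative direction (fewer resections, lower
recurrence, higher R0, longer survival); its outputs are illustrative.

## What the synthetic fixtures do and do not show

`generate_synthetic_anchors` produces survival anchors from known piecewise
hazards — exactly (closed form) or with truncated Gaussian noise.  Recovery
tests on these fixtures show the calibrator is correct and identified for
curves generated by the model family itself.  They do not show that real
digitised Kaplan–Meier data satisfy the piecewise-exponential assumption,
nor do the anchor fixtures carry the full published curves — only their
printed summaries.  Calibrating to an arm's own published survival
summaries makes the survival endpoints self-consistent by construction;
the economic outputs remain genuine model predictions.

## Known limitations

* The published per-strategy cost totals and QALYs are not exactly
  reproducible: the original cost-accrual rules, calibration internals and
  PSA distributions are unpublished.  This model's discounted totals are
  lower (≈ $98k/$128k/$154k vs the published $112k/$205k/$241k) but
  preserve the ordering and the frontier structure; the headline ICER of
  FOLFIRINOX vs G-nP lands at $87.7k vs the published $80.9k.
* The dropout destination split, the palliative median for treated arms,
  the hospitalised-toxicity costing and the chemoradiation add-on timing
  are explicit modelling choices held in settings, not published values.
* The untreated arm's 5- and 10-year anchor values of zero are encoded as
  1e-4 to keep hazards finite.
* Survival beyond the published 10-year landmarks (months 120–144) is an
  extrapolation of the last calibrated segment.
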