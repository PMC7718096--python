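# Methods

## The measurement

A pharmacy benefit manager (PBM) screens every incoming prescription claim
against the patient's medication history (prospective drug utilization
review, DUR) and rejects fills that would complete a serious drug-drug
interaction (DDI). The history available to DUR depends on how records are
linked to patients. Under a **beneficiary-identifier regime** the identity
is the (payor, member-ID) pair, so any insurance transition severs the
history. Under a **unique-patient-identifier (UPI) regime** records are
linked by deterministic demographic matching, so history survives
transitions. An alert whose precipitating (historical) fill was
adjudicated under a different (payor, beneficiary) pair than the
triggering fill is a **crossover alert**; on clean data the set of alerts
found under UPI but not under the beneficiary regime is *exactly* the
crossover set, and this set-difference identity is the package's central
invariant (enforced as an acceptance test at 10^4 patients).

## Synthetic claims model

Because real PBM claims warehouses are proprietary, all analyses run on a
synthetic generator whose ground truth is known.

**Enrollment churn.** Each patient holds consecutive enrollment spans
partitioning the simulation horizon (default 2016-09-01..2019-08-31, the
3-year window of the reference study). For each calendar year whose
January 1 falls inside the horizon, the patient transitions with
probability `annual_transition_prob` (default **0.20/yr**, consistent with
the ~18.6%/yr cohort attrition reported for the studied PBM); a fraction
`january_concentration` (default **0.5**, an assumption — the true
fraction is unpublished) of those transitions lands exactly on January 1,
the rest uniformly through the year. Medicaid patients transition
uniformly year-round (`medicaid_seasonality_flat`), reflecting rolling
eligibility. Additional one-shot transitions fire on the birthdays at
ages 19, 26 and 65 with probabilities {0.6, 0.5, 0.9} (assumptions; the
age-65 trigger forces Medicare Part D). A transition regenerates the
beneficiary identifier whenever the payor changes, and also (default on)
when the payor switches PBMs — covering all three transition modes by
which histories fragment. The partial Sep–Dec 2016 stub year carries no
annual transition draw, so the realized boundary rate per patient-year
equals the configured probability exactly.

**Demographic uniqueness.** Distinct patients are guaranteed distinct
demographic match keys (collisions are resolved by redrawing the birth
date), so at `typo_rate = 0` the matching keys are generative truth and
UPI linkage is exact by construction. Transcription noise is modelled by
`perturb_demographics`, which corrupts first name, last name, postal code
and birth date independently per claim.

**Claims.** Background fills arrive at **9.6 fills/patient-year**
(≈1.44×10^9 claims / 49.7×10^6 patients / 3 yr in the reference study),
drug drawn uniformly from the catalog. With probability `ddi_plant_rate`
(default 0.05) a patient hosts one planted serious interacting pair; the
planted density is deliberately far above the study's ~1.7×10^-4 alerts
per claim so that desk-scale runs (10^3–10^4 patients) yield thousands of
alerts for stable rate estimates. Two planting modes exist: *organic*
(pair anchored uniformly in time; crossover status emerges from churn)
and *forced* (`plant_crossover_share = x`: the pair straddles a span
boundary with probability exactly x), the latter used for parameter-
recovery calibration as the only alert source (background restricted to
non-interacting classes).

**Off-benefit fills.** Fills of configured classes (default:
erectile-dysfunction drugs) are adjudicated with probability 0.02 under a
synthetic cash/coupon identifier unique to (patient, class). The rate is
an assumption: plans often deny ED coverage, and the observed ~2%
crossover rate among ED alerts (versus 0.8% for macrolides) bounds the
cash share at roughly this order.

**Post-alert behavior.** In organic mode each alerted claim is followed
within 14 days by a same-drug re-dispense with probability 0.735 or a
same-condition alternative with probability 0.10 (the disposition mix of
the reference study). Re-dispenses can themselves re-alert while the
precipitating supply is active; these second-generation alerts receive no
planted resolution, so the realized override share in synthetic streams
(~45%) sits below the planted 73.5%. This is a known generator
limitation, not a property of the classifier.

**Ground truth.** The truth ledger is an exhaustive pairwise scan within
true patients under the DUR window rules — an implementation deliberately
independent of the streaming engine, so engine-vs-truth equality is a
meaningful dual-route check (plus a third, pure-Python brute force in the
tests).

## DUR engine

History lookback is **90 days**, boundary inclusive, with the
precipitating supply required to be still active
(`fill_date + days_supply ≥ screening date`); most US prescriptions carry
at most a 90-day supply, so older claims cannot still be active. The
exact lookback of production systems is unpublished; both parameters are
configurable. Same-day fills: a precipitating claim must be strictly
earlier, or same-day with a smaller claim id — a deterministic tie-break
that counts each unordered pair once. One alert is emitted per
(triggering, precipitating) pair, so a single incoming claim can raise
several alerts; all rate denominators count alerts, not claims.

## Identity linkage

UPI assignment is transitive closure (union-find) over ordered match
passes — default (1) normalized first + last + birth date + sex, (2) first
initial + last + birth date + postal code; normalization case-folds and
strips punctuation. Components are labelled by their smallest claim id
for run-to-run stability. Production matching algorithms are proprietary;
these documented passes are a transparent stand-in, and no probabilistic
(Fellegi–Sunter) scoring is used because the emulated systems are
deterministic. Linkage quality is scored by pairwise precision/recall of
claim co-assignment plus entity-level split/merge counts.

## Dispositions

The outcome window is **half-open** `(alert_date, alert_date + 14]`: the
triggering claim itself cannot resolve its own alert, since the alert is
the rejection of that fill (whether the study's window included day 0 is
unstated; this is our documented choice). OVERRIDE = same drug re-
dispensed (standing in for unobservable internal pharmacy review);
REPLACEMENT = different drug, same condition group (therapeutic
equivalence is operationalized by the catalog's explicit `condition_group`
map, and the replacement is not required to be non-interacting);
ABANDONMENT = neither. Precedence is OVERRIDE > REPLACEMENT; the
resolving claim is the earliest qualifying fill. Reported percentages
round half away from zero at one decimal (two where the source prints
two), which reproduces every printed figure from its printed
numerator/denominator.

## Projection

`P = 1/m − 1` with `m` the PBM's share of the US insured population. The
reference chain uses the printed `m = 0.165`; computed from the raw
inputs (49.7M / (328M × 91.5%)) the share is 16.56%, a ~0.06-point
discrepancy inherited from the source's own rounding. The published
"crossover alert percentage of 5.0%" matches the *additional* rate `c·P`
(= 4.98% at full precision), not the total-under-full-exchange rate `c/m`
(= 5.94%); both are exposed on `ProjectionResult` so the ambiguity is
explicit. The printed annual undetected total (22,730) is not exactly
recoverable from printed intermediates (full precision gives 22,822,
+0.4%); it is therefore carried as an input to the contraindicated-
dispensing step `D = U·(a + r)`, which reproduces the printed 6,023. The
weighted national annual volume (458,285) depends on unpublished age/sex
weights and is accepted as an input; `annualize_national_alerts` supports
direct standardization when a reference weight table is supplied, and
reduces to the unweighted `(n/years)/m` when the weights equal the
observed stratum shares. Internal computation keeps full precision;
rounding happens only at reporting.

## Statistics

Chi-square is Pearson without continuity correction (configurable); the t
test is Welch by default (whether the source pooled variances is
unstated). Logistic fits are maximum likelihood (statsmodels Newton,
gradient tolerance 1e-8) with Wald 95% intervals, matching the symmetric
printed CIs; separation or non-convergence raises an explicit error.
Calibration: a planted January effect (OR 2.4, n = 10^5, baseline event
rate ~1%) must be covered by the 95% CI with nominal frequency over 50
fixed seeds, judged at a 3-binomial-SD tolerance (≥ 43/50) — the honest
tolerance for that seed count.

## Problem sizes and determinism

Default test/acceptance sizes: 300-patient streams for unit oracles,
10^4 patients (~3×10^5 claims) for the set-difference identity, 20 seeds ×
700 patients per planted crossover share for parameter recovery, 50 seeds
× 10^5 observations for logistic calibration. All randomness flows from
one root seed through fixed per-stage substreams
(population / claims / perturbation), so identical configurations
reproduce byte-identical claim streams and report bundles (verified by
checksum manifest).

## Known limitations

* Synthetic demographics are drawn from small name pools and carry no
  real-world frequency structure; linkage error rates under perturbation
  say nothing quantitative about production matcher accuracy.
* Disposition proportions in synthetic streams are diluted by
  second-generation alerts (above).
* Benefit type is redrawn only at transitions and seasonality is decided
  by the patient's initial benefit; mid-life Medicaid churn profiles are
  therefore approximate.
* The projection is a point estimate; no interval is attached, matching
  the source analysis's scope.
* Pharmacologic realism of specific drug pairs, pricing/adjudication, and
  e-prescribing flows are out of scope.
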