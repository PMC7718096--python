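# crossalert

Crossover drug-drug interaction (DDI) alert analysis: how much safer is
prospective drug utilization review (DUR) when patient records are linked
by a **unique patient identifier (UPI)** instead of the payor-assigned
**beneficiary identifier**?

When a US patient changes insurance — new payor, new pharmacy benefit
manager (PBM), or a new member ID under the same PBM — their prescription
history fragments. A DUR system keyed on the beneficiary identifier treats
the patient as new and silently loses the medication history that would
have triggered a serious-DDI rejection. A DUR system keyed on a
demographically matched UPI keeps the history intact; the alerts it finds
*across* insurance identifiers are **crossover alerts**, and they measure
exactly what beneficiary-ID-only systems miss.

`crossalert` is aimed at health-services and pharmacoepidemiology
researchers. It provides:

* a **synthetic pharmacy-claims generator** with realistic payor/PBM churn
  (January-concentrated transitions; extra transitions at ages 19, 26 and
  65; benefit-type-specific seasonality; off-benefit "cash" fills for
  classes like erectile-dysfunction drugs), planted serious-DDI pairs, and
  a complete ground-truth ledger;
* **identity linkage** under both regimes — beneficiary-ID grouping and
  deterministic demographic matching (union-find over normalized match
  passes);
* a **DUR engine** that screens each claim against the active history of
  its identity (90-day lookback, active days' supply) and flags crossover
  alerts;
* **alert dispositions** — override / replacement / abandonment within a
  14-day window — and stratified rate tables (month, age, benefit type,
  therapeutic class, sex);
* the **national projection**: with the studied PBM covering a share `m`
  of the US insured population, the proportionality factor `P = 1/m − 1`
  scales the observed crossover rate `c` to the unobserved market; annual
  undetected alerts are `U = A·(c·P)` and contraindicated dispensings
  `D = U·(a + r)`, where `a`, `r` are the abandonment and replacement
  proportions;
* chi-square / Welch-t / logistic-regression tooling for covariate
  analysis of crossover status.

## Worked example

The projection chain, run on the reference figures of a 3-year
retrospective study of a national PBM serving 49.7 million patients
(16.5% of the US insured population, 242,646 serious-DDI alerts, 2,388 of
them crossover):

```
$ crossalert report
{
  "proportionality_factor": 5.06,
  "crossover_alert_pct": 0.98,
  "projected_additional_crossover_pct": 5.0,
  "january_crossover_pct": 1.9,
  "projected_january_crossover_pct": 9.6,
  "abandoned_pct": 16.5,
  "overridden_pct": 73.5,
  "replaced_pct": 10.0,
  "contraindicated_dispensings_annual": 6023,
  ...
}
```

Reading: a PBM with `m = 0.165` market share sees only within-book
transitions, so full identity linkage and record exchange would multiply
crossover alerts by `P = 1/0.165 − 1 = 5.06` — the observed 0.98% crossover
rate projects to 5.0% additional alerts (9.6% in January, when coverage
turns over). Applied to 458,285 annual national alerts and the printed
undetected total of 22,730, the 26.5% of alerts that would have been
abandoned or replaced yields ≈6,023 contraindicated dispensings per year
that better identification could prevent.

An end-to-end synthetic run:

```python
import crossalert as ca

patients, spans = ca.generate_population(2000, seed=7)
claims, truth   = ca.simulate_claims(patients, spans, seed=7)

upi  = ca.assign_upi_deterministic(claims)
bene = ca.link_by_beneficiary(claims)
ledger_upi  = ca.run_pdur(claims, upi,  ca.default_interactions())
ledger_bene = ca.run_pdur(claims, bene, ca.default_interactions())

print(len(ledger_upi), len(ledger_bene), int(ledger_upi.crossover.sum()))
# 9491 9207 284   -> the 284 UPI-only alerts are exactly the crossover alerts
```

The command line mirrors the pipeline stage by stage
(`crossalert simulate | link | screen | classify | estimate | report | all`);
`crossalert all --seed 7 --out run/` writes the full report bundle with a
checksum manifest.

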