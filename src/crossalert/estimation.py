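"""National extrapolation of undetected serious-DDI alerts, plus cohort attrition.

The extrapolation logic: a PBM covering a share ``m`` of the US insured
population observes crossover alerts only among patients transitioning
*within* its own book of business.  Under the assumption that patients
transition between PBMs at random, full identity linkage and record
exchange across the whole market would multiply observed crossover alerts
by the proportionality factor ``P = 1/m - 1`` (the uncovered-to-covered
population ratio).  Scaling the annual national alert volume ``A`` by the
projected additional crossover rate ``c * P`` gives the annual undetected
alerts ``U``; of those, only the share that would have been abandoned or
replaced (``a + r``) represents a prevented contraindicated dispensing
``D = U * (a + r)``.

Both the *additional* rate ``c * P`` and the *total under full exchange*
rate ``c / m`` are exposed; reported reference values match ``c * P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .alert_outcomes import percentage


@dataclass
class ProjectionInputs:
    n_alerts_total: int
    n_crossover: int
    study_years: float
    n_patients_covered: float
    us_population: float
    insured_fraction: float
    abandonment_prop: float
    replacement_prop: float
    national_annual_alerts: Optional[float] = None
    #: printed market share to use verbatim; computed from populations if None
    market_share_override: Optional[float] = None
    n_alerts_january: Optional[int] = None
    n_crossover_january: Optional[int] = None

    def validate(self) -> None:
        if self.n_crossover > self.n_alerts_total:
            raise ValueError("n_crossover exceeds n_alerts_total")
        for f in (self.insured_fraction, self.abandonment_prop, self.replacement_prop):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction out of [0,1]: {f}")


#: Reference figures from the motivating 3-year retrospective study of a
#: national PBM serving 49.7 million patients (2016-09 .. 2019-08).
REFERENCE_STUDY = ProjectionInputs(
    n_alerts_total=242_646,
    n_crossover=2_388,
    study_years=3,
    n_patients_covered=49.7e6,
    us_population=328e6,
    insured_fraction=0.915,
    abandonment_prop=0.165,
    replacement_prop=0.100,
    national_annual_alerts=458_285,  # age/sex-weighted figure, supplied as input
    market_share_override=0.165,
    n_alerts_january=21_801,
    n_crossover_january=414,
)

#: Reference disposition counts (override / replacement / abandonment of total).
REFERENCE_DISPOSITIONS = {
    "n_overridden": 178_239,
    "n_replaced": 24_279,
    "n_abandoned": 40_128,
    "n_total": 242_646,
    "n_crossover": 2_388,
    "n_crossover_abandoned": 527,
    "n_crossover_overridden": 1_688,
    "n_crossover_replaced": 173,
}

#: Reference chronic-therapy (atorvastatin/amlodipine, ages 38-48) cohorts.
REFERENCE_COHORTS = {
    "2017": {"n": 373_929, "absent": {"2018": 69_500, "2019": 117_069}},
    "2019": {"n": 412_101, "absent": {"2018": 76_222, "2017": 147_520}},
}

#: Annual undetected-alert figure as printed in the reference study (the
#: rounding path from its weighted inputs is not published; carried as an
#: input to the contraindicated-dispensing step).
REFERENCE_UNDETECTED_ANNUAL = 22_730


@dataclass(frozen=True)
class ProjectionResult:
    market_share: float
    proportionality_factor: float
    observed_crossover_rate: float
    projected_additional_rate: float
    projected_total_rate: float
    annual_national_alerts: float
    undetected_annual: float
    contraindicated_annual: float

    def as_dict(self) -> dict:
        return {
            "market_share": self.market_share,
            "proportionality_factor": self.proportionality_factor,
            "observed_crossover_rate": self.observed_crossover_rate,
            "projected_additional_rate": self.projected_additional_rate,
            "projected_total_rate": self.projected_total_rate,
            "annual_national_alerts": self.annual_national_alerts,
            "undetected_annual": self.undetected_annual,
            "contraindicated_annual": self.contraindicated_annual,
        }


def market_share(n_covered: float, us_population: float, insured_fraction: float) -> float:
    """Share of the US insured population covered by the studied PBM."""
    denom = us_population * insured_fraction
    if denom <= 0:
        raise ValueError("us_population * insured_fraction must be positive")
    return n_covered / denom


def proportionality_factor(m: float, round_to: Optional[int] = 2) -> float:
    """P = 1/m - 1: uncovered-to-covered ratio (reported to 2 decimals)."""
    if not (0 < m <= 1):
        raise ValueError(f"market share must be in (0, 1], got {m}")
    p = 1.0 / m - 1.0
    return round(p, round_to) if round_to is not None else p


def project_crossover_rate(c: float, P: float) -> float:
    """Additional crossover rate under full linkage and exchange: c * P."""
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"crossover rate out of [0,1]: {c}")
    return c * P


def annualize_national_alerts(
    n_alerts_total: float,
    study_years: float,
    m: float,
    stratum_alert_counts: Optional[Mapping] = None,
    covered_stratum_shares: Optional[Mapping] = None,
    reference_weights: Optional[Mapping] = None,
) -> float:
    """Annual national alert volume A, optionally directly standardized.

    Unweighted: ``A = (n_alerts_total / study_years) / m``.  With a
    reference weight table (stratum -> national population weight, summing
    to 1) plus observed per-stratum alert counts and the covered
    population's stratum shares, each stratum rate is scaled to national
    size and combined with the reference weights (direct standardization).
    Weights equal to the covered shares reproduce the unweighted figure.
    """
    if study_years <= 0:
        raise ValueError("study_years must be > 0")
    if reference_weights is None:
        return (n_alerts_total / study_years) / m
    if stratum_alert_counts is None or covered_stratum_shares is None:
        raise ValueError("weighted estimate needs stratum counts and covered shares")
    total_w = sum(reference_weights.values())
    if abs(total_w - 1.0) > 1e-9:
        raise ValueError(f"reference weights must sum to 1, got {total_w}")
    a = 0.0
    for k, w in reference_weights.items():
        share = covered_stratum_shares[k]
        if share <= 0:
            raise ValueError(f"covered share for stratum {k!r} must be positive")
        a += w * (stratum_alert_counts[k] / study_years) / (m * share)
    return a


def undetected_alerts(annual_alerts: float, projected_rate: float) -> float:
    """U = A * projected additional crossover rate."""
    if annual_alerts < 0 or projected_rate < 0:
        raise ValueError("inputs must be non-negative")
    return annual_alerts * projected_rate


def contraindicated_dispensings(
    undetected: float, abandonment_prop: float, replacement_prop: float
) -> int:
    """D = U * (a + r), the undetected alerts that would have changed therapy."""
    if abandonment_prop + replacement_prop > 1 + 1e-12:
        raise ValueError("abandonment + replacement proportions exceed 1")
    return int(round(undetected * (abandonment_prop + replacement_prop)))


def project(inputs: ProjectionInputs) -> ProjectionResult:
    """Run the full extrapolation chain from a set of projection inputs."""
    inputs.validate()
    m = (
        inputs.market_share_override
        if inputs.market_share_override is not None
        else market_share(
            inputs.n_patients_covered, inputs.us_population, inputs.insured_fraction
        )
    )
    P = proportionality_factor(m)
    c = (
        inputs.n_crossover / inputs.n_alerts_total if inputs.n_alerts_total else 0.0
    )
    additional = project_crossover_rate(c, P)
    total = c / m if inputs.n_alerts_total else 0.0
    A = (
        inputs.national_annual_alerts
        if inputs.national_annual_alerts is not None
        else annualize_national_alerts(inputs.n_alerts_total, inputs.study_years, m)
    )
    U = undetected_alerts(A, additional)
    D = contraindicated_dispensings(U, inputs.abandonment_prop, inputs.replacement_prop)
    return ProjectionResult(
        market_share=m,
        proportionality_factor=P,
        observed_crossover_rate=c,
        projected_additional_rate=additional,
        projected_total_rate=total,
        annual_national_alerts=A,
        undetected_annual=U,
        contraindicated_annual=D,
    )


@dataclass
class CohortSpec:
    """Chronic-therapy cohort: >= min_fills of the listed drugs in the index
    year, dispensed at ages within age_range."""

    drug_set: frozenset = frozenset({"ATO01", "AML01"})
    age_range: tuple = (38, 48)
    index_year: int = 2017
    min_fills: int = 2

    def validate(self) -> None:
        if self.min_fills < 1:
            raise ValueError("min_fills must be >= 1")
        if not self.drug_set:
            raise ValueError("drug_set must be non-empty")


def _age_at_fill(claims: pd.DataFrame) -> pd.Series:
    birth = pd.to_datetime(claims.birth_date)
    when = pd.to_datetime(claims.fill_date)
    years = when.dt.year - birth.dt.year
    before = (when.dt.month < birth.dt.month) | (
        (when.dt.month == birth.dt.month) & (when.dt.day < birth.dt.day)
    )
    return years - before.astype(int)


def select_cohort(
    claims: pd.DataFrame, linkage_map: pd.DataFrame, spec: CohortSpec
) -> list[str]:
    """Identities qualifying for the cohort, sorted for stable output."""
    spec.validate()
    df = claims.merge(linkage_map[["claim_id", "identity_key"]], on="claim_id")
    df = df[df.drug_id.isin(spec.drug_set)]
    df = df[pd.to_datetime(df.fill_date).dt.year == spec.index_year]
    age = _age_at_fill(df)
    lo, hi = spec.age_range
    df = df[(age >= lo) & (age <= hi)]
    counts = df.groupby("identity_key").size()
    return sorted(counts.index[counts >= spec.min_fills])


def attrition(
    cohort, claims: pd.DataFrame, linkage_map: pd.DataFrame, target_year: int
) -> float:
    """Fraction of the cohort with zero claims (any drug) in target_year."""
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    df = claims.merge(linkage_map[["claim_id", "identity_key"]], on="claim_id")
    present = set(
        df.loc[pd.to_datetime(df.fill_date).dt.year == target_year, "identity_key"]
    )
    absent = sum(1 for k in cohort if k not in present)
    return absent / len(cohort)


def worked_example_report() -> dict:
    """The reference study's printed extrapolation chain, recomputed.

    Every figure is derived at run time from the study's printed inputs
    (counts, the printed market share 0.165, the weighted annual volume,
    and the printed undetected total).  Percentages are rounded half away
    from zero at the printed precision.
    """
    s = REFERENCE_STUDY
    d = REFERENCE_DISPOSITIONS
    m = s.market_share_override
    P = proportionality_factor(m)
    c = s.n_crossover / s.n_alerts_total
    c_jan = s.n_crossover_january / s.n_alerts_january
    result = project(s)
    report = {
        "market_share_printed": m,
        "market_share_computed": market_share(
            s.n_patients_covered, s.us_population, s.insured_fraction
        ),
        "proportionality_factor": P,
        "crossover_alert_pct": percentage(s.n_crossover, s.n_alerts_total, 2),
        "projected_additional_crossover_pct": percentage(c * P, 1, 1),
        "january_crossover_pct": percentage(
            s.n_crossover_january, s.n_alerts_january, 1
        ),
        "projected_january_crossover_pct": percentage(c_jan * P, 1, 1),
        "abandoned_pct": percentage(d["n_abandoned"], d["n_total"], 1),
        "overridden_pct": percentage(d["n_overridden"], d["n_total"], 1),
        "replaced_pct": percentage(d["n_replaced"], d["n_total"], 1),
        "crossover_abandoned_pct": percentage(
            d["n_crossover_abandoned"], d["n_crossover"], 1
        ),
        "crossover_overridden_pct": percentage(
            d["n_crossover_overridden"], d["n_crossover"], 1
        ),
        "crossover_replaced_pct": percentage(
            d["n_crossover_replaced"], d["n_crossover"], 1
        ),
        "undetected_annual_alerts_printed": REFERENCE_UNDETECTED_ANNUAL,
        "undetected_annual_alerts_computed": round(result.undetected_annual),
        "contraindicated_dispensings_annual": contraindicated_dispensings(
            REFERENCE_UNDETECTED_ANNUAL, s.abandonment_prop, s.replacement_prop
        ),
    }
    for year, info in REFERENCE_COHORTS.items():
        for target, n_absent in info["absent"].items():
            report[f"cohort{year}_absent_{target}_pct"] = percentage(
                n_absent, info["n"], 1
            )
    return report
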