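"""Alert dispositions and stratified crossover/outcome rate tables.

Each serious-DDI alert resolves, within a 14-day window after the alert,
to one of three outcomes observed in subsequent claims of the same patient
identity:

* OVERRIDE — the same medication is dispensed anyway (internal pharmacy
  review let it through);
* REPLACEMENT — a different medication treating the same condition
  (same condition_group) is dispensed instead;
* ABANDONMENT — neither occurs: the therapy is dropped.

The window is half-open ``(alert_date, alert_date + window]``: the
triggering claim itself (day 0) never resolves its own alert, since the
alert is precisely the rejection of that fill.  OVERRIDE takes precedence
over REPLACEMENT when both qualifying fills exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import pandas as pd

OVERRIDE = "OVERRIDE"
REPLACEMENT = "REPLACEMENT"
ABANDONMENT = "ABANDONMENT"
OUTCOMES = (OVERRIDE, REPLACEMENT, ABANDONMENT)

DISPOSITION_COLUMNS = ["alert_id", "outcome", "resolving_claim_id"]


@dataclass
class OutcomeConfig:
    outcome_window: int = 14
    #: OVERRIDE matched on drug_id by default; set to match therapeutic_class.
    override_on_class: bool = False

    def validate(self) -> None:
        if self.outcome_window <= 0:
            raise ValueError("outcome_window must be > 0")


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage rounded half away from zero, as figures are reported."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(q, ROUND_HALF_UP)
    )


def classify_outcome(
    alert, identity_claims: pd.DataFrame, config: Optional[OutcomeConfig] = None
) -> dict:
    """Disposition of one alert from the claims of its (UPI) identity.

    Precedence is OVERRIDE > REPLACEMENT; the resolving claim is the
    earliest qualifying fill (ties by claim_id).  Returns a dict with
    alert_id, outcome and resolving_claim_id (None for ABANDONMENT).
    """
    config = config or OutcomeConfig()
    config.validate()
    alert_date = pd.Timestamp(alert["alert_date"])
    window_end = alert_date + pd.Timedelta(days=config.outcome_window)
    trig = identity_claims.loc[
        identity_claims.claim_id == alert["triggering_claim_id"]
    ].iloc[0]
    cand = identity_claims[
        (identity_claims.fill_date > alert_date)
        & (identity_claims.fill_date <= window_end)
    ].sort_values(["fill_date", "claim_id"], kind="mergesort")
    if config.override_on_class:
        same = cand[cand.therapeutic_class == trig.therapeutic_class]
    else:
        same = cand[cand.drug_id == trig.drug_id]
    if len(same):
        return {
            "alert_id": alert["alert_id"],
            "outcome": OVERRIDE,
            "resolving_claim_id": same.claim_id.iat[0],
        }
    repl = cand[
        (cand.condition_group == trig.condition_group) & (cand.drug_id != trig.drug_id)
    ]
    if len(repl):
        return {
            "alert_id": alert["alert_id"],
            "outcome": REPLACEMENT,
            "resolving_claim_id": repl.claim_id.iat[0],
        }
    return {"alert_id": alert["alert_id"], "outcome": ABANDONMENT, "resolving_claim_id": None}


def classify_outcomes(
    ledger: pd.DataFrame,
    claims: pd.DataFrame,
    linkage_map: pd.DataFrame,
    config: Optional[OutcomeConfig] = None,
) -> pd.DataFrame:
    """Disposition table covering every alert in the ledger.

    Vectorized equivalent of applying :func:`classify_outcome` to every
    alert against the claims of its identity.
    """
    config = config or OutcomeConfig()
    config.validate()
    if ledger.empty:
        return pd.DataFrame(columns=DISPOSITION_COLUMNS)
    linked = claims[
        ["claim_id", "fill_date", "drug_id", "therapeutic_class", "condition_group"]
    ].merge(linkage_map[["claim_id", "identity_key"]], on="claim_id")

    led = ledger[["alert_id", "triggering_claim_id", "alert_date"]].merge(
        linked.rename(
            columns={
                c: f"trig_{c}"
                for c in ("fill_date", "drug_id", "therapeutic_class", "condition_group")
            }
        ),
        left_on="triggering_claim_id",
        right_on="claim_id",
    ).drop(columns="claim_id")
    led["alert_date"] = pd.to_datetime(led["alert_date"])

    cand = led.merge(linked, on="identity_key")
    window_end = cand.alert_date + pd.Timedelta(days=config.outcome_window)
    cand = cand[(cand.fill_date > cand.alert_date) & (cand.fill_date <= window_end)]
    if config.override_on_class:
        is_override = cand.therapeutic_class == cand.trig_therapeutic_class
    else:
        is_override = cand.drug_id == cand.trig_drug_id
    is_repl = (cand.condition_group == cand.trig_condition_group) & (
        cand.drug_id != cand.trig_drug_id
    )
    cand = cand[is_override | is_repl].copy()
    cand["outcome"] = REPLACEMENT
    cand.loc[is_override.reindex(cand.index, fill_value=False), "outcome"] = OVERRIDE
    # precedence OVERRIDE > REPLACEMENT, then earliest fill, then claim_id
    cand["rank"] = (cand.outcome == REPLACEMENT).astype(int)
    cand = cand.sort_values(
        ["alert_id", "rank", "fill_date", "claim_id"], kind="mergesort"
    )
    best = cand.groupby("alert_id", sort=False).first().reset_index()

    out = ledger[["alert_id"]].merge(
        best[["alert_id", "outcome", "claim_id"]].rename(
            columns={"claim_id": "resolving_claim_id"}
        ),
        on="alert_id",
        how="left",
    )
    out["outcome"] = out.outcome.fillna(ABANDONMENT)
    out["resolving_claim_id"] = out.resolving_claim_id.where(out.outcome != ABANDONMENT, None)
    return out[DISPOSITION_COLUMNS]


def _age_at(birth: pd.Series, when: pd.Series) -> pd.Series:
    """Completed years of age at the event date."""
    years = when.dt.year - birth.dt.year
    before_birthday = (when.dt.month < birth.dt.month) | (
        (when.dt.month == birth.dt.month) & (when.dt.day < birth.dt.day)
    )
    return years - before_birthday.astype(int)


STRATA = ("overall", "month", "month_series", "benefit_type", "age", "therapeutic_class", "sex")


def tabulate_rates(
    ledger: pd.DataFrame,
    dispositions: pd.DataFrame,
    claims: pd.DataFrame,
    strata=STRATA,
) -> dict[str, pd.DataFrame]:
    """Crossover and disposition rates by stratum of the triggering claim.

    ``month`` aggregates calendar months 1-12 across years; ``month_series``
    keeps the full year-month sequence (the figure-style monthly series).
    Rates are returned as fractions; use :func:`percentage` for reporting.
    """
    if ledger.empty:
        cols = [
            "stratum", "n_alerts", "n_crossover", "n_override", "n_replacement",
            "n_abandonment", "crossover_rate", "p_override", "p_replacement",
            "p_abandonment",
        ]
        return {s: pd.DataFrame(columns=cols) for s in strata}
    df = (
        ledger.merge(dispositions, on="alert_id")
        .merge(
            claims[
                ["claim_id", "benefit_type", "birth_date", "sex",
                 "therapeutic_class", "fill_date"]
            ],
            left_on="triggering_claim_id",
            right_on="claim_id",
        )
    )
    df["alert_date"] = pd.to_datetime(df["alert_date"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["month"] = df.alert_date.dt.month
    df["month_series"] = df.alert_date.dt.to_period("M").astype(str)
    df["age"] = _age_at(df.birth_date, df.alert_date)
    df["overall"] = "all"

    out = {}
    for stratum in strata:
        g = df.groupby(stratum)
        tab = pd.DataFrame(
            {
                "n_alerts": g.size(),
                "n_crossover": g.crossover.sum(),
                "n_override": g.outcome.apply(lambda s: int((s == OVERRIDE).sum())),
                "n_replacement": g.outcome.apply(lambda s: int((s == REPLACEMENT).sum())),
                "n_abandonment": g.outcome.apply(lambda s: int((s == ABANDONMENT).sum())),
            }
        )
        tab["crossover_rate"] = tab.n_crossover / tab.n_alerts
        for o in ("override", "replacement", "abandonment"):
            tab[f"p_{o}"] = tab[f"n_{o}"] / tab.n_alerts
        tab.index.name = "stratum"
        out[stratum] = tab.reset_index()
    return out
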