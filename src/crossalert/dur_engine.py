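"""Prospective drug utilization review (DUR) over identity-linked histories.

Each incoming claim is screened against the prescription history of the
identity it maps to under a chosen linkage regime.  A serious interacting
pair in active history raises one alert per (triggering, precipitating)
claim pair; alerts whose two claims carry different (payor, beneficiary)
identifiers are *crossover* alerts — detectable only because the identity
regime linked records across insurance identifiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .catalog import InteractionTable

logger = logging.getLogger(__name__)

LEDGER_COLUMNS = [
    "alert_id", "triggering_claim_id", "precipitating_claim_id",
    "alert_date", "class_pair", "crossover", "regime",
]


@dataclass
class DurConfig:
    """Lookback rule for active prescription history.

    history_window
        Calendar days of lookback, boundary inclusive.  Defaults to 90 —
        most prescriptions are dispensed for at most a 90-day supply, so
        older precipitating claims cannot still be active.
    require_active_supply
        If set, a history fill only counts while its dispensed supply is
        still running (fill_date + days_supply >= screening date).
    """

    history_window: int = 90
    require_active_supply: bool = True

    def validate(self) -> None:
        if self.history_window <= 0:
            raise ValueError("history_window must be > 0")


def active_history(
    identity_claims: pd.DataFrame,
    as_of,
    config: Optional[DurConfig] = None,
    same_day_before: Optional[str] = None,
) -> pd.DataFrame:
    """Claims of one identity still pharmacologically relevant at ``as_of``.

    Keeps claims filled strictly before ``as_of``, no more than
    ``history_window`` days earlier, and (if ``require_active_supply``)
    whose supply is still running.  When ``same_day_before`` is given,
    same-day fills with a smaller claim_id are also admitted — the
    deterministic tie rule used when screening a claim against fills
    adjudicated the same day.
    """
    config = config or DurConfig()
    config.validate()
    as_of = pd.Timestamp(as_of)
    before = identity_claims.fill_date < as_of
    if same_day_before is not None:
        before |= (identity_claims.fill_date == as_of) & (
            identity_claims.claim_id < same_day_before
        )
    keep = before & (
        identity_claims.fill_date
        >= as_of - pd.to_timedelta(config.history_window, unit="D")
    )
    if config.require_active_supply:
        keep &= (
            identity_claims.fill_date
            + pd.to_timedelta(identity_claims.days_supply, unit="D")
            >= as_of
        )
    return identity_claims[keep]


def screen_claim(
    incoming, history: pd.DataFrame, interactions: InteractionTable
) -> list[dict]:
    """Serious-DDI alerts raised by one incoming claim against its history.

    Returns one alert dict per history claim whose therapeutic class forms a
    SERIOUS pair with the incoming claim's class, ordered by precipitating
    claim_id.  Unknown classes never alert (logged once per class).
    """
    cls = incoming["therapeutic_class"]
    if cls not in interactions.classes:
        logger.warning("unknown therapeutic class %r: no screening", cls)
        return []
    alerts = []
    for h in history.sort_values("claim_id").itertuples():
        if interactions.serious(cls, h.therapeutic_class):
            alerts.append(
                {
                    "triggering_claim_id": incoming["claim_id"],
                    "precipitating_claim_id": h.claim_id,
                    "alert_date": pd.Timestamp(incoming["fill_date"]),
                    "class_pair": "|".join(sorted((cls, h.therapeutic_class))),
                    "crossover": int(
                        (incoming["payor_id"], incoming["beneficiary_id"])
                        != (h.payor_id, h.beneficiary_id)
                    ),
                }
            )
    return alerts


def flag_crossover(triggering, precipitating) -> bool:
    """True iff the two claims carry different (payor, beneficiary) identifiers."""
    return (triggering["payor_id"], triggering["beneficiary_id"]) != (
        precipitating["payor_id"],
        precipitating["beneficiary_id"],
    )


def run_pdur(
    claims: pd.DataFrame,
    linkage_map: pd.DataFrame,
    interactions: InteractionTable,
    config: Optional[DurConfig] = None,
) -> pd.DataFrame:
    """Screen a whole claim stream under one linkage regime.

    Claims are processed in fill-date order (ties by claim_id) within each
    identity; every serious pair in active history yields one alert.  The
    returned ledger is deterministic and idempotent for identical input.
    """
    config = config or DurConfig()
    config.validate()
    regime = str(linkage_map["regime"].iat[0]) if len(linkage_map) else "UPI"
    window = pd.Timedelta(days=config.history_window)

    df = claims[
        ["claim_id", "fill_date", "therapeutic_class", "days_supply",
         "payor_id", "beneficiary_id"]
    ].merge(linkage_map[["claim_id", "identity_key"]], on="claim_id")
    df = df[df.therapeutic_class.isin(interactions.classes)]
    df = df.sort_values(["fill_date", "claim_id"], kind="mergesort")

    rows = []
    for _, grp in df.groupby("identity_key", sort=False):
        hist: list[tuple] = []  # (fill_date, claim_id, class, supply_end, payor, bene)
        for r in grp.itertuples():
            # expire claims beyond the lookback window
            cutoff = r.fill_date - window
            while hist and hist[0][0] < cutoff:
                hist.pop(0)
            for h_date, h_id, h_cls, h_end, h_payor, h_bene in hist:
                if config.require_active_supply and h_end < r.fill_date:
                    continue
                if interactions.serious(r.therapeutic_class, h_cls):
                    rows.append(
                        (
                            r.claim_id, h_id, r.fill_date,
                            "|".join(sorted((r.therapeutic_class, h_cls))),
                            int((r.payor_id, r.beneficiary_id) != (h_payor, h_bene)),
                        )
                    )
            hist.append(
                (
                    r.fill_date, r.claim_id, r.therapeutic_class,
                    r.fill_date + pd.Timedelta(days=int(r.days_supply)),
                    r.payor_id, r.beneficiary_id,
                )
            )

    ledger = pd.DataFrame(
        rows,
        columns=[
            "triggering_claim_id", "precipitating_claim_id", "alert_date",
            "class_pair", "crossover",
        ],
    )
    ledger = ledger.sort_values(
        ["alert_date", "triggering_claim_id", "precipitating_claim_id"],
        kind="mergesort",
    ).reset_index(drop=True)
    ledger["alert_id"] = [f"A{i:08d}" for i in range(len(ledger))]
    ledger["regime"] = regime
    return ledger[LEDGER_COLUMNS]
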