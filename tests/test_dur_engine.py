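"""DUR screening against quadratic all-pairs oracles and set properties."""

import numpy as np
import pandas as pd
import pytest

import crossalert as ca
from crossalert.dur_engine import DurConfig, active_history, screen_claim

from conftest import build_claims


def _pair_set(ledger):
    return set(zip(ledger.triggering_claim_id, ledger.precipitating_claim_id))


def _brute_force_ledger(claims, identity, interactions, window=90, active=True):
    """Independent quadratic oracle over identity groups."""
    out = set()
    rows = claims.to_dict("records")
    for t in rows:
        for p in rows:
            if identity[t["claim_id"]] != identity[p["claim_id"]]:
                continue
            earlier = p["fill_date"] < t["fill_date"] or (
                p["fill_date"] == t["fill_date"] and p["claim_id"] < t["claim_id"]
            )
            if not earlier:
                continue
            if (t["fill_date"] - p["fill_date"]).days > window:
                continue
            if active and p["fill_date"] + pd.Timedelta(days=p["days_supply"]) < t["fill_date"]:
                continue
            if interactions.serious(t["therapeutic_class"], p["therapeutic_class"]):
                out.add((t["claim_id"], p["claim_id"]))
    return out


class TestActiveHistory:
    def test_expired_window_excluded(self):
        claims = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01", "days_supply": 30}]
        )
        hist = active_history(claims, "2017-04-11")  # 100 days later
        assert hist.empty

    def test_recent_active_included(self):
        claims = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01", "days_supply": 30}]
        )
        hist = active_history(claims, "2017-01-11")
        assert list(hist.claim_id) == ["C0"]

    def test_supply_lapsed_excluded_when_required(self):
        claims = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01", "days_supply": 10}]
        )
        assert active_history(claims, "2017-02-01").empty
        cfg = DurConfig(require_active_supply=False)
        assert len(active_history(claims, "2017-02-01", cfg)) == 1

    def test_randomized_equals_predicate_filter(self):
        rng = np.random.default_rng(5)
        claims = build_claims(
            [
                {
                    "claim_id": f"C{i:02d}",
                    "fill_date": str(
                        pd.Timestamp("2017-01-01") + pd.Timedelta(days=int(d))
                    ),
                    "days_supply": int(s),
                }
                for i, (d, s) in enumerate(
                    zip(rng.integers(0, 200, 50), rng.integers(5, 95, 50))
                )
            ]
        )
        as_of = pd.Timestamp("2017-05-01")
        got = set(active_history(claims, as_of).claim_id)
        expect = {
            r["claim_id"]
            for r in claims.to_dict("records")
            if r["fill_date"] < as_of
            and r["fill_date"] >= as_of - pd.Timedelta(days=90)
            and r["fill_date"] + pd.Timedelta(days=r["days_supply"]) >= as_of
        }
        assert got == expect


class TestScreenClaim:
    def test_serious_pair_alerts(self):
        history = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01", "drug_id": "ATO01",
              "therapeutic_class": "statin", "days_supply": 90}]
        )
        incoming = build_claims(
            [{"claim_id": "C1", "fill_date": "2017-01-10"}]
        ).iloc[0]
        alerts = screen_claim(incoming, history, ca.default_interactions())
        assert len(alerts) == 1
        assert alerts[0]["class_pair"] == "macrolide|statin"

    def test_empty_history_no_alert(self):
        incoming = build_claims([{"claim_id": "C1", "fill_date": "2017-01-10"}]).iloc[0]
        history = build_claims([{"claim_id": "C0", "fill_date": "2017-01-01"}]).iloc[:0]
        assert screen_claim(incoming, history, ca.default_interactions()) == []

    def test_unknown_class_no_alert(self, caplog):
        history = build_claims([{"claim_id": "C0", "fill_date": "2017-01-01"}])
        incoming = build_claims(
            [{"claim_id": "C1", "fill_date": "2017-01-05",
              "therapeutic_class": "experimental"}]
        ).iloc[0]
        with caplog.at_level("WARNING"):
            assert screen_claim(incoming, history, ca.default_interactions()) == []
        assert "unknown therapeutic class" in caplog.text

    def test_multiple_interacting_history_claims(self):
        """Three interacting entries among twenty -> three alerts, as all-pairs."""
        interactions = ca.default_interactions()
        rows = [
            {"claim_id": f"C{i:02d}", "fill_date": f"2017-01-{i + 1:02d}",
             "drug_id": "CET01", "therapeutic_class": "antihistamine",
             "days_supply": 30}
            for i in range(17)
        ]
        for j, i in enumerate((17, 18, 19)):
            rows.append(
                {"claim_id": f"C{i:02d}", "fill_date": f"2017-01-{i + 1:02d}",
                 "drug_id": "ATO01", "therapeutic_class": "statin",
                 "days_supply": 90}
            )
        history = build_claims(rows)
        incoming = build_claims(
            [{"claim_id": "C99", "fill_date": "2017-01-25"}]
        ).iloc[0]
        alerts = screen_claim(incoming, history, interactions)
        assert [a["precipitating_claim_id"] for a in alerts] == ["C17", "C18", "C19"]


class TestRunPdur:
    def test_upi_ledger_superset_of_beneficiary(self, small_ledgers):
        assert _pair_set(small_ledgers["ledger_bene"]) <= _pair_set(
            small_ledgers["ledger_upi"]
        )

    def test_no_interacting_pairs_empty_ledger(self, interactions):
        claims = build_claims(
            [
                {"claim_id": f"C{i}", "fill_date": f"2017-01-{i + 1:02d}",
                 "drug_id": "CET01", "therapeutic_class": "antihistamine"}
                for i in range(10)
            ]
        )
        ledger = ca.run_pdur(claims, ca.link_by_beneficiary(claims), interactions)
        assert ledger.empty

    def test_recovers_ground_truth_under_upi(self, small_sim, small_ledgers):
        truth = small_sim["truth"]
        ledger = small_ledgers["ledger_upi"]
        got = ledger[["triggering_claim_id", "precipitating_claim_id", "crossover"]]
        got = got.sort_values(
            ["triggering_claim_id", "precipitating_claim_id"]
        ).reset_index(drop=True)
        expect = truth.sort_values(
            ["triggering_claim_id", "precipitating_claim_id"]
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expect)

    def test_equals_brute_force_on_small_instance(self, interactions):
        patients, spans = ca.generate_population(40, seed=21)
        claims, _ = ca.simulate_claims(
            patients, spans, seed=21, background_rate=6.0
        )
        assert len(claims) <= 1000
        m = ca.assign_upi_deterministic(claims)
        identity = dict(zip(m.claim_id, m.identity_key))
        ledger = ca.run_pdur(claims, m, interactions)
        assert _pair_set(ledger) == _brute_force_ledger(claims, identity, interactions)

    def test_idempotent(self, small_sim, small_ledgers, interactions):
        again = ca.run_pdur(
            small_sim["claims"], small_ledgers["map_upi"], interactions
        )
        pd.testing.assert_frame_equal(again, small_ledgers["ledger_upi"])


class TestFlagCrossover:
    def test_same_identifier_not_crossover(self):
        claims = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01"},
             {"claim_id": "C1", "fill_date": "2017-01-05"}]
        )
        assert not ca.flag_crossover(claims.iloc[1], claims.iloc[0])

    def test_prior_payor_is_crossover(self):
        claims = build_claims(
            [{"claim_id": "C0", "fill_date": "2017-01-01", "payor_id": "PAY8",
              "beneficiary_id": "B8"},
             {"claim_id": "C1", "fill_date": "2017-01-05"}]
        )
        assert ca.flag_crossover(claims.iloc[1], claims.iloc[0])

    def test_ledger_flags_match_ground_truth(self, small_sim, small_ledgers):
        truth = small_sim["truth"]
        ledger = small_ledgers["ledger_upi"]
        t = dict(
            zip(
                zip(truth.triggering_claim_id, truth.precipitating_claim_id),
                truth.crossover,
            )
        )
        for row in ledger.itertuples():
            assert t[(row.triggering_claim_id, row.precipitating_claim_id)] == row.crossover
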