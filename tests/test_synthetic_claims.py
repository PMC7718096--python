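"""Generator behavior: churn, planting, perturbation, ground-truth completeness."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import crossalert as ca
from crossalert.catalog import INERT_CLASSES

from conftest import build_claims


def _hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df.astype(str), index=False).values.tobytes()
    ).hexdigest()


class TestGeneratePopulation:
    def test_zero_churn_single_span(self):
        cfg = ca.ChurnConfig(annual_transition_prob=0.0, age_triggers={})
        _, spans = ca.generate_population(1, cfg, seed=7)
        assert len(spans) == 1
        assert spans.start_date.iat[0] == pd.Timestamp(ca.HORIZON_START)
        assert spans.end_date.iat[0] == pd.Timestamp(ca.HORIZON_END)

    def test_forced_january_boundary(self):
        cfg = ca.ChurnConfig(
            annual_transition_prob=1.0,
            january_concentration=1.0,
            age_triggers={},
            benefit_mix={"OTHER": 1.0},
        )
        _, spans = ca.generate_population(400, cfg, seed=7)
        jan1 = spans[spans.start_date.dt.month.eq(1) & spans.start_date.dt.day.eq(1)]
        assert set(jan1.true_patient_key) == set(spans.true_patient_key)

    def test_annual_transition_fraction(self):
        """Empirical boundary rate per patient-year within 3 binomial SDs of 0.3."""
        p, n, years = 0.3, 10_000, 3
        cfg = ca.ChurnConfig(annual_transition_prob=p, age_triggers={})
        _, spans = ca.generate_population(n, cfg, seed=7)
        n_boundaries = len(spans) - n  # spans per patient = transitions + 1
        frac = n_boundaries / (n * years)
        sd = np.sqrt(p * (1 - p) / (n * years))
        assert abs(frac - p) < 3 * sd

    def test_spans_partition_horizon(self):
        cfg = ca.ChurnConfig(annual_transition_prob=0.8)
        _, spans = ca.generate_population(50, cfg, seed=3)
        for _, g in spans.groupby("true_patient_key"):
            g = g.sort_values("start_date")
            assert g.start_date.iat[0] == pd.Timestamp(ca.HORIZON_START)
            assert g.end_date.iat[-1] == pd.Timestamp(ca.HORIZON_END)
            assert (g.start_date <= g.end_date).all()
            gaps = g.start_date.iloc[1:].values - g.end_date.iloc[:-1].values
            assert (gaps == np.timedelta64(1, "D")).all()

    def test_beneficiary_changes_with_payor(self):
        cfg = ca.ChurnConfig(annual_transition_prob=0.9)
        _, spans = ca.generate_population(150, cfg, seed=5)
        for _, g in spans.groupby("true_patient_key"):
            g = g.sort_values("start_date")
            payor_changed = g.payor_id.iloc[1:].values != g.payor_id.iloc[:-1].values
            bene_changed = (
                g.beneficiary_id.iloc[1:].values != g.beneficiary_id.iloc[:-1].values
            )
            assert (bene_changed | ~payor_changed).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ca.ConfigurationError):
            ca.generate_population(1, ca.ChurnConfig(annual_transition_prob=1.5))


class TestSimulateClaims:
    def test_planted_pair_same_span_not_crossover(self, interactions):
        claims = build_claims(
            [
                {"claim_id": "C0", "fill_date": "2017-03-01", "drug_id": "ATO01",
                 "therapeutic_class": "statin", "condition_group": "lipid_control",
                 "days_supply": 30},
                {"claim_id": "C1", "fill_date": "2017-03-11"},  # macrolide, day 10
            ]
        )
        truth = ca.ground_truth_alerts(claims, interactions)
        assert len(truth) == 1
        assert truth.crossover.iat[0] == 0
        assert truth.triggering_claim_id.iat[0] == "C1"

    def test_planted_pair_across_payors_is_crossover(self, interactions):
        claims = build_claims(
            [
                {"claim_id": "C0", "fill_date": "2017-03-01", "drug_id": "ATO01",
                 "therapeutic_class": "statin", "condition_group": "lipid_control",
                 "days_supply": 30},
                {"claim_id": "C1", "fill_date": "2017-03-11",
                 "payor_id": "PAY9", "beneficiary_id": "B9"},
            ]
        )
        truth = ca.ground_truth_alerts(claims, interactions)
        assert len(truth) == 1
        assert truth.crossover.iat[0] == 1

    def test_zero_plant_rate_inert_background_empty_truth(self, catalog, interactions):
        patients, spans = ca.generate_population(100, seed=7)
        _, truth = ca.simulate_claims(
            patients, spans, catalog, interactions,
            ddi_plant_rate=0.0, background_classes=INERT_CLASSES, seed=7,
        )
        assert truth.empty

    def test_determinism(self, catalog, interactions):
        outs = []
        for _ in range(2):
            patients, spans = ca.generate_population(120, seed=9)
            claims, truth = ca.simulate_claims(
                patients, spans, catalog, interactions, seed=9
            )
            outs.append((_hash(claims), _hash(truth)))
        assert outs[0] == outs[1]

    def test_claims_conserved_within_spans(self, small_sim):
        """Every fill date lies inside exactly one span of its true patient."""
        claims, spans = small_sim["claims"], small_sim["spans"]
        merged = claims[["claim_id", "true_patient_key", "fill_date"]].merge(
            spans[["true_patient_key", "start_date", "end_date"]],
            on="true_patient_key",
        )
        inside = merged[
            (merged.fill_date >= merged.start_date)
            & (merged.fill_date <= merged.end_date)
        ]
        counts = inside.groupby("claim_id").size()
        assert len(counts) == len(claims)
        assert (counts == 1).all()

    def test_truth_matches_brute_force_scan(self, small_sim, interactions):
        """All-pairs scan grouped by true patient reproduces the truth ledger."""
        claims, truth = small_sim["claims"], small_sim["truth"]
        expect = set()
        for _, g in claims.groupby("true_patient_key"):
            rows = g.to_dict("records")
            for t in rows:
                for p in rows:
                    earlier = p["fill_date"] < t["fill_date"] or (
                        p["fill_date"] == t["fill_date"]
                        and p["claim_id"] < t["claim_id"]
                    )
                    if not earlier:
                        continue
                    if (t["fill_date"] - p["fill_date"]).days > 90:
                        continue
                    if (
                        p["fill_date"] + pd.Timedelta(days=p["days_supply"])
                        < t["fill_date"]
                    ):
                        continue
                    if interactions.serious(
                        t["therapeutic_class"], p["therapeutic_class"]
                    ):
                        cross = (t["payor_id"], t["beneficiary_id"]) != (
                            p["payor_id"], p["beneficiary_id"]
                        )
                        expect.add((t["claim_id"], p["claim_id"], int(cross)))
        got = set(
            zip(truth.triggering_claim_id, truth.precipitating_claim_id, truth.crossover)
        )
        assert got == expect


class TestPerturbDemographics:
    def test_zero_rate_identity(self, small_sim):
        claims = small_sim["claims"]
        out = ca.perturb_demographics(claims, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, claims)

    def test_rate_one_alters_every_record(self, small_sim):
        claims = small_sim["claims"].head(500)
        out = ca.perturb_demographics(claims, 1.0, seed=1)
        changed = (
            (out.first_name != claims.first_name)
            | (out.last_name != claims.last_name)
            | (out.postal_code != claims.postal_code)
            | (out.birth_date != claims.birth_date)
        )
        assert changed.all()

    def test_altered_fraction_matches_expectation(self, small_sim):
        """P(record altered) = 1 - (1-r)^4 over the four perturbed fields."""
        claims = small_sim["claims"]
        n = len(claims)
        assert n >= 5000
        r = 0.05
        out = ca.perturb_demographics(claims, r, seed=2)
        changed = (
            (out.first_name != claims.first_name)
            | (out.last_name != claims.last_name)
            | (out.postal_code != claims.postal_code)
            | (out.birth_date != claims.birth_date)
        )
        p = 1 - (1 - r) ** 4
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(changed.mean() - p) < 3 * sd

    def test_truth_key_untouched(self, small_sim):
        claims = small_sim["claims"]
        out = ca.perturb_demographics(claims, 1.0, seed=3)
        assert (out.true_patient_key == claims.true_patient_key).all()
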