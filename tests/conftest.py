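import pandas as pd
import pytest

import crossalert as ca

DEFAULT_ROW = {
    "beneficiary_id": "B0",
    "payor_id": "PAY0",
    "pbm_id": "PBM0",
    "benefit_type": "OTHER",
    "first_name": "Ann",
    "last_name": "Smith",
    "birth_date": "1970-01-15",
    "sex": "F",
    "postal_code": "63101",
    "drug_id": "AZI01",
    "therapeutic_class": "macrolide",
    "condition_group": "antibiotic",
    "days_supply": 10,
    "pharmacy_id": "PH000",
    "true_patient_key": "P0",
}


def build_claims(rows: list[dict]) -> pd.DataFrame:
    """Hand-crafted claim frame; unspecified fields take shared defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(DEFAULT_ROW)
        r.setdefault("claim_id", f"C{i:08d}")
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full)
    if "claim_id" not in df or df.claim_id.isna().any():
        raise ValueError("every row needs a claim_id")
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["fill_date"] = pd.to_datetime(df["fill_date"])
    return df


@pytest.fixture(scope="session")
def interactions():
    return ca.default_interactions()


@pytest.fixture(scope="session")
def catalog():
    return ca.default_catalog()


@pytest.fixture(scope="session")
def small_sim(interactions, catalog):
    """A 300-patient organic-mode stream with ground truth (seed 42)."""
    patients, spans = ca.generate_population(300, seed=42)
    claims, truth = ca.simulate_claims(patients, spans, catalog, interactions, seed=42)
    return {"patients": patients, "spans": spans, "claims": claims, "truth": truth}


@pytest.fixture(scope="session")
def small_ledgers(small_sim, interactions):
    claims = small_sim["claims"]
    map_bene = ca.link_by_beneficiary(claims)
    map_upi = ca.assign_upi_deterministic(claims)
    return {
        "map_bene": map_bene,
        "map_upi": map_upi,
        "ledger_bene": ca.run_pdur(claims, map_bene, interactions),
        "ledger_upi": ca.run_pdur(claims, map_upi, interactions),
    }
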