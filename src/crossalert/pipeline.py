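"""End-to-end orchestration: simulate -> link -> screen -> classify -> estimate.

`run_pipeline` executes the whole chain on a synthetic claim stream and
writes the full report bundle (claims, linkage maps and alert ledgers under
both identity regimes, dispositions, stratified rate tables, projection
report, and a checksum manifest).  Each stage also stands alone behind its
CSV contract, so the CLI subcommands can run them independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .alert_outcomes import OutcomeConfig, classify_outcomes, tabulate_rates
from .catalog import DrugCatalog, InteractionTable, default_catalog, default_interactions
from .dur_engine import DurConfig, run_pdur
from .estimation import (
    ProjectionInputs,
    project,
    worked_example_report,
)
from .identity_linkage import assign_upi_deterministic, link_by_beneficiary
from .synthetic_claims import (
    HORIZON_END,
    HORIZON_START,
    ChurnConfig,
    generate_population,
    perturb_demographics,
    simulate_claims,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    seed: int = 0
    n_patients: int = 2000
    horizon_start: str = str(HORIZON_START)
    horizon_end: str = str(HORIZON_END)
    background_rate: float = 9.6
    ddi_plant_rate: float = 0.05
    typo_rate: float = 0.0
    churn: ChurnConfig = field(default_factory=ChurnConfig)
    dur: DurConfig = field(default_factory=DurConfig)
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    #: projection context for the synthetic stream: market share of the
    #: simulated PBM within its notional market, and the national scale.
    market_share: float = 0.165
    out_dir: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        for key, sub in (("churn", ChurnConfig), ("dur", DurConfig), ("outcome", OutcomeConfig)):
            if key in raw and isinstance(raw[key], dict):
                d = raw[key]
                if key == "churn" and "age_triggers" in d:
                    d["age_triggers"] = {int(k): v for k, v in d["age_triggers"].items()}
                raw[key] = sub(**d)
        return cls(**raw)


def run_pipeline(
    config: RunConfig,
    catalog: Optional[DrugCatalog] = None,
    interactions: Optional[InteractionTable] = None,
) -> dict:
    """Execute the full study pipeline; returns all artifacts in memory.

    When ``config.out_dir`` is set the bundle is also written to disk with a
    manifest of SHA-256 checksums; identical configs reproduce identical
    bytes.
    """
    catalog = catalog or default_catalog()
    interactions = interactions or default_interactions()

    logger.info("stage=simulate n_patients=%d seed=%d", config.n_patients, config.seed)
    patients, spans = generate_population(
        config.n_patients,
        config.churn,
        seed=config.seed,
        horizon=(config.horizon_start, config.horizon_end),
    )
    claims, truth = simulate_claims(
        patients,
        spans,
        catalog,
        interactions,
        ddi_plant_rate=config.ddi_plant_rate,
        background_rate=config.background_rate,
        churn_config=config.churn,
        dur_config=config.dur,
        seed=config.seed,
    )
    if config.typo_rate:
        claims = perturb_demographics(claims, config.typo_rate, seed=config.seed)
    logger.info("stage=simulate claims=%d truth_alerts=%d", len(claims), len(truth))

    map_bene = link_by_beneficiary(claims)
    map_upi = assign_upi_deterministic(claims)
    logger.info(
        "stage=link identities_beneficiary=%d identities_upi=%d",
        map_bene.identity_key.nunique(), map_upi.identity_key.nunique(),
    )

    ledger_bene = run_pdur(claims, map_bene, interactions, config.dur)
    ledger_upi = run_pdur(claims, map_upi, interactions, config.dur)
    n_cross = int(ledger_upi.crossover.sum())
    logger.info(
        "stage=screen alerts_beneficiary=%d alerts_upi=%d crossover=%d",
        len(ledger_bene), len(ledger_upi), n_cross,
    )

    dispositions = classify_outcomes(ledger_upi, claims, map_upi, config.outcome)
    rates = tabulate_rates(ledger_upi, dispositions, claims)

    overall = rates["overall"]
    if len(overall):
        row = overall.iloc[0]
        a_prop = float(row.p_abandonment)
        r_prop = float(row.p_replacement)
    else:
        a_prop = r_prop = 0.0
    years = (
        pd.Timestamp(config.horizon_end) - pd.Timestamp(config.horizon_start)
    ).days / 365.25
    inputs = ProjectionInputs(
        n_alerts_total=len(ledger_upi),
        n_crossover=n_cross,
        study_years=years,
        n_patients_covered=config.n_patients,
        us_population=config.n_patients / max(config.market_share, 1e-12),
        insured_fraction=1.0,
        abandonment_prop=a_prop,
        replacement_prop=r_prop,
        market_share_override=config.market_share,
    )
    projection = project(inputs)

    result = {
        "patients": patients,
        "spans": spans,
        "claims": claims,
        "truth": truth,
        "linkage": {"BENEFICIARY": map_bene, "UPI": map_upi},
        "ledger": {"BENEFICIARY": ledger_bene, "UPI": ledger_upi},
        "dispositions": dispositions,
        "rates": rates,
        "projection": projection,
    }

    if config.out_dir:
        _write_bundle(result, config)
    return result


def _write_bundle(result: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    def emit(name, df):
        path = io.write_table(df, out / name)
        files[name] = io.sha256_file(path)

    io.write_claims(result["claims"], out / "claims.csv")
    files["claims.csv"] = io.sha256_file(out / "claims.csv")
    emit("truth_patients.csv", result["claims"][["claim_id", "true_patient_key"]])
    emit("spans.csv", result["spans"])
    emit("truth_alerts.csv", result["truth"])
    emit("linkage_beneficiary.csv", result["linkage"]["BENEFICIARY"])
    emit("linkage_upi.csv", result["linkage"]["UPI"])
    emit("alerts_beneficiary.csv", result["ledger"]["BENEFICIARY"])
    emit("alerts_upi.csv", result["ledger"]["UPI"])
    emit("dispositions.csv", result["dispositions"])
    for stratum, tab in result["rates"].items():
        emit(f"rates_{stratum}.csv", tab)

    proj_path = out / "projection.json"
    proj_path.write_text(
        json.dumps(result["projection"].as_dict(), indent=2, sort_keys=True) + "\n"
    )
    files["projection.json"] = io.sha256_file(proj_path)

    manifest = {
        "package": "crossalert",
        "version": __version__,
        "config": json.loads(config.to_json()),
        "files": files,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


__all__ = ["RunConfig", "run_pipeline", "worked_example_report"]
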