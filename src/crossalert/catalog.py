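"""Drug catalog and serious drug-drug interaction table.

The catalog maps each dispensable product to a therapeutic class (the unit at
which interactions are declared) and a condition group (the unit at which a
later fill counts as a *replacement* therapy).  The interaction table is a
symmetric set of class pairs flagged SERIOUS; only serious pairs are screened
by the DUR engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SERIOUS = "SERIOUS"

CATALOG_COLUMNS = ["drug_id", "therapeutic_class", "typical_days_supply", "condition_group"]
INTERACTION_COLUMNS = ["class_a", "class_b", "severity"]


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    therapeutic_class: str
    typical_days_supply: int
    condition_group: str


class DrugCatalog:
    """Immutable lookup from drug_id to class / supply / condition group."""

    def __init__(self, records: list[DrugRecord]):
        ids = [r.drug_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate drug_id in catalog")
        self._records = {r.drug_id: r for r in records}

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self._records

    def __getitem__(self, drug_id: str) -> DrugRecord:
        return self._records[drug_id]

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self._records)

    @property
    def classes(self) -> set[str]:
        return {r.therapeutic_class for r in self._records.values()}

    def drugs_in_class(self, therapeutic_class: str) -> list[str]:
        return sorted(
            r.drug_id for r in self._records.values() if r.therapeutic_class == therapeutic_class
        )

    def drugs_in_classes(self, classes) -> list[str]:
        wanted = set(classes)
        return sorted(
            r.drug_id for r in self._records.values() if r.therapeutic_class in wanted
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.drug_id, r.therapeutic_class, r.typical_days_supply, r.condition_group)
            for r in sorted(self._records.values(), key=lambda r: r.drug_id)
        ]
        return pd.DataFrame(rows, columns=CATALOG_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DrugCatalog":
        return cls(
            [
                DrugRecord(
                    str(row.drug_id),
                    str(row.therapeutic_class),
                    int(row.typical_days_supply),
                    str(row.condition_group),
                )
                for row in frame.itertuples()
            ]
        )


class InteractionTable:
    """Symmetric serious class-pair table: (a, b) present implies (b, a) resolvable."""

    def __init__(self, pairs):
        self._pairs: set[frozenset] = set()
        for entry in pairs:
            a, b = entry[0], entry[1]
            severity = entry[2] if len(entry) > 2 else SERIOUS
            if a == b:
                raise ValueError(f"self-pair not allowed: {a}")
            if severity != SERIOUS:
                # carried for extensibility; only SERIOUS pairs are stored/screened
                continue
            self._pairs.add(frozenset((a, b)))
        if not self._pairs:
            raise ValueError("interaction table is empty")
        self._classes = {c for p in self._pairs for c in p}

    def __len__(self) -> int:
        return len(self._pairs)

    @property
    def classes(self) -> set[str]:
        return set(self._classes)

    def serious(self, class_a: str, class_b: str) -> bool:
        return frozenset((class_a, class_b)) in self._pairs

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(tuple(sorted(p)) for p in self._pairs)
        return pd.DataFrame(
            [(a, b, SERIOUS) for a, b in rows], columns=INTERACTION_COLUMNS
        )

    def symmetric_frame(self) -> pd.DataFrame:
        """Both orientations of every pair, convenient for merge-based scans."""
        rows = []
        for p in self._pairs:
            a, b = sorted(p)
            rows.append((a, b))
            rows.append((b, a))
        return pd.DataFrame(sorted(rows), columns=["class_a", "class_b"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InteractionTable":
        return cls(
            [
                (str(r.class_a), str(r.class_b), str(getattr(r, "severity", SERIOUS)))
                for r in frame.itertuples()
            ]
        )


# Non-interacting classes, usable as a neutral background for controlled runs.
INERT_CLASSES = ("antihistamine", "ppi", "ssri", "biguanide")

_DEFAULT_DRUGS = [
    # antibiotics
    ("AZI01", "macrolide", 10, "antibiotic"),
    ("CLA01", "macrolide", 14, "antibiotic"),
    ("CIP01", "quinolone", 10, "antibiotic"),
    ("LEV01", "quinolone", 10, "antibiotic"),
    # opioids
    ("TRA01", "opioid_analgesic", 30, "analgesic"),
    ("OXY01", "opioid_analgesic", 30, "analgesic"),
    ("COD01", "opioid_nonsalicylate", 15, "analgesic"),
    # sildenafil/tadalafil families
    ("SIL01", "erectile_dysfunction", 30, "erectile_dysfunction"),
    ("TAD01", "erectile_dysfunction", 30, "erectile_dysfunction"),
    ("SIL20", "pulmonary_arterial_hypertension", 30, "pah"),
    # nitrates
    ("NTG01", "vasodilator", 90, "angina"),
    ("ISO01", "vasodilator", 90, "angina"),
    # chronic preventives (cohort drugs included)
    ("ATO01", "statin", 90, "lipid_control"),
    ("SIM01", "statin", 90, "lipid_control"),
    ("AML01", "calcium_channel_blocker", 90, "hypertension"),
    ("WAR01", "anticoagulant", 30, "anticoagulation"),
    ("BZD01", "benzodiazepine", 30, "anxiety"),
    # inert background
    ("CET01", "antihistamine", 30, "allergy"),
    ("OME01", "ppi", 90, "reflux"),
    ("SER01", "ssri", 30, "depression"),
    ("MET01", "biguanide", 90, "diabetes"),
]

_DEFAULT_INTERACTIONS = [
    ("macrolide", "statin", SERIOUS),
    ("macrolide", "anticoagulant", SERIOUS),
    ("quinolone", "anticoagulant", SERIOUS),
    ("erectile_dysfunction", "vasodilator", SERIOUS),
    ("pulmonary_arterial_hypertension", "vasodilator", SERIOUS),
    ("opioid_analgesic", "benzodiazepine", SERIOUS),
    ("opioid_nonsalicylate", "benzodiazepine", SERIOUS),
]


def default_catalog() -> DrugCatalog:
    return DrugCatalog([DrugRecord(*row) for row in _DEFAULT_DRUGS])


def default_interactions() -> InteractionTable:
    return InteractionTable(_DEFAULT_INTERACTIONS)
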