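"""Synthetic pharmacy-claims generator with payor/PBM churn and planted DDI pairs.

Emulates the data-generating process behind prospective drug utilization
review at a pharmacy benefit manager (PBM): patients hold a sequence of
enrollment spans, each under one (payor, PBM, beneficiary identifier,
benefit type); claims are adjudicated under the identifiers of the span
active on the fill date.  Identifier transitions concentrate on January 1
and at ages 19, 26 and 65, the points where US patients typically change
coverage.  Fills of "off-benefit" classes (e.g. erectile-dysfunction drugs,
often not covered) may be recorded under a synthetic cash/coupon identifier
instead of the enrollment identifier.

Every stream carries ground truth: the hidden true patient key on each claim
and a ledger of all serious interacting claim pairs with their expected
crossover status (the two fills occurred under different insurance
identifiers), computed by an exhaustive pairwise scan within true patients.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import DrugCatalog, InteractionTable, default_catalog, default_interactions
from .dur_engine import DurConfig

HORIZON_START = dt.date(2016, 9, 1)
HORIZON_END = dt.date(2019, 8, 31)

BENEFIT_TYPES = ("MEDICAID", "EXCHANGE", "MEDICARE_D", "OTHER")

CLAIM_COLUMNS = [
    "claim_id", "beneficiary_id", "payor_id", "pbm_id", "benefit_type",
    "first_name", "last_name", "birth_date", "sex", "postal_code",
    "fill_date", "drug_id", "therapeutic_class", "condition_group",
    "days_supply", "pharmacy_id",
]

TRUTH_COLUMNS = ["triggering_claim_id", "precipitating_claim_id", "crossover"]

# rng substream tags (mixed with the user seed via SeedSequence)
_POP_STREAM = 101
_CLAIM_STREAM = 202
_TYPO_STREAM = 303

_FIRST_NAMES = [
    "James", "Mary", "Robert", "Patricia", "John", "Jennifer", "Michael",
    "Linda", "David", "Elizabeth", "William", "Barbara", "Richard", "Susan",
    "Joseph", "Jessica", "Thomas", "Sarah", "Charles", "Karen", "Daniel",
    "Nancy", "Matthew", "Lisa", "Anthony", "Betty", "Mark", "Margaret",
    "Donald", "Sandra", "Steven", "Ashley", "Paul", "Kimberly", "Andrew",
    "Emily", "Joshua", "Donna", "Kenneth", "Michelle",
]
_LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration (probability outside [0, 1], etc.)."""


class GenerationError(RuntimeError):
    """Internal inconsistency in the generated stream (signals a bug)."""


@dataclass
class ChurnConfig:
    """Enrollment-churn model parameters.

    annual_transition_prob
        Per-calendar-year probability that a patient changes payor (and so
        receives a new beneficiary identifier).
    january_concentration
        Fraction of annual transitions that take effect exactly on Jan 1;
        the remainder fall uniformly through the year.  Ignored for
        Medicaid patients when ``medicaid_seasonality_flat`` is set, whose
        transitions are always uniform (eligibility is applied year-round).
    age_triggers
        Extra transition probability applied once, on the birthday at each
        listed age (family-plan exits at 19/26, Medicare entry at 65).
    offbenefit_classes
        Therapeutic classes whose fills are, with the given probability,
        adjudicated under a synthetic cash/coupon identifier unique to the
        (patient, class) instead of the enrollment identifier.
    """

    annual_transition_prob: float = 0.20
    january_concentration: float = 0.5
    age_triggers: Mapping[int, float] = field(
        default_factory=lambda: {19: 0.6, 26: 0.5, 65: 0.9}
    )
    benefit_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "MEDICAID": 0.20, "EXCHANGE": 0.05, "MEDICARE_D": 0.20, "OTHER": 0.55
        }
    )
    medicaid_seasonality_flat: bool = True
    offbenefit_classes: Mapping[str, float] = field(
        default_factory=lambda: {"erectile_dysfunction": 0.02}
    )
    pbm_switch_prob: float = 0.1
    rebadge_on_pbm_switch: bool = True
    benefit_redraw_prob: float = 0.3
    n_payors: int = 40
    n_pbms: int = 6

    def validate(self) -> None:
        probs = [
            self.annual_transition_prob, self.january_concentration,
            self.pbm_switch_prob, self.benefit_redraw_prob,
            *self.age_triggers.values(), *self.benefit_mix.values(),
            *self.offbenefit_classes.values(),
        ]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"probability out of [0,1]: {p}")
        if set(self.benefit_mix) - set(BENEFIT_TYPES):
            raise ConfigurationError("unknown benefit type in benefit_mix")
        total = sum(self.benefit_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"benefit_mix must sum to 1, got {total}")
        if self.n_payors < 2 or self.n_pbms < 2:
            raise ConfigurationError("need at least 2 payors and 2 PBMs")


def _as_date(d) -> dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, str):
        return dt.date.fromisoformat(d)
    return d


def _birthday(birth: dt.date, age: int) -> dt.date:
    # Feb 29 birthdays fall back to Feb 28 in non-leap years
    try:
        return birth.replace(year=birth.year + age)
    except ValueError:
        return birth.replace(year=birth.year + age, day=28)


def generate_population(
    n_patients: int,
    config: Optional[ChurnConfig] = None,
    seed: int = 0,
    horizon: tuple = (HORIZON_START, HORIZON_END),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate patients and churned enrollment spans covering the horizon.

    Returns ``(patients, spans)``.  Spans for one patient partition the
    horizon exactly; the beneficiary identifier is regenerated on every
    payor change (and, configurably, when the payor switches PBM).
    Identical ``(n_patients, config, seed)`` reproduce identical output.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    config = config or ChurnConfig()
    config.validate()
    start, end = _as_date(horizon[0]), _as_date(horizon[1])
    if start > end:
        raise ConfigurationError("horizon start after end")

    rng = np.random.default_rng([_POP_STREAM, seed])

    first = rng.choice(_FIRST_NAMES, n_patients)
    last = rng.choice(_LAST_NAMES, n_patients)
    sex = rng.choice(["M", "F"], n_patients)
    birth_lo = dt.date(1935, 1, 1).toordinal()
    birth_hi = dt.date(2002, 8, 31).toordinal()
    birth_ord = rng.integers(birth_lo, birth_hi + 1, n_patients)
    postal = rng.integers(10000, 99999, n_patients)

    # Distinct patients must carry distinct demographic match keys: the UPI
    # regime's keys are generative truth at typo_rate 0, so collisions are
    # resolved by redrawing the birth date.
    for _ in range(100):
        pass1 = pd.Series(
            [f"{f}|{l}|{b}|{s}" for f, l, b, s in zip(first, last, birth_ord, sex)]
        )
        pass2 = pd.Series(
            [f"{f[0]}|{l}|{b}|{z}" for f, l, b, z in zip(first, last, birth_ord, postal)]
        )
        dup = (
            pass1.duplicated(keep="first") | pass2.duplicated(keep="first")
        ).to_numpy()
        if not dup.any():
            break
        birth_ord[dup] = rng.integers(birth_lo, birth_hi + 1, int(dup.sum()))
    else:  # pragma: no cover - astronomically unlikely
        raise GenerationError("could not generate unique patient demographics")

    patients = pd.DataFrame(
        {
            "true_patient_key": [f"P{i:06d}" for i in range(n_patients)],
            "first_name": first,
            "last_name": last,
            "birth_date": pd.to_datetime([dt.date.fromordinal(o) for o in birth_ord]),
            "sex": sex,
            "postal_code": [f"{z:05d}" for z in postal],
        }
    )

    payors = [f"PAY{i:03d}" for i in range(config.n_payors)]
    pbms = [f"PBM{i:02d}" for i in range(config.n_pbms)]
    payor_pbm = {p: pbms[i % config.n_pbms] for i, p in enumerate(payors)}

    benefit_names = sorted(config.benefit_mix)
    benefit_probs = np.array([config.benefit_mix[b] for b in benefit_names])

    jan_firsts = [
        dt.date(y, 1, 1)
        for y in range(start.year, end.year + 1)
        if start < dt.date(y, 1, 1) <= end
    ]

    span_rows = []
    bene_seq = 0
    for i in range(n_patients):
        key = patients.true_patient_key.iat[i]
        birth = patients.birth_date.iat[i].date()
        age_at_start = (start - birth).days // 365

        benefit = str(rng.choice(benefit_names, p=benefit_probs))
        if age_at_start >= 65:
            benefit = "MEDICARE_D"
        flat = benefit == "MEDICAID" and config.medicaid_seasonality_flat

        transitions: list[tuple[dt.date, str]] = []
        for jan1 in jan_firsts:
            if rng.random() < config.annual_transition_prob:
                if (not flat) and rng.random() < config.january_concentration:
                    d = jan1
                else:
                    year_end = min(dt.date(jan1.year, 12, 31), end)
                    lo = max(jan1, start + dt.timedelta(days=1)).toordinal()
                    hi = year_end.toordinal()
                    d = dt.date.fromordinal(int(rng.integers(lo, hi + 1)))
                transitions.append((d, "annual"))
        for age in sorted(config.age_triggers):
            bday = _birthday(birth, age)
            if start < bday <= end and rng.random() < config.age_triggers[age]:
                transitions.append((bday, f"age{age}"))

        # dedupe by date, sort chronologically
        by_date: dict[dt.date, str] = {}
        for d, kind in sorted(transitions):
            by_date.setdefault(d, kind)

        payor = str(rng.choice(payors))
        pbm = payor_pbm[payor]
        bene = f"B{bene_seq:08d}"
        bene_seq += 1
        span_start = start
        for d in sorted(by_date):
            kind = by_date[d]
            span_rows.append((key, payor, pbm, bene, benefit, span_start, d - dt.timedelta(days=1)))
            if rng.random() < config.pbm_switch_prob:
                # payor stays, payor switches its PBM
                pbm = str(rng.choice([x for x in pbms if x != pbm]))
                if config.rebadge_on_pbm_switch:
                    bene = f"B{bene_seq:08d}"
                    bene_seq += 1
            else:
                payor = str(rng.choice([x for x in payors if x != payor]))
                pbm = payor_pbm[payor]
                bene = f"B{bene_seq:08d}"
                bene_seq += 1
            if kind == "age65":
                benefit = "MEDICARE_D"
            elif rng.random() < config.benefit_redraw_prob:
                benefit = str(rng.choice(benefit_names, p=benefit_probs))
            span_start = d
        span_rows.append((key, payor, pbm, bene, benefit, span_start, end))

    spans = pd.DataFrame(
        span_rows,
        columns=[
            "true_patient_key", "payor_id", "pbm_id", "beneficiary_id",
            "benefit_type", "start_date", "end_date",
        ],
    )
    spans["start_date"] = pd.to_datetime(spans["start_date"])
    spans["end_date"] = pd.to_datetime(spans["end_date"])
    return patients, spans


def _pick_drug(rng, catalog: DrugCatalog, cls: str) -> str:
    drugs = catalog.drugs_in_class(cls)
    return str(rng.choice(drugs))


def simulate_claims(
    patients: pd.DataFrame,
    spans: pd.DataFrame,
    catalog: Optional[DrugCatalog] = None,
    interactions: Optional[InteractionTable] = None,
    *,
    ddi_plant_rate: float = 0.05,
    background_rate: float = 9.6,
    plant_crossover_share: Optional[float] = None,
    background_classes: Optional[Sequence[str]] = None,
    resolution_probs: Optional[tuple[float, float]] = (0.735, 0.10),
    churn_config: Optional[ChurnConfig] = None,
    dur_config: Optional[DurConfig] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a claim stream over the enrollment spans, with ground truth.

    Background fills arrive at ``background_rate`` per patient-year (drug
    drawn uniformly from ``background_classes``, default: whole catalog).
    With probability ``ddi_plant_rate`` a patient additionally hosts one
    planted serious interacting pair.  Two planting modes:

    * organic (``plant_crossover_share=None``): the pair is anchored at a
      uniform date and straddles an identifier change only when churn
      happens to put one there — crossover status emerges from the churn
      model.
    * forced (``plant_crossover_share=x``): the pair straddles a span
      boundary with probability exactly ``x`` (hosts restricted to patients
      with >= 2 spans), giving a known true cross-identifier share for
      calibration studies.

    In organic mode, each alerted (triggering) claim is followed within 14
    days by a same-drug re-dispense or a same-condition alternative with
    the ``resolution_probs`` = (override, replacement) probabilities, so
    alert dispositions in the stream resemble observed pharmacy behavior;
    pass ``resolution_probs=None`` to disable.

    Returns ``(claims, truth)`` where ``truth`` is the exhaustive ledger of
    serious interacting pairs under the DUR window rules, with crossover
    flagged whenever the two fills carry different (payor, beneficiary)
    identifiers.
    """
    if not (0.0 <= ddi_plant_rate <= 1.0):
        raise ConfigurationError(f"ddi_plant_rate out of [0,1]: {ddi_plant_rate}")
    if plant_crossover_share is not None and not (0.0 <= plant_crossover_share <= 1.0):
        raise ConfigurationError("plant_crossover_share out of [0,1]")
    if resolution_probs is not None:
        p_o, p_r = resolution_probs
        if not (0.0 <= p_o <= 1.0 and 0.0 <= p_r <= 1.0 and p_o + p_r <= 1.0):
            raise ConfigurationError("resolution_probs must be probabilities summing to <= 1")
    catalog = catalog or default_catalog()
    interactions = interactions or default_interactions()
    if len(catalog) == 0 or len(interactions) == 0:
        raise ConfigurationError("catalog and interaction table must be non-empty")
    churn_config = churn_config or ChurnConfig()
    dur_config = dur_config or DurConfig()

    rng = np.random.default_rng([_CLAIM_STREAM, seed])
    n_patients = len(patients)
    start = spans.start_date.min()
    end = spans.end_date.max()
    total_days = (end - start).days + 1
    years = total_days / 365.25

    supply_map = {d: catalog[d].typical_days_supply for d in catalog.drug_ids}
    class_map = {d: catalog[d].therapeutic_class for d in catalog.drug_ids}
    cond_map = {d: catalog[d].condition_group for d in catalog.drug_ids}

    # --- background fills -------------------------------------------------
    if background_classes is not None:
        bg_pool = catalog.drugs_in_classes(background_classes)
    else:
        bg_pool = catalog.drug_ids
    if not bg_pool:
        raise ConfigurationError("background_classes matches no catalog drug")
    n_bg = rng.poisson(background_rate * years, size=n_patients)
    pat_idx = np.repeat(np.arange(n_patients), n_bg)
    n_total_bg = int(n_bg.sum())
    offsets = rng.integers(0, total_days, size=n_total_bg)
    bg_drugs = rng.choice(bg_pool, size=n_total_bg)

    rows = {
        "pat_idx": list(pat_idx),
        "fill_date": list(start + pd.to_timedelta(offsets, unit="D")),
        "drug_id": [str(d) for d in bg_drugs],
        "days_supply": [supply_map[str(d)] for d in bg_drugs],
    }

    # --- planted interacting pairs ---------------------------------------
    pair_list = sorted(tuple(sorted(p)) for p in interactions.to_frame()[["class_a", "class_b"]].itertuples(index=False))
    offb = set(churn_config.offbenefit_classes)

    def _append(pi, date, drug, supply):
        rows["pat_idx"].append(pi)
        rows["fill_date"].append(pd.Timestamp(date))
        rows["drug_id"].append(drug)
        rows["days_supply"].append(supply)

    if plant_crossover_share is None:
        hosts = np.nonzero(rng.random(n_patients) < ddi_plant_rate)[0]
        for pi in hosts:
            ca, cb = pair_list[int(rng.integers(len(pair_list)))]
            drug_a, drug_b = _pick_drug(rng, catalog, ca), _pick_drug(rng, catalog, cb)
            s_a = supply_map[drug_a]
            gap = int(rng.integers(1, min(s_a, 28) + 1))
            anchor = int(rng.integers(0, total_days - gap))
            d0 = start + pd.Timedelta(days=anchor)
            _append(int(pi), d0, drug_a, s_a)
            _append(int(pi), d0 + pd.Timedelta(days=gap), drug_b, supply_map[drug_b])
    else:
        clean_pairs = [p for p in pair_list if p[0] not in offb and p[1] not in offb]
        if not clean_pairs:
            raise ConfigurationError("no interacting pair outside off-benefit classes")
        span_counts = spans.groupby("true_patient_key").size()
        key_to_idx = {k: i for i, k in enumerate(patients.true_patient_key)}
        eligible = [key_to_idx[k] for k in span_counts.index[span_counts >= 2]]
        eligible = np.array(sorted(eligible))
        spans_by_pat = {k: g.sort_values("start_date") for k, g in spans.groupby("true_patient_key")}
        hosts = eligible[rng.random(len(eligible)) < ddi_plant_rate]
        for pi in hosts:
            key = patients.true_patient_key.iat[int(pi)]
            g = spans_by_pat[key]
            ca, cb = clean_pairs[int(rng.integers(len(clean_pairs)))]
            drug_a, drug_b = _pick_drug(rng, catalog, ca), _pick_drug(rng, catalog, cb)
            if rng.random() < plant_crossover_share:
                k = int(rng.integers(1, len(g)))
                boundary = g.start_date.iat[k]
                back = int(rng.integers(3, 11))
                fwd = int(rng.integers(1, 11))
                prev_start = g.start_date.iat[k - 1]
                d_prec = max(boundary - pd.Timedelta(days=back), prev_start)
                d_trig = min(boundary + pd.Timedelta(days=fwd), g.end_date.iat[k])
            else:
                lengths = (g.end_date - g.start_date).dt.days
                ok = np.nonzero(lengths.values >= 21)[0]
                k = int(ok[rng.integers(len(ok))]) if len(ok) else int(lengths.values.argmax())
                lo = g.start_date.iat[k]
                hi = g.end_date.iat[k] - pd.Timedelta(days=11)
                hi = max(hi, lo)
                d_prec = lo + pd.Timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
                d_trig = min(d_prec + pd.Timedelta(days=int(rng.integers(1, 11))), g.end_date.iat[k])
            _append(int(pi), d_prec, drug_a, 30)
            _append(int(pi), d_trig, drug_b, 30)

    span_cols = spans[
        ["true_patient_key", "start_date", "end_date", "payor_id", "pbm_id",
         "beneficiary_id", "benefit_type"]
    ].sort_values("start_date", kind="mergesort")

    def _adjudicate(df: pd.DataFrame) -> pd.DataFrame:
        """Attach span identifiers, cash/coupon substitution and demographics."""
        df = df.copy()
        df["therapeutic_class"] = df.drug_id.map(class_map)
        df["condition_group"] = df.drug_id.map(cond_map)
        df["fill_date"] = pd.to_datetime(df["fill_date"])
        df = df.sort_values("fill_date", kind="mergesort")
        df = pd.merge_asof(
            df, span_cols,
            left_on="fill_date", right_on="start_date",
            by="true_patient_key", direction="backward",
        )
        bad = df.start_date.isna() | (df.fill_date > df.end_date)
        if bad.any():
            raise GenerationError(
                f"{int(bad.sum())} claims fall outside all enrollment spans"
            )
        df = df.drop(columns=["start_date", "end_date"])
        for cls in sorted(offb):
            p = churn_config.offbenefit_classes[cls]
            mask = (df.therapeutic_class == cls).values
            if not mask.any() or p == 0:
                continue
            hit = mask & (rng.random(len(df)) < p)
            if hit.any():
                df.loc[hit, "beneficiary_id"] = [
                    f"CASH-{k}-{cls}" for k in df.loc[hit, "true_patient_key"]
                ]
                df.loc[hit, "payor_id"] = "CASH"
                df.loc[hit, "pbm_id"] = "CASH"
        return df.merge(patients, on="true_patient_key")

    def _finalize(df: pd.DataFrame, id_offset: int) -> pd.DataFrame:
        df = df.sort_values(
            ["fill_date", "true_patient_key", "drug_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["claim_id"] = [f"C{id_offset + i:08d}" for i in range(len(df))]
        df["pharmacy_id"] = [
            f"PH{j:03d}" for j in rng.integers(0, 50, size=len(df))
        ]
        return df[CLAIM_COLUMNS + ["true_patient_key"]]

    base = pd.DataFrame(rows)
    base["true_patient_key"] = patients.true_patient_key.values[base.pat_idx.values]
    base = base.drop(columns="pat_idx")
    claims = _finalize(_adjudicate(base), 0)

    # --- post-alert resolution fills (organic mode only) ------------------
    # Each alerted (triggering) claim is followed, with the configured
    # probabilities, by a same-drug re-dispense (override) or an alternative
    # for the same condition (replacement) within 14 days.  Calibration
    # (forced) mode skips this so planted pairs stay the only alert source.
    if plant_crossover_share is None and resolution_probs is not None:
        p_override, p_replace = resolution_probs
        pre = ground_truth_alerts(claims, interactions, dur_config)
        if len(pre):
            cond_drugs: dict[str, list[str]] = {}
            for d in catalog.drug_ids:
                cond_drugs.setdefault(cond_map[d], []).append(d)
            info = claims.set_index("claim_id")
            extra = {
                "true_patient_key": [], "fill_date": [],
                "drug_id": [], "days_supply": [],
            }
            for tid in sorted(pre.triggering_claim_id.unique()):
                row = info.loc[tid]
                u = rng.random()
                delay = int(rng.integers(1, 15))
                d_fill = min(row.fill_date + pd.Timedelta(days=delay), end)
                if u < p_override:
                    drug = row.drug_id
                elif u < p_override + p_replace:
                    alts = [
                        x for x in cond_drugs.get(row.condition_group, [])
                        if x != row.drug_id
                    ]
                    if not alts:
                        continue
                    drug = str(alts[int(rng.integers(len(alts)))])
                else:
                    continue
                extra["true_patient_key"].append(row.true_patient_key)
                extra["fill_date"].append(d_fill)
                extra["drug_id"].append(drug)
                extra["days_supply"].append(supply_map[drug])
            if extra["drug_id"]:
                ex = _finalize(_adjudicate(pd.DataFrame(extra)), len(claims))
                claims = (
                    pd.concat([claims, ex], ignore_index=True)
                    .sort_values(["fill_date", "claim_id"], kind="mergesort")
                    .reset_index(drop=True)
                )

    truth = ground_truth_alerts(claims, interactions, dur_config)
    return claims, truth


def ground_truth_alerts(
    claims: pd.DataFrame,
    interactions: InteractionTable,
    config: Optional[DurConfig] = None,
    group_col: str = "true_patient_key",
) -> pd.DataFrame:
    """Exhaustive pairwise serious-interaction scan within identity groups.

    Applies the same window rules as the DUR engine (precipitating fill
    strictly earlier, or same-day with smaller claim_id; within the history
    window; supply still active) but by brute-force self-join rather than by
    streaming, so it serves as the generator's independent ground truth.
    """
    config = config or DurConfig()
    cols = claims.loc[
        claims.therapeutic_class.isin(interactions.classes),
        [group_col, "claim_id", "fill_date", "therapeutic_class",
         "days_supply", "payor_id", "beneficiary_id"],
    ]
    if cols.empty:
        return pd.DataFrame(columns=TRUTH_COLUMNS).astype({"crossover": int})
    m = cols.merge(cols, on=group_col, suffixes=("_t", "_p"))
    precede = (m.fill_date_p < m.fill_date_t) | (
        (m.fill_date_p == m.fill_date_t) & (m.claim_id_p < m.claim_id_t)
    )
    in_window = m.fill_date_p >= m.fill_date_t - pd.to_timedelta(
        config.history_window, unit="D"
    )
    keep = precede & in_window
    if config.require_active_supply:
        keep &= (
            m.fill_date_p + pd.to_timedelta(m.days_supply_p, unit="D")
            >= m.fill_date_t
        )
    m = m[keep]
    sym = interactions.symmetric_frame()
    m = m.merge(
        sym,
        left_on=["therapeutic_class_t", "therapeutic_class_p"],
        right_on=["class_a", "class_b"],
    )
    crossover = (
        (m.payor_id_t != m.payor_id_p) | (m.beneficiary_id_t != m.beneficiary_id_p)
    ).astype(int)
    out = pd.DataFrame(
        {
            "triggering_claim_id": m.claim_id_t,
            "precipitating_claim_id": m.claim_id_p,
            "crossover": crossover,
        }
    )
    return out.sort_values(
        ["triggering_claim_id", "precipitating_claim_id"], kind="mergesort"
    ).reset_index(drop=True)


def _corrupt_name(rng, s: str) -> str:
    if len(s) < 2 or rng.random() < 0.5:
        i = int(rng.integers(0, len(s)))
        alphabet = "abcdefghijklmnopqrstuvwxyz"
        repl = alphabet[int(rng.integers(0, 26))]
        while repl == s[i].lower():
            repl = alphabet[int(rng.integers(0, 26))]
        return s[:i] + repl + s[i + 1:]
    i = int(rng.integers(0, len(s) - 1))
    if s[i] == s[i + 1]:  # transposing equal chars would be a no-op
        return _corrupt_char(rng, s, i)
    return s[:i] + s[i + 1] + s[i] + s[i + 2:]


def _corrupt_char(rng, s: str, i: int) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = alphabet[int(rng.integers(0, 26))]
    while repl == s[i].lower():
        repl = alphabet[int(rng.integers(0, 26))]
    return s[:i] + repl + s[i + 1:]


def perturb_demographics(
    claims: pd.DataFrame, typo_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Corrupt claim-level demographics, emulating transcription error.

    Each of first_name, last_name, postal_code and birth_date is
    independently corrupted with probability ``typo_rate`` (names: single
    character substitution or adjacent transposition; postal code: one digit
    changed; birth date: shifted 1-3 days).  The hidden true_patient_key is
    untouched.
    """
    if not (0.0 <= typo_rate <= 1.0):
        raise ConfigurationError(f"typo_rate out of [0,1]: {typo_rate}")
    out = claims.copy()
    if typo_rate == 0.0 or out.empty:
        return out
    rng = np.random.default_rng([_TYPO_STREAM, seed])
    n = len(out)
    for col in ("first_name", "last_name"):
        mask = rng.random(n) < typo_rate
        if mask.any():
            vals = out[col].to_numpy(dtype=object, copy=True)
            for i in np.nonzero(mask)[0]:
                vals[i] = _corrupt_name(rng, str(vals[i]))
            out[col] = vals
    mask = rng.random(n) < typo_rate
    if mask.any():
        vals = out["postal_code"].to_numpy(dtype=object, copy=True)
        for i in np.nonzero(mask)[0]:
            s = str(vals[i])
            j = int(rng.integers(0, len(s)))
            d = str(rng.integers(0, 10))
            while d == s[j]:
                d = str(rng.integers(0, 10))
            vals[i] = s[:j] + d + s[j + 1:]
        out["postal_code"] = vals
    mask = rng.random(n) < typo_rate
    if mask.any():
        shifts = np.zeros(n, dtype=int)
        raw = rng.integers(1, 4, size=n) * rng.choice([-1, 1], size=n)
        shifts[mask] = raw[mask]
        out["birth_date"] = out["birth_date"] + pd.to_timedelta(shifts, unit="D")
    return out
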