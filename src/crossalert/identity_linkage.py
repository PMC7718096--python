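"""Claim-to-patient identity assignment under two regimes.

BENEFICIARY: the identity is the (payor, beneficiary identifier) pair —
a record arriving from a new payor is, by construction, a new patient.

UPI: a unique patient identifier assigned by deterministic demographic
matching — an ordered list of match passes, each a set of normalized key
fields; claims sharing any pass key are united (transitive closure via
union-find), and the component is labelled by its smallest claim_id so the
assignment is stable run to run.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

REGIME_BENEFICIARY = "BENEFICIARY"
REGIME_UPI = "UPI"

MAP_COLUMNS = ["claim_id", "identity_key", "regime"]

#: Default match passes: (1) full name + birth date + sex;
#: (2) first initial + last name + birth date + postal code.
DEFAULT_PASSES: tuple[tuple[str, ...], ...] = (
    ("first_name", "last_name", "birth_date", "sex"),
    ("first_initial", "last_name", "birth_date", "postal_code"),
)

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def _normalize(value) -> str:
    """Case-fold and strip punctuation/whitespace."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return _NON_ALNUM.sub("", str(value).casefold())


@dataclass(frozen=True)
class LinkageQuality:
    """Pairwise precision/recall plus entity-level split and merge counts."""

    precision: float
    recall: float
    n_splits: int
    n_merges: int


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        while p[i] != i:
            p[i] = p[p[i]]
            i = p[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def link_by_beneficiary(claims: pd.DataFrame) -> pd.DataFrame:
    """Identity = (payor_id, beneficiary_id); never merges across payors."""
    if claims.empty:
        raise ValueError("claims must be non-empty")
    missing = claims.beneficiary_id.isna() | (claims.beneficiary_id.astype(str) == "")
    if missing.any():
        bad = claims.loc[missing, "claim_id"].tolist()[:5]
        raise ValueError(f"claims with missing beneficiary_id, e.g. {bad}")
    key = claims.payor_id.astype(str) + "|" + claims.beneficiary_id.astype(str)
    return pd.DataFrame(
        {
            "claim_id": claims.claim_id,
            "identity_key": key,
            "regime": REGIME_BENEFICIARY,
        }
    ).reset_index(drop=True)


def _pass_keys(claims: pd.DataFrame, fields: Sequence[str]) -> pd.Series:
    """Normalized composite key per claim; empty string where any field is blank."""
    parts = []
    for f in fields:
        if f == "first_initial":
            col = claims["first_name"].map(lambda v: _normalize(v)[:1])
        elif f == "birth_date":
            col = pd.to_datetime(claims["birth_date"]).dt.strftime("%Y%m%d")
        else:
            col = claims[f].map(_normalize)
        parts.append(col.astype(str))
    key = parts[0]
    complete = parts[0] != ""
    for p in parts[1:]:
        key = key + "|" + p
        complete &= p != ""
    return key.where(complete, "")


def assign_upi_deterministic(
    claims: pd.DataFrame,
    passes: Sequence[Sequence[str]] = DEFAULT_PASSES,
) -> pd.DataFrame:
    """Union-find closure over the match passes; component key = min claim_id.

    A claim with a blank field skips that pass; a claim matching no pass at
    all (all demographics missing) remains a logged singleton.
    """
    if claims.empty:
        raise ValueError("claims must be non-empty")
    if not passes:
        raise ValueError("passes must be non-empty")
    idx = claims.reset_index(drop=True)
    uf = _UnionFind(len(idx))
    matched = pd.Series(False, index=idx.index)
    for fields in passes:
        keys = _pass_keys(idx, fields)
        usable = keys != ""
        matched |= usable
        first_of_key: dict[str, int] = {}
        for i in usable[usable].index:
            k = keys.iat[i]
            j = first_of_key.setdefault(k, i)
            if j != i:
                uf.union(j, i)
    n_orphans = int((~matched).sum())
    if n_orphans:
        logger.warning(
            "%d claims with no usable demographic pass key assigned singleton identities",
            n_orphans,
        )
    comp: dict[int, list[int]] = {}
    for i in range(len(idx)):
        comp.setdefault(uf.find(i), []).append(i)
    ids = idx.claim_id.astype(str)
    identity = [""] * len(idx)
    for members in comp.values():
        key = min(ids.iat[i] for i in members)
        for i in members:
            identity[i] = key
    return pd.DataFrame(
        {"claim_id": idx.claim_id, "identity_key": identity, "regime": REGIME_UPI}
    )


def linkage_quality(
    linkage_map: pd.DataFrame, truth: pd.DataFrame
) -> LinkageQuality:
    """Pairwise precision/recall of claim co-assignment against planted truth.

    ``truth`` carries (claim_id, true_patient_key) for every mapped claim.
    Splits count true patients fragmented over several identity keys; merges
    count identity keys spanning more than one true patient.  With no
    splits and no merges both pairwise scores are exactly 1.
    """
    merged = linkage_map[["claim_id", "identity_key"]].merge(
        truth[["claim_id", "true_patient_key"]], on="claim_id", how="left"
    )
    if merged.true_patient_key.isna().any():
        raise ValueError("truth does not cover all mapped claims")
    cell = merged.groupby(["identity_key", "true_patient_key"]).size()
    pred = merged.groupby("identity_key").size()
    true = merged.groupby("true_patient_key").size()
    tp = sum(comb(int(n), 2) for n in cell)
    pred_pairs = sum(comb(int(n), 2) for n in pred)
    true_pairs = sum(comb(int(n), 2) for n in true)
    precision = tp / pred_pairs if pred_pairs else 1.0
    recall = tp / true_pairs if true_pairs else 1.0
    n_splits = int(
        (cell.reset_index().groupby("true_patient_key").identity_key.nunique() > 1).sum()
    )
    n_merges = int(
        (cell.reset_index().groupby("identity_key").true_patient_key.nunique() > 1).sum()
    )
    return LinkageQuality(precision, recall, n_splits, n_merges)
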