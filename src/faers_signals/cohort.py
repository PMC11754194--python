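"""Case cleaning and target-drug screening.

The analysis cohort is produced in the FDA-recommended order: drop
FDA-deleted cases, collapse duplicate CASEIDs to the most recent version
(largest FDA_DT, ties broken by largest PRIMARYID), then screen for the
target drug by substring match on DRUGNAME / PROD_AI, optionally restricted
to rows where that same drug is the primary suspect (PS).  The counting
unit handed to disproportionality is the unique (report, preferred term)
pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import id_sort_key
from .faers_io import as_frame, parse_faers_date

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningKeywords",
    "PairUniverse",
    "remove_deleted",
    "deduplicate_reports",
    "screen_target_drug",
    "build_report_event_pairs",
    "normalize_pt",
]

#: Table-1-style screening for eculizumab: match the active ingredient or
#: either trade/generic name, restricted to primary-suspect rows.
ECULIZUMAB_KEYWORDS = None  # set below, after the class definition


@dataclass(frozen=True)
class ScreeningKeywords:
    """Substring screening conditions for the target-drug population.

    A drug row matches when any ``drugname_substrings`` entry occurs in
    DRUGNAME or any ``prod_ai_substrings`` entry occurs in PROD_AI
    (case-insensitive, contains semantics).  When ``restrict_to_role`` is
    set, the *matching row itself* must carry that role code.
    """

    drugname_substrings: tuple[str, ...] = ()
    prod_ai_substrings: tuple[str, ...] = ()
    restrict_to_role: str | None = None

    def __post_init__(self):
        if not (self.drugname_substrings or self.prod_ai_substrings):
            raise ValueError("at least one screening substring is required")


ECULIZUMAB_KEYWORDS = ScreeningKeywords(
    drugname_substrings=("ECULIZUMAB", "SOLIRIS"),
    prod_ai_substrings=("ECULIZUMAB",),
    restrict_to_role="PS",
)

_WS = re.compile(r"\s+")


def normalize_pt(pt: str) -> tuple[str, str]:
    """Return (matching key, display form) for a preferred term.

    Matching is whitespace-collapsed and case-folded because FAERS PT
    capitalisation drifts across quarters; the display form keeps the
    original casing (trimmed, whitespace-collapsed).
    """
    display = _WS.sub(" ", str(pt).strip())
    return display.casefold(), display


def remove_deleted(demo_records, dele_records) -> tuple[pd.DataFrame, int]:
    """Drop DEMO rows whose CASEID is listed in DELE; returns (kept, n_removed)."""
    demo = as_frame(demo_records)
    dele = as_frame(dele_records)
    if len(demo) == 0 or len(dele) == 0:
        return demo.copy(), 0
    deleted = set(dele["caseid"].astype(str))
    keep = ~demo["caseid"].astype(str).isin(deleted)
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d report(s) in %d deleted case(s)", removed, len(deleted))
    return demo[keep].reset_index(drop=True), removed


def _fda_dt_key(raw: pd.Series) -> np.ndarray:
    """FDA_DT as a comparable integer; unparseable dates sort lowest (-1)."""
    def one(v: str) -> int:
        p = parse_faers_date(v)
        return int(p.date.strftime("%Y%m%d")) if p.is_exact else -1

    n_bad = 0
    out = np.empty(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        out[i] = one(v)
        n_bad += out[i] < 0
    if n_bad:
        logger.warning("%d record(s) with unparseable FDA_DT sort lowest in dedup", n_bad)
    return out


def deduplicate_reports(demo_records) -> pd.DataFrame:
    """Keep one DEMO row per CASEID: the largest FDA_DT, then the largest
    PRIMARYID (numeric comparison for all-digit ids, else lexicographic).

    Output is sorted by CASEID, so the operation is deterministic and
    idempotent.
    """
    demo = as_frame(demo_records)
    if len(demo) == 0:
        return demo.copy()
    df = demo.copy()
    df["_fda_key"] = _fda_dt_key(df["fda_dt"].astype(str))

    counts = df["caseid"].astype(str).value_counts()
    dup_cases = set(counts.index[counts > 1])
    case_str = df["caseid"].astype(str)
    uniques = df[~case_str.isin(dup_cases)]

    survivors = [uniques]
    if dup_cases:
        dups = df[case_str.isin(dup_cases)]
        idx = []
        for _, grp in dups.groupby(dups["caseid"].astype(str), sort=False):
            best = max(
                grp.index,
                key=lambda i: (grp.at[i, "_fda_key"], id_sort_key(grp.at[i, "primaryid"])),
            )
            idx.append(best)
        survivors.append(dups.loc[idx])
    out = pd.concat(survivors)
    out = out.sort_values("caseid", key=lambda s: s.map(id_sort_key), kind="stable")
    return out.drop(columns="_fda_key").reset_index(drop=True)


def target_drug_rows(drug_records, keywords: ScreeningKeywords) -> pd.DataFrame:
    """Drug rows matching the screening terms (role restriction applied).

    The role restriction applies to the matching row itself: a report whose
    only keyword match is a concomitant row is not a target when
    ``restrict_to_role='PS'``.
    """
    drug = as_frame(drug_records)
    if len(drug) == 0:
        return drug.copy()
    name = (
        drug["drugname"].astype(str).str.casefold()
        if "drugname" in drug
        else pd.Series("", index=drug.index)
    )
    ai = (
        drug["prod_ai"].astype(str).str.casefold()
        if "prod_ai" in drug
        else pd.Series("", index=drug.index)
    )
    hit = pd.Series(False, index=drug.index)
    for sub in keywords.drugname_substrings:
        hit |= name.str.contains(re.escape(sub.casefold()), regex=True)
    for sub in keywords.prod_ai_substrings:
        hit |= ai.str.contains(re.escape(sub.casefold()), regex=True)
    if keywords.restrict_to_role is not None:
        hit &= drug["role_cod"].astype(str).str.upper() == keywords.restrict_to_role.upper()
    return drug[hit].copy()


def screen_target_drug(drug_records, keywords: ScreeningKeywords) -> set[str]:
    """PRIMARYIDs of reports with >=1 drug row matching the screening terms."""
    rows = target_drug_rows(drug_records, keywords)
    if len(rows) == 0:
        return set()
    return set(rows["primaryid"].astype(str))


@dataclass
class PairUniverse:
    """Unique (report, PT) pairs — the counting unit for the 2x2 cells.

    ``pairs`` has columns primaryid, pt_key (normalized), pt (display),
    is_target.  Summary counts mirror the cohort funnel.
    """

    pairs: pd.DataFrame
    n_reports_total: int
    n_target_reports: int
    n_target_pairs: int
    n_dropped_orphans: int = 0
    target_ids: set[str] = field(default_factory=set)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_report_event_pairs(deduped_demo, reac_records, target_ids: set[str]) -> PairUniverse:
    """Deduplicated (report, normalized PT) pairs over the cleaned cohort.

    REAC rows whose PRIMARYID is absent from the deduplicated DEMO set
    (superseded versions, deleted cases) are dropped and counted.
    """
    demo = as_frame(deduped_demo)
    reac = as_frame(reac_records)
    demo_ids = set(demo["primaryid"].astype(str)) if len(demo) else set()
    if len(reac) == 0:
        pairs = pd.DataFrame(columns=["primaryid", "pt_key", "pt", "is_target"])
        return PairUniverse(pairs, len(demo_ids), len(target_ids & demo_ids), 0, 0, set(target_ids))

    df = reac.copy()
    df["primaryid"] = df["primaryid"].astype(str)
    in_demo = df["primaryid"].isin(demo_ids)
    dropped = int((~in_demo).sum())
    if dropped:
        logger.info("dropped %d REAC row(s) without a surviving DEMO report", dropped)
    df = df[in_demo]

    display = df["pt"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    df = pd.DataFrame(
        {
            "primaryid": df["primaryid"].to_numpy(),
            "pt_key": display.str.casefold().to_numpy(),
            "pt": display.to_numpy(),
        }
    )
    df = df[df["pt_key"] != ""]
    df = df.drop_duplicates(["primaryid", "pt_key"], keep="first").reset_index(drop=True)
    df["is_target"] = df["primaryid"].isin(target_ids)

    target_reports = target_ids & demo_ids
    return PairUniverse(
        pairs=df,
        n_reports_total=len(demo_ids),
        n_target_reports=len(target_reports),
        n_target_pairs=int(df["is_target"].sum()),
        n_dropped_orphans=dropped,
        target_ids=set(target_ids),
    )
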