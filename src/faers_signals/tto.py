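"""Time-to-onset (TTO) analysis.

TTO is the interval in whole days between the start of the target drug
(earliest exact THER start date among the report's matching drug rows) and
the event date (DEMO event date).  Reports are excluded — never imputed,
unless ``impute_partial='month_start'`` is requested — when either date is
missing or partial, or when the interval is negative; exclusion reasons are
kept so that bins plus exclusions always partition the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from .faers_io import ParsedDate, parse_faers_date

__all__ = [
    "OnsetRecord",
    "compute_onset_days",
    "summarize_tto",
    "bin_tto",
    "TTO_BINS",
    "EXCLUSION_REASONS",
]

EXCLUSION_REASONS = ("missing_event_dt", "missing_start_dt", "partial_date", "negative")

#: Closed onset-day bins, inclusive of both endpoints; day 0 (event on the
#: start date) falls in the first bin, day 361 and beyond in the open tail.
TTO_BINS = (
    ("0-30", 0, 30),
    ("31-60", 31, 60),
    ("61-90", 61, 90),
    ("91-120", 91, 120),
    ("121-150", 121, 150),
    ("151-180", 151, 180),
    ("181-360", 181, 360),
    (">360", 361, None),
)


@dataclass(frozen=True)
class OnsetRecord:
    """Either an onset in days (>= 0) or one exclusion reason, never both."""

    primaryid: str
    onset_days: int | None = None
    exclusion: str | None = None

    def __post_init__(self):
        if (self.onset_days is None) == (self.exclusion is None):
            raise ValueError("exactly one of onset_days / exclusion must be set")
        if self.exclusion is not None and self.exclusion not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion!r}")

    @property
    def included(self) -> bool:
        return self.onset_days is not None


def _impute(p: ParsedDate, impute_partial: str) -> ParsedDate:
    if impute_partial == "month_start" and p.kind == "partial" and p.month is not None:
        return ParsedDate("exact", date=date(p.year, p.month, 1), year=p.year, month=p.month)
    return p


def compute_onset_days(
    primaryid: str,
    event_dt: str | ParsedDate,
    start_dts: list[str | ParsedDate],
    impute_partial: str = "none",
) -> OnsetRecord:
    """Onset = event date minus the earliest exact start date, in days.

    Exclusion precedence: missing event date, then missing start dates
    (none supplied or all empty/invalid), then partial dates (either side),
    then negative intervals.  Total — never raises on bad dates.
    """
    if impute_partial not in ("none", "month_start"):
        raise ValueError(f"unknown impute_partial policy {impute_partial!r}")
    ev = event_dt if isinstance(event_dt, ParsedDate) else parse_faers_date(event_dt)
    ev = _impute(ev, impute_partial)
    starts = [
        _impute(s if isinstance(s, ParsedDate) else parse_faers_date(s), impute_partial)
        for s in start_dts
    ]
    if ev.kind == "missing":
        return OnsetRecord(primaryid, exclusion="missing_event_dt")
    if not starts or all(s.kind == "missing" for s in starts):
        return OnsetRecord(primaryid, exclusion="missing_start_dt")
    if ev.kind == "partial":
        return OnsetRecord(primaryid, exclusion="partial_date")
    exact_starts = [s.date for s in starts if s.is_exact]
    if not exact_starts:
        return OnsetRecord(primaryid, exclusion="partial_date")
    days = (ev.date - min(exact_starts)).days
    if days < 0:
        return OnsetRecord(primaryid, exclusion="negative")
    return OnsetRecord(primaryid, onset_days=days)


def summarize_tto(onset_records: list[OnsetRecord]) -> dict:
    """Median and IQR of included onsets (linear-interpolation quantiles).

    Returns ``{"n_included", "median", "q1", "q3"}``; quantiles are NaN
    when nothing is included.
    """
    days = np.asarray([r.onset_days for r in onset_records if r.included], dtype=float)
    if days.size == 0:
        return {"n_included": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # type-7 linear interpolation
    return {"n_included": int(days.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def bin_tto(onset_records: list[OnsetRecord]) -> dict[str, int]:
    """Counts per onset bin plus one ``excluded`` bucket.

    Bin edges are inclusive on both sides, so the counts partition every
    record exactly once.
    """
    counts = {label: 0 for label, _, _ in TTO_BINS}
    counts["excluded"] = 0
    for rec in onset_records:
        if not rec.included:
            counts["excluded"] += 1
            continue
        d = rec.onset_days
        for label, lo, hi in TTO_BINS:
            if d >= lo and (hi is None or d <= hi):
                counts[label] += 1
                break
    return counts
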