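"""Subgroup analyses: sex-imbalance ROR per PT and age-stratified signals.

The sex analysis compares, among the target drug's reports only, how often
each PT is reported for female vs male patients (unknown sex excluded from
both margins).  A PT is female-skewed when the 95% CI lower bound of the
F:M reporting odds ratio exceeds 1 with at least 3 combined cases, and
male-skewed when the upper bound is below 1.

Age stratification rebuilds the drug-vs-rest contingency tables within
each age stratum (<18, 18-64, >=65, unknown), so a signal concentrated in
one stratum is not diluted by the others.  Ages are normalised to years
from the FAERS unit codes (YR, DEC, MON, WK, DY, HR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PairUniverse
from .dispro import Z95, detect_signals
from .faers_io import as_frame

__all__ = [
    "SexImbalanceResult",
    "sex_imbalance",
    "age_in_years",
    "age_stratum",
    "AGE_STRATA",
    "stratified_signals",
]

AGE_STRATA = ("<18", "18-64", ">=65", "unknown")

#: multiplicative factors to years per FAERS age unit code
_AGE_FACTORS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766}


def age_in_years(age: str, age_cod: str) -> float:
    """Age normalised to years, NaN when the value or unit is missing/invalid."""
    s = str(age).strip()
    unit = str(age_cod).strip().upper()
    if not s or unit not in _AGE_FACTORS:
        return float("nan")
    try:
        value = float(s)
    except ValueError:
        return float("nan")
    if value < 0:
        return float("nan")
    return value * _AGE_FACTORS[unit]


def age_stratum(age: str, age_cod: str) -> str:
    """Stratum label; the 18.0 and 65.0 boundaries belong to the older bin."""
    years = age_in_years(age, age_cod)
    if np.isnan(years):
        return "unknown"
    if years < 18:
        return "<18"
    if years < 65:
        return "18-64"
    return ">=65"


@dataclass(frozen=True)
class SexImbalanceResult:
    """F-vs-M 2x2 for one PT over target-report pairs.

    ``ror_fm`` is the female:male reporting odds ratio
    (a_f*b_m)/(b_f*a_m); ``direction`` is 'female' when the CI excludes 1
    from above, 'male' from below, else 'none'.
    """

    pt: str
    a_f: int
    b_f: int
    a_m: int
    b_m: int
    ror_fm: float
    ci_lo: float
    ci_hi: float
    direction: str


def sex_imbalance(
    universe: PairUniverse,
    demo_records,
    min_cases: int = 3,
    zero_cell: str = "undefined",
) -> list[SexImbalanceResult]:
    """Sex-imbalance ROR for every PT among the target drug's pairs.

    Reports with unknown sex are excluded from both margins.  A zero cell
    leaves the ROR undefined (direction 'none') unless
    ``zero_cell='haldane'`` adds 0.5 to the four cells.
    """
    demo = as_frame(demo_records)
    sex_of = demo.set_index(demo["primaryid"].astype(str))["sex"].astype(str).str.upper()
    tgt = universe.pairs[universe.pairs["is_target"]].copy()
    if len(tgt) == 0:
        return []
    tgt["sex"] = tgt["primaryid"].map(sex_of)
    tgt = tgt[tgt["sex"].isin(["F", "M"])]
    n_f = int((tgt["sex"] == "F").sum())
    n_m = int((tgt["sex"] == "M").sum())

    results = []
    grouped = tgt.groupby("pt_key", sort=True)
    for _, grp in grouped:
        pt = grp["pt"].iloc[0]
        a_f = int((grp["sex"] == "F").sum())
        a_m = int((grp["sex"] == "M").sum())
        b_f = n_f - a_f
        b_m = n_m - a_m
        cells = np.array([a_f, b_f, a_m, b_m], dtype=float)
        if zero_cell == "haldane" and (cells == 0).any():
            cells = cells + 0.5
        af, bf, am, bm = cells
        if min(cells) <= 0:
            ror = lo = hi = float("nan")
        else:
            ror = (af * bm) / (bf * am)
            se = float(np.sqrt(1 / af + 1 / bf + 1 / am + 1 / bm))
            lo = ror * float(np.exp(-Z95 * se))
            hi = ror * float(np.exp(Z95 * se))
        direction = "none"
        if a_f + a_m >= min_cases and np.isfinite(lo):
            if lo > 1.0:
                direction = "female"
            elif hi < 1.0:
                direction = "male"
        results.append(
            SexImbalanceResult(pt, a_f, b_f, a_m, b_m, ror, lo, hi, direction)
        )
    return results


def stratified_signals(
    universe: PairUniverse,
    demo_records,
    strata: tuple[str, ...] = AGE_STRATA,
    **detect_kwargs,
) -> dict[str, pd.DataFrame]:
    """Signal tables per age stratum (same schema as ``detect_signals``).

    Each stratum restricts both the target and comparator pairs to reports
    of that age group, so the comparator is the rest of the database within
    the same stratum.  Unknown-age reports form their own stratum rather
    than being dropped; an empty stratum yields an empty table.
    """
    demo = as_frame(demo_records)
    labels = [age_stratum(a, c) for a, c in zip(demo["age"], demo["age_cod"])]
    stratum_of = pd.Series(labels, index=demo["primaryid"].astype(str))
    pair_stratum = universe.pairs["primaryid"].map(stratum_of)
    demo_stratum = pd.Series(labels, index=demo.index)

    out: dict[str, pd.DataFrame] = {}
    for label in strata:
        mask = (pair_stratum == label).fillna(False).to_numpy(dtype=bool)
        sub_pairs = universe.pairs[mask].reset_index(drop=True)
        ids = set(demo.loc[(demo_stratum == label).to_numpy(), "primaryid"].astype(str))
        sub = PairUniverse(
            pairs=sub_pairs,
            n_reports_total=len(ids),
            n_target_reports=len(ids & universe.target_ids),
            n_target_pairs=int(sub_pairs["is_target"].sum()) if len(sub_pairs) else 0,
            target_ids=universe.target_ids,
        )
        out[label] = detect_signals(sub, **detect_kwargs)
    return out
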