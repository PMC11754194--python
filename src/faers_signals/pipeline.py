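"""End-to-end pipeline: ingest, clean, screen, mine, summarise, write.

``run_pipeline`` drives the whole analysis for one configuration — either
a directory of FAERS-style quarterly ASCII files or a synthetic
configuration rendered to such files first — and writes TSV outputs, a
structured run log (the cohort funnel with exact reconciliation) and a
config echo into the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import pct, round_half_up
from .cohort import (
    ECULIZUMAB_KEYWORDS,
    PairUniverse,
    ScreeningKeywords,
    build_report_event_pairs,
    deduplicate_reports,
    remove_deleted,
    screen_target_drug,
    target_drug_rows,
)
from .dispro import detect_signals
from .faers_io import (
    TABLE_SCHEMAS,
    parse_faers_date,
    read_ascii_table,
    records_to_frame,
)
from .subgroup import AGE_STRATA, age_stratum, sex_imbalance, stratified_signals
from .synthetic import SyntheticConfig, generate_dataset
from .tto import OnsetRecord, bin_tto, compute_onset_days, summarize_tto

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "rank_signals",
    "annual_report_counts",
    "demographic_table",
    "soc_aggregate",
    "load_tables",
    "format_signal_table",
]

#: outcome code -> Table-4-style label
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization - Initial or Prolonged",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent Impairment/Damage",
    "OT": "Other",
}
SERIOUS_CODES = ("DE", "LT", "HO", "DS", "CA", "RI")

OCCP_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "PH": "Pharmacist",
    "LW": "Lawyer",
    "OT": "Other health-professional",
    "": "Not Specified",
}


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one of input_dir / synthetic."""

    output_dir: str | Path
    input_dir: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    keywords: ScreeningKeywords = field(default_factory=lambda: ECULIZUMAB_KEYWORDS)
    pt_soc_map: str | Path | None = None  # two-column TSV (pt, soc); MedDRA is licensed
    ic_method: str = "mcmc-dirichlet"
    mcmc_draws: int = 100_000
    zero_cell: str = "undefined"
    unit: str = "pair"
    min_case_count: int = 30  # ranking keeps a strictly greater than this
    top_n: int = 100
    impute_partial: str = "none"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir / synthetic must be given")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir} does not exist")
        if self.pt_soc_map is not None and not Path(self.pt_soc_map).is_file():
            raise FileNotFoundError(f"PT->SOC map {self.pt_soc_map} does not exist")


@dataclass
class PipelineResult:
    """Computed artefacts of one run plus the paths they were written to."""

    signals: pd.DataFrame
    ranked: pd.DataFrame
    universe: PairUniverse
    demographics: pd.DataFrame
    annual_counts: dict[str, int]
    tto_summary: dict
    tto_bins: dict[str, int]
    sex_imbalance: list
    strata: dict[str, pd.DataFrame]
    soc_summary: pd.DataFrame
    run_log: dict
    output_dir: Path


def load_tables(input_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read every ``<kind>_<quarter>.txt`` file under ``input_dir`` and
    concatenate per table kind (empty frame when a kind is absent)."""
    input_dir = Path(input_dir)
    out: dict[str, pd.DataFrame] = {}
    for kind in TABLE_SCHEMAS:
        frames = []
        for path in sorted(input_dir.glob(f"{kind}_*.txt")):
            frames.append(records_to_frame(read_ascii_table(path, kind)))
        non_empty = [f for f in frames if len(f)]
        if non_empty:
            out[kind] = pd.concat(non_empty, ignore_index=True)
        else:
            record_type, _ = TABLE_SCHEMAS[kind]
            cols = [f.name for f in dataclasses.fields(record_type) if f.name != "outcomes"]
            out[kind] = pd.DataFrame(columns=cols)
    return out


def rank_signals(signal_table: pd.DataFrame, min_case_count: int = 30, top_n: int = 100) -> pd.DataFrame:
    """PTs passing all four algorithms with a strictly greater than
    ``min_case_count``, ranked by EBGM05 descending (ties: larger a first,
    then PT name), truncated to ``top_n``."""
    if len(signal_table) == 0:
        return signal_table.copy()
    keep = signal_table[(signal_table["pass_all"]) & (signal_table["a"] > min_case_count)]
    keep = keep.sort_values(
        ["ebgm05", "a", "pt"], ascending=[False, False, True], na_position="last",
        kind="mergesort",
    )
    return keep.head(top_n).reset_index(drop=True)


def annual_report_counts(demo: pd.DataFrame) -> dict[str, int]:
    """Report counts by FDA receipt year; unparseable dates fall in 'unknown'."""
    counts: dict[str, int] = {}
    if len(demo) == 0:
        return counts
    for raw in demo["fda_dt"].astype(str):
        p = parse_faers_date(raw)
        key = str(p.year) if p.year is not None else "unknown"
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def _serious(outcomes) -> bool:
    return any(code in SERIOUS_CODES for code in outcomes)


def demographic_table(
    demo: pd.DataFrame,
    outc: pd.DataFrame | None = None,
    onset_records: list[OnsetRecord] | None = None,
    top_countries: int = 5,
) -> pd.DataFrame:
    """Descriptive cohort table (sex, age, reporter, country, seriousness,
    outcomes, onset bins) with percentages of the cohort size, half-up 2 dp.

    Every categorical block sums to the cohort size via explicit
    Not-Specified / Other rows; the outcome block adds 'No outcome
    recorded' so it reconciles too (a report may carry several outcome
    codes — seriousness uses the report level, the outcome block counts
    reports per code).
    """
    n = len(demo)
    if n == 0:
        raise ValueError("empty cohort")
    rows: list[tuple[str, str, int]] = []

    sex = demo["sex"].astype(str).str.upper()
    rows.append(("Gender", "Female", int((sex == "F").sum())))
    rows.append(("Gender", "Male", int((sex == "M").sum())))
    rows.append(("Gender", "Not Specified", int((~sex.isin(["F", "M"])).sum())))

    strata = [age_stratum(a, c) for a, c in zip(demo["age"], demo["age_cod"])]
    svals = pd.Series(strata)
    for label, display in [("<18", "<18"), ("18-64", ">=18, <65"), (">=65", ">=65"),
                           ("unknown", "Not Specified")]:
        rows.append(("Age (years)", display, int((svals == label).sum())))

    occp = demo["occp_cod"].astype(str).str.upper() if "occp_cod" in demo else pd.Series("", index=demo.index)
    known = set(OCCP_LABELS) - {""}
    for code in sorted(known):
        rows.append(("Reported Person", OCCP_LABELS[code], int((occp == code).sum())))
    rows.append(("Reported Person", "Not Specified", int((~occp.isin(known)).sum())))

    country = demo.get("reporter_country", pd.Series("", index=demo.index)).astype(str)
    country = country.where(country.str.strip() != "", "Not Specified")
    vc = country.value_counts()
    top = [k for k in vc.index if k != "Not Specified"][:top_countries]
    for name in top:
        rows.append(("Reported Countries", name, int(vc[name])))
    other = n - sum(int(vc[k]) for k in top) - int(vc.get("Not Specified", 0))
    rows.append(("Reported Countries", "Other", other))
    rows.append(("Reported Countries", "Not Specified", int(vc.get("Not Specified", 0))))

    # outcomes: attach OUTC codes per report
    codes_of: dict[str, set] = {}
    if outc is not None and len(outc):
        for pid, code in zip(outc["primaryid"].astype(str), outc["outc_cod"].astype(str)):
            codes_of.setdefault(pid, set()).add(code.upper())
    pids = demo["primaryid"].astype(str)
    outcome_sets = [codes_of.get(p, set()) for p in pids]
    n_serious = sum(1 for s in outcome_sets if _serious(s))
    rows.append(("Serious reports", "Serious", n_serious))
    rows.append(("Serious reports", "Non-Serious", n - n_serious))
    for code, label in OUTCOME_LABELS.items():
        rows.append(("Outcome", label, sum(1 for s in outcome_sets if code in s)))
    rows.append(("Outcome", "No outcome recorded", sum(1 for s in outcome_sets if not s)))

    if onset_records is not None:
        bins = bin_tto(onset_records)
        for label, count in bins.items():
            display = "Missing or outliers (<0)" if label == "excluded" else f"{label}d"
            rows.append(("Time to event onset (days)", display, count))

    df = pd.DataFrame(rows, columns=["block", "category", "count"])
    df["pct"] = [pct(cnt, n) for cnt in df["count"]]
    return df


def soc_aggregate(signal_table: pd.DataFrame, pt_to_soc: dict[str, str] | str | Path) -> pd.DataFrame:
    """Aggregate passing PTs by system organ class.

    ``pt_to_soc`` is a mapping or the path of a two-column TSV (pt, soc);
    PTs absent from the map land in 'UNMAPPED' (logged) so totals are
    conserved.  Returns per SOC the number of passing PTs, the summed case
    count a, and both as percentages of the respective totals.
    """
    if not isinstance(pt_to_soc, dict):
        mapping_df = pd.read_csv(pt_to_soc, sep="\t", dtype=str)
        pt_to_soc = dict(zip(mapping_df.iloc[:, 0], mapping_df.iloc[:, 1]))
    lut = {str(k).casefold().strip(): str(v) for k, v in pt_to_soc.items()}
    passing = signal_table[signal_table["pass_all"]] if len(signal_table) else signal_table
    if len(passing) == 0:
        return pd.DataFrame(columns=["soc", "n_pts", "pct_pts", "n_cases", "pct_cases"])
    socs = [lut.get(str(p).casefold().strip(), "UNMAPPED") for p in passing["pt"]]
    n_unmapped = sum(1 for s in socs if s == "UNMAPPED")
    if n_unmapped:
        logger.warning("%d passing PT(s) missing from the PT->SOC map", n_unmapped)
    df = pd.DataFrame({"soc": socs, "a": passing["a"].to_numpy()})
    agg = df.groupby("soc", sort=True).agg(n_pts=("a", "size"), n_cases=("a", "sum")).reset_index()
    total_pts = int(agg["n_pts"].sum())
    total_cases = int(agg["n_cases"].sum())
    agg["pct_pts"] = [pct(v, total_pts) for v in agg["n_pts"]]
    agg["pct_cases"] = [pct(v, total_cases) for v in agg["n_cases"]]
    return agg[["soc", "n_pts", "pct_pts", "n_cases", "pct_cases"]]


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else f"{round_half_up(x, 2):.2f}"


def format_signal_table(signal_table: pd.DataFrame, pt_to_soc: dict[str, str] | None = None) -> pd.DataFrame:
    """Render a signal table with display columns: ROR (95% CI), PRR,
    chi2, IC (IC025), EBGM (EBGM05), grade and pass flags, 2 dp half-up."""
    lut = {str(k).casefold().strip(): str(v) for k, v in (pt_to_soc or {}).items()}
    out = pd.DataFrame(
        {
            "soc": [lut.get(str(p).casefold().strip(), "UNMAPPED") for p in signal_table["pt"]]
            if lut
            else "",
            "pt": signal_table["pt"],
            "a": signal_table["a"],
            "ror_ci": [
                f"{_fmt(r)} ({_fmt(lo)}-{_fmt(hi)})"
                for r, lo, hi in zip(signal_table["ror"], signal_table["ror_lo"], signal_table["ror_hi"])
            ],
            "prr": [_fmt(v) for v in signal_table["prr"]],
            "chi2": [_fmt(v) for v in signal_table["chi2"]],
            "ic_ic025": [
                f"{_fmt(v)} ({_fmt(lo)})" for v, lo in zip(signal_table["ic"], signal_table["ic_lo"])
            ],
            "ebgm_ebgm05": [
                f"{_fmt(v)} ({_fmt(lo)})" for v, lo in zip(signal_table["ebgm"], signal_table["ebgm05"])
            ],
            "grade": signal_table["grade"],
            "pass_ror": signal_table["pass_ror"],
            "pass_prr": signal_table["pass_prr"],
            "pass_bcpnn": signal_table["pass_bcpnn"],
            "pass_mgps": signal_table["pass_mgps"],
            "pass_all": signal_table["pass_all"],
        }
    )
    return out


def _target_onset_records(
    demo: pd.DataFrame,
    ther: pd.DataFrame,
    match_rows: pd.DataFrame,
    impute_partial: str,
) -> list[OnsetRecord]:
    """Onset records for the cohort: event date vs the target drug's
    earliest THER start, matched through drug_seq."""
    if len(ther):
        merged = match_rows.merge(
            ther,
            left_on=["primaryid", "drug_seq"],
            right_on=["primaryid", "dsg_drug_seq"],
            how="left",
        )
        starts_of = (
            merged.groupby("primaryid")["start_dt"]
            .apply(lambda s: [v for v in s if isinstance(v, str)])
            .to_dict()
        )
    else:
        starts_of = {}
    records = []
    for pid, event_dt in zip(demo["primaryid"].astype(str), demo["event_dt"].astype(str)):
        records.append(
            compute_onset_days(pid, event_dt, starts_of.get(pid, []), impute_partial=impute_partial)
        )
    return records


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; deterministic for a given config and seed."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "counts": {}}
    t_all = time.perf_counter()

    def stage(name):
        log["stages"][name] = {"seconds": None}
        return name, time.perf_counter()

    def done(handle):
        name, t0 = handle
        log["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)

    h = stage("ingest")
    pt_soc_path = config.pt_soc_map
    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic, out_dir / "dataset")
        input_dir = dataset.root
        if pt_soc_path is None:
            pt_soc_path = dataset.pt_soc_map
    else:
        input_dir = Path(config.input_dir)
    tables = load_tables(input_dir)
    demo, drug, reac = tables["demo"], tables["drug"], tables["reac"]
    ther, outc, dele = tables["ther"], tables["outc"], tables["dele"]
    log["counts"]["raw_reports"] = len(demo)
    done(h)

    h = stage("clean")
    demo_kept, n_deleted = remove_deleted(demo, dele)
    deduped = deduplicate_reports(demo_kept)
    n_dups = len(demo_kept) - len(deduped)
    log["counts"]["deleted_cases_removed"] = n_deleted
    log["counts"]["duplicate_reports_removed"] = n_dups
    log["counts"]["cohort_candidates"] = len(deduped)
    assert log["counts"]["raw_reports"] - n_deleted - n_dups == len(deduped)
    done(h)

    h = stage("screen")
    target_ids = screen_target_drug(drug, config.keywords)
    match_rows = target_drug_rows(drug, config.keywords)
    universe = build_report_event_pairs(deduped, reac, target_ids)
    log["counts"]["target_reports"] = universe.n_target_reports
    log["counts"]["pairs_total"] = universe.n_pairs
    log["counts"]["target_pairs"] = universe.n_target_pairs
    log["counts"]["orphan_reac_rows_dropped"] = universe.n_dropped_orphans
    done(h)

    h = stage("signals")
    signals = detect_signals(
        universe,
        ic_method=config.ic_method,
        zero_cell=config.zero_cell,
        unit=config.unit,
        mcmc_draws=config.mcmc_draws,
        seed=config.seed,
    )
    ranked = rank_signals(signals, config.min_case_count, config.top_n)
    log["counts"]["pts_mined"] = len(signals)
    log["counts"]["pts_pass_all"] = int(signals["pass_all"].sum()) if len(signals) else 0
    done(h)

    h = stage("descriptive")
    target_set = set(deduped["primaryid"].astype(str)) & target_ids
    cohort_demo = deduped[deduped["primaryid"].astype(str).isin(target_set)]
    onset_records = _target_onset_records(cohort_demo, ther, match_rows, config.impute_partial)
    demographics = (
        demographic_table(cohort_demo, outc, onset_records) if len(cohort_demo) else pd.DataFrame()
    )
    annual = annual_report_counts(cohort_demo)
    tto_summary = summarize_tto(onset_records)
    tto_bins = bin_tto(onset_records)
    done(h)

    h = stage("subgroups")
    imbalance = sex_imbalance(universe, deduped, zero_cell=config.zero_cell)
    strata = stratified_signals(
        universe,
        deduped,
        ic_method=config.ic_method,
        zero_cell=config.zero_cell,
        unit=config.unit,
        mcmc_draws=config.mcmc_draws,
        seed=config.seed,
    )
    done(h)

    h = stage("write")
    pt_soc = None
    if pt_soc_path is not None:
        mdf = pd.read_csv(pt_soc_path, sep="\t", dtype=str)
        pt_soc = dict(zip(mdf.iloc[:, 0], mdf.iloc[:, 1]))
    signals.to_csv(out_dir / "signals.tsv", sep="\t", index=False)
    format_signal_table(ranked, pt_soc).to_csv(out_dir / "ranked_signals.tsv", sep="\t", index=False)
    soc_summary = (
        soc_aggregate(signals, pt_soc) if pt_soc is not None else
        pd.DataFrame(columns=["soc", "n_pts", "pct_pts", "n_cases", "pct_cases"])
    )
    soc_summary.to_csv(out_dir / "soc_summary.tsv", sep="\t", index=False)
    if len(demographics):
        demographics.to_csv(out_dir / "demographics.tsv", sep="\t", index=False)
    pd.DataFrame(annual.items(), columns=["year", "n_reports"]).to_csv(
        out_dir / "annual_counts.tsv", sep="\t", index=False
    )
    n_cohort = len(cohort_demo)
    tto_rows = [
        {"bin": label, "count": cnt, "pct": pct(cnt, n_cohort) if n_cohort else float("nan")}
        for label, cnt in tto_bins.items()
    ]
    tto_df = pd.DataFrame(tto_rows)
    tto_df.to_csv(out_dir / "tto_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [dataclasses.asdict(r) for r in imbalance]
    ).to_csv(out_dir / "sex_imbalance.tsv", sep="\t", index=False)
    for label, table in strata.items():
        safe = label.replace("<", "lt").replace(">=", "ge")
        table.to_csv(out_dir / f"signals_stratum_{safe}.tsv", sep="\t", index=False)
    log["counts"]["tto_included"] = tto_summary["n_included"]
    log["seconds_total"] = round(time.perf_counter() - t_all, 3)
    with (out_dir / "run_log.json").open("w") as fh:
        json.dump(log, fh, indent=2)
    with (out_dir / "config_echo.json").open("w") as fh:
        json.dump(_config_echo(config), fh, indent=2, default=str)
    done(h)

    return PipelineResult(
        signals=signals,
        ranked=ranked,
        universe=universe,
        demographics=demographics,
        annual_counts=annual,
        tto_summary=tto_summary,
        tto_bins=tto_bins,
        sex_imbalance=imbalance,
        strata=strata,
        soc_summary=soc_summary,
        run_log=log,
        output_dir=out_dir,
    )


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    return echo
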