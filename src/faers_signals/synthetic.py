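"""Synthetic FAERS-like dataset generator with planted drug-event signals.

Every downstream stage of the pipeline (deduplication, drug screening,
disproportionality, time-to-onset, subgroups) is testable against ground
truth because the generator controls the joint distribution of reports,
drugs and events:

* each base report gets one primary-suspect (PS) drug drawn from
  ``drug_probs`` plus a Poisson number of concomitant drugs;
* each (report, PT) event is an independent Bernoulli draw whose
  probability is the PT's baseline, multiplied by ``target_rr`` when a
  planted signal's drug is the report's PS drug (capped at 1);
* FAERS artefacts are injected on top: duplicate CASEIDs under new
  PRIMARYIDs with equal or later FDA_DT, FDA-deleted cases, high
  missingness in sex/age/dates, 6-digit partial dates and negative
  drug-event intervals.

``expected_counts`` returns the analytic expectation of the 2x2 cells for
each planted signal (before duplicate/deletion injection), which serves as
an independent oracle for the analysis stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DrugSpec",
    "PlantedSignal",
    "SyntheticConfig",
    "SimulatedTables",
    "QuarterlyFileSet",
    "generate_tables",
    "generate_dataset",
    "expected_counts",
    "recovery_config",
]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class DrugSpec:
    """A drug as it appears in DRUG rows: verbatim name + active ingredient."""

    drugname: str
    prod_ai: str


@dataclass(frozen=True)
class PlantedSignal:
    """Ground-truth association: reports whose PS drug is ``drug`` report
    ``pt`` with probability min(1, target_rr * baseline)."""

    drug: str
    pt: str
    target_rr: float


def _default_sex_probs():
    return {"F": 0.47, "M": 0.32, "UNK": 0.21}


def _default_age_probs():
    return {"<18": 0.04, "18-64": 0.18, ">=65": 0.06, "unknown": 0.72}


def _default_role_probs():
    return {"SS": 0.3, "C": 0.6, "I": 0.1}


def _default_occp_probs():
    return {"CN": 0.74, "MD": 0.13, "OT": 0.06, "PH": 0.03, "LW": 0.001, "": 0.039}


def _default_country_probs():
    return {"US": 0.79, "BR": 0.03, "GB": 0.03, "JP": 0.02, "CA": 0.02, "FR": 0.06, "DE": 0.05}


def _default_outcome_probs():
    # marginal, independent per code; roughly the mix seen in public FAERS
    return {"HO": 0.28, "DE": 0.10, "LT": 0.016, "DS": 0.005, "CA": 0.0004, "RI": 0.0001, "OT": 0.45}


@dataclass
class SyntheticConfig:
    """Full specification of one simulated reporting database.

    Probabilities are per-report (or per report x PT for events); the four
    categorical distributions must each sum to 1 within 1e-9.
    """

    n_reports: int
    quarters: list[str]
    drugs: list[DrugSpec]
    pts: list[tuple[str, str]]  # (preferred term, SOC)
    baseline_event_prob: float
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    pt_event_probs: dict[str, float] | None = None  # per-PT override of the baseline
    drug_probs: list[float] | None = None  # PS-drug distribution; uniform if None
    concomitant_rate: float = 0.5  # Poisson mean of extra non-PS drugs
    duplicate_rate: float = 0.0
    deleted_rate: float = 0.0
    missing_event_dt_rate: float = 0.5
    missing_start_dt_rate: float = 0.3
    partial_date_rate: float = 0.1
    negative_onset_rate: float = 0.02
    onset_median_days: float = 150.0
    onset_log_sigma: float = 1.5
    sex_probs: dict[str, float] = field(default_factory=_default_sex_probs)
    age_probs: dict[str, float] = field(default_factory=_default_age_probs)
    role_probs: dict[str, float] = field(default_factory=_default_role_probs)
    occp_probs: dict[str, float] = field(default_factory=_default_occp_probs)
    country_probs: dict[str, float] = field(default_factory=_default_country_probs)
    outcome_probs: dict[str, float] = field(default_factory=_default_outcome_probs)
    seed: int = 0

    def pt_names(self) -> list[str]:
        return [p for p, _ in self.pts]

    def event_prob(self, pt: str) -> float:
        if self.pt_event_probs and pt in self.pt_event_probs:
            return self.pt_event_probs[pt]
        return self.baseline_event_prob

    def ps_share(self, drug: str) -> float:
        names = [d.drugname for d in self.drugs]
        probs = self.drug_probs or [1.0 / len(names)] * len(names)
        return probs[names.index(drug)]

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ConfigError("n_reports must be >= 1")
        if not self.quarters:
            raise ConfigError("at least one quarter required")
        if not self.drugs:
            raise ConfigError("at least one drug required")
        if not self.pts:
            raise ConfigError("at least one PT required")
        if not (0.0 < self.baseline_event_prob < 1.0):
            raise ConfigError("baseline_event_prob must be in (0, 1)")
        for name, rate in [
            ("duplicate_rate", self.duplicate_rate),
            ("deleted_rate", self.deleted_rate),
            ("missing_event_dt_rate", self.missing_event_dt_rate),
            ("missing_start_dt_rate", self.missing_start_dt_rate),
            ("partial_date_rate", self.partial_date_rate),
            ("negative_onset_rate", self.negative_onset_rate),
        ]:
            if not (0.0 <= rate < 1.0):
                raise ConfigError(f"{name} must be in [0, 1)")
        for name, dist in [
            ("sex_probs", self.sex_probs),
            ("age_probs", self.age_probs),
            ("role_probs", self.role_probs),
            ("occp_probs", self.occp_probs),
            ("country_probs", self.country_probs),
        ]:
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
            if any(p < 0 for p in dist.values()):
                raise ConfigError(f"{name} has a negative probability")
        if self.drug_probs is not None:
            if len(self.drug_probs) != len(self.drugs):
                raise ConfigError("drug_probs length must match drugs")
            if abs(sum(self.drug_probs) - 1.0) > 1e-9:
                raise ConfigError("drug_probs must sum to 1")
        drug_names = {d.drugname for d in self.drugs}
        pt_names = {p for p, _ in self.pts}
        if self.pt_event_probs:
            unknown = set(self.pt_event_probs) - pt_names
            if unknown:
                raise ConfigError(f"pt_event_probs for unknown PTs: {sorted(unknown)}")
            if any(not (0.0 < v < 1.0) for v in self.pt_event_probs.values()):
                raise ConfigError("pt_event_probs values must be in (0, 1)")
        seen = set()
        for s in self.planted_signals:
            if s.drug not in drug_names:
                raise ConfigError(f"planted signal on unknown drug {s.drug!r}")
            if s.pt not in pt_names:
                raise ConfigError(f"planted signal on unknown PT {s.pt!r}")
            if s.target_rr < 0:
                raise ConfigError("target_rr must be >= 0")
            if (s.drug, s.pt) in seen:
                raise ConfigError(f"duplicate planted signal for {(s.drug, s.pt)}")
            seen.add((s.drug, s.pt))


@dataclass
class SimulatedTables:
    """In-memory simulated database: one DataFrame per FAERS table.

    ``demo`` carries an internal ``_quarter`` column used to split files;
    it is dropped on write.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    dele: pd.DataFrame
    ground_truth: pd.DataFrame
    pt_soc_map: pd.DataFrame
    config: SyntheticConfig


@dataclass
class QuarterlyFileSet:
    """Paths of an emitted dataset: per-quarter table files plus sidecars."""

    root: Path
    quarters: list[str]
    tables: dict[str, dict[str, Path]]  # kind -> quarter -> path
    ground_truth: Path
    pt_soc_map: Path

    def paths_for(self, kind: str) -> list[Path]:
        return [self.tables[kind][q] for q in self.quarters]


def _quarter_bounds(label: str) -> tuple[np.datetime64, int]:
    """Return (first day, number of days) of a quarter label like '2020Q1'."""
    try:
        year = int(label[:4])
        q = int(label[5])
        assert label[4] in "Qq" and 1 <= q <= 4
    except (ValueError, IndexError, AssertionError):
        raise ConfigError(f"bad quarter label {label!r}") from None
    start = np.datetime64(f"{year:04d}-{(q - 1) * 3 + 1:02d}-01")
    if q == 4:
        end = np.datetime64(f"{year + 1:04d}-01-01")
    else:
        end = np.datetime64(f"{year:04d}-{q * 3 + 1:02d}-01")
    return start, int((end - start) / np.timedelta64(1, "D"))


def _fmt_dates(days: np.ndarray) -> np.ndarray:
    """Vectorised datetime64[D] -> 'YYYYMMDD' strings."""
    s = np.datetime_as_string(days.astype("datetime64[D]"), unit="D")
    return np.char.replace(s, "-", "")


def _categorical(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.asarray(keys, dtype=object)[idx]


def generate_tables(config: SyntheticConfig) -> SimulatedTables:
    """Simulate the database in memory; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pt_names = np.asarray(config.pt_names(), dtype=object)
    n_pts = len(pt_names)
    drug_names = [d.drugname for d in config.drugs]
    prod_ais = {d.drugname: d.prod_ai for d in config.drugs}

    caseid_num = np.arange(10_000_000, 10_000_000 + n, dtype=np.int64)
    caseid = caseid_num.astype(str).astype(object)
    primaryid = (caseid_num * 10 + 1).astype(str).astype(object)

    # --- quarters and FDA receipt dates -----------------------------------
    q_idx = rng.integers(0, len(config.quarters), size=n)
    starts, lengths = zip(*(_quarter_bounds(q) for q in config.quarters))
    starts = np.asarray(starts)
    lengths = np.asarray(lengths)
    fda_day = starts[q_idx] + rng.integers(0, lengths[q_idx]).astype("timedelta64[D]")
    quarter = np.asarray(config.quarters, dtype=object)[q_idx]

    # --- primary-suspect drug and concomitants ----------------------------
    probs = config.drug_probs or [1.0 / len(drug_names)] * len(drug_names)
    ps_idx = rng.choice(len(drug_names), size=n, p=np.asarray(probs) / np.sum(probs))
    n_extra = rng.poisson(config.concomitant_rate, size=n)
    n_extra = np.minimum(n_extra, len(drug_names) - 1)

    # --- events: independent Bernoulli per (report, PT) -------------------
    base = np.array([config.event_prob(p) for p in pt_names], dtype=float)
    prob = np.broadcast_to(base, (n, n_pts)).copy()
    for sig in config.planted_signals:
        g = drug_names.index(sig.drug)
        j = int(np.nonzero(pt_names == sig.pt)[0][0])
        rows = ps_idx == g
        prob[rows, j] = min(1.0, sig.target_rr * base[j])
    events = rng.random((n, n_pts)) < prob
    ev_r, ev_c = np.nonzero(events)

    # --- event and therapy-start dates ------------------------------------
    report_delay = rng.integers(0, 61, size=n).astype("timedelta64[D]")
    event_day = fda_day - report_delay
    onset = np.rint(
        rng.lognormal(np.log(config.onset_median_days), config.onset_log_sigma, size=n)
    ).astype(np.int64)
    negative = rng.random(n) < config.negative_onset_rate
    onset = np.where(negative, -rng.integers(1, 101, size=n), onset)
    start_day = event_day - onset.astype("timedelta64[D]")

    event_dt = _fmt_dates(event_day).astype(object)
    start_dt = _fmt_dates(start_day).astype(object)
    # partial dates first (YYYYMM), then missingness on top
    ev_partial = rng.random(n) < config.partial_date_rate
    st_partial = rng.random(n) < config.partial_date_rate
    event_dt[ev_partial] = [s[:6] for s in event_dt[ev_partial]]
    start_dt[st_partial] = [s[:6] for s in start_dt[st_partial]]
    event_dt[rng.random(n) < config.missing_event_dt_rate] = ""
    start_dt[rng.random(n) < config.missing_start_dt_rate] = ""

    # --- demographics ------------------------------------------------------
    sex = _categorical(rng, config.sex_probs, n)
    sex[sex == "UNK"] = ""
    stratum = _categorical(rng, config.age_probs, n)
    age = np.full(n, "", dtype=object)
    age_cod = np.full(n, "", dtype=object)
    child = stratum == "<18"
    adult = stratum == "18-64"
    old = stratum == ">=65"
    child_years = rng.integers(0, 18, size=int(child.sum()))
    child_age = child_years.astype(object)
    child_cod = np.full(int(child.sum()), "YR", dtype=object)
    infants = child_years < 2
    child_age[infants] = (child_years[infants] * 12 + rng.integers(0, 12, size=int(infants.sum())))
    child_cod[infants] = "MON"
    age[child] = [str(v) for v in child_age]
    age_cod[child] = child_cod
    age[adult] = rng.integers(18, 65, size=int(adult.sum())).astype(str)
    age_cod[adult] = "YR"
    old_years = rng.integers(65, 91, size=int(old.sum()))
    old_age = old_years.astype(str).astype(object)
    old_cod = np.full(int(old.sum()), "YR", dtype=object)
    dec = rng.random(int(old.sum())) < 0.05  # a few records use decades
    old_age[dec] = [f"{y / 10:.1f}" for y in old_years[dec]]
    old_cod[dec] = "DEC"
    age[old] = old_age
    age_cod[old] = old_cod
    occp = _categorical(rng, config.occp_probs, n)
    country = _categorical(rng, config.country_probs, n)

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "fda_dt": _fmt_dates(fda_day),
            "event_dt": event_dt,
            "sex": sex,
            "age": age,
            "age_cod": age_cod,
            "occp_cod": occp,
            "reporter_country": country,
            "_quarter": quarter,
        }
    )

    # --- DRUG / THER rows ---------------------------------------------------
    drug_rows = {"primaryid": [], "drug_seq": [], "role_cod": [], "drugname": [], "prod_ai": []}
    ther_rows = {"primaryid": [], "dsg_drug_seq": [], "start_dt": []}
    extra_roles_all = _categorical(rng, config.role_probs, int(n_extra.sum()))
    extra_cursor = 0
    n_drugs = len(drug_names)
    for i in range(n):
        pid = primaryid[i]
        g = int(ps_idx[i])
        drug_rows["primaryid"].append(pid)
        drug_rows["drug_seq"].append("1")
        drug_rows["role_cod"].append("PS")
        drug_rows["drugname"].append(drug_names[g])
        drug_rows["prod_ai"].append(prod_ais[drug_names[g]])
        ther_rows["primaryid"].append(pid)
        ther_rows["dsg_drug_seq"].append("1")
        ther_rows["start_dt"].append(start_dt[i])
        k = int(n_extra[i])
        if k:
            others = [j for j in range(n_drugs) if j != g]
            chosen = rng.choice(others, size=k, replace=False)
            for seq, j in enumerate(chosen, start=2):
                drug_rows["primaryid"].append(pid)
                drug_rows["drug_seq"].append(str(seq))
                drug_rows["role_cod"].append(extra_roles_all[extra_cursor])
                extra_cursor += 1
                drug_rows["drugname"].append(drug_names[j])
                drug_rows["prod_ai"].append(prod_ais[drug_names[j]])
                ther_rows["primaryid"].append(pid)
                ther_rows["dsg_drug_seq"].append(str(seq))
                ther_rows["start_dt"].append("")
    drug = pd.DataFrame(drug_rows)
    ther = pd.DataFrame(ther_rows)

    reac = pd.DataFrame({"primaryid": primaryid[ev_r], "pt": pt_names[ev_c]})

    # --- outcomes -----------------------------------------------------------
    outc_pid, outc_cod = [], []
    for code, p in config.outcome_probs.items():
        hit = rng.random(n) < p
        outc_pid.append(primaryid[hit])
        outc_cod.append(np.full(int(hit.sum()), code, dtype=object))
    outc = pd.DataFrame(
        {"primaryid": np.concatenate(outc_pid), "outc_cod": np.concatenate(outc_cod)}
    )
    outc = outc.sort_values(["primaryid", "outc_cod"], kind="stable").reset_index(drop=True)

    # --- duplicate injection ------------------------------------------------
    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        dup_rows = rng.choice(n, size=n_dup, replace=False)
        dup_pid = (caseid_num[dup_rows] * 10 + 2).astype(str).astype(object)
        bump = rng.integers(0, 2, size=n_dup).astype(bool)  # half later FDA_DT, half equal
        dup_fda = fda_day[dup_rows] + np.where(
            bump, rng.integers(1, 91, size=n_dup), 0
        ).astype("timedelta64[D]")
        dup_demo = demo.iloc[dup_rows].copy()
        dup_demo["primaryid"] = dup_pid
        dup_demo["fda_dt"] = _fmt_dates(dup_fda)
        remap = dict(zip(primaryid[dup_rows], dup_pid))

        def _dup_table(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(remap)].copy()
            sub["primaryid"] = sub["primaryid"].map(remap)
            return sub

        demo = pd.concat([demo, dup_demo], ignore_index=True)
        drug = pd.concat([drug, _dup_table(drug)], ignore_index=True)
        reac = pd.concat([reac, _dup_table(reac)], ignore_index=True)
        ther = pd.concat([ther, _dup_table(ther)], ignore_index=True)
        outc = pd.concat([outc, _dup_table(outc)], ignore_index=True)

    # --- deletions ----------------------------------------------------------
    n_del = int(round(config.deleted_rate * n))
    if n_del:
        del_rows = rng.choice(n, size=n_del, replace=False)
        dele = pd.DataFrame({"caseid": caseid[np.sort(del_rows)]})
    else:
        dele = pd.DataFrame({"caseid": pd.Series([], dtype=object)})

    gt = expected_counts(config)
    pt_soc = pd.DataFrame({"pt": [p for p, _ in config.pts], "soc": [s for _, s in config.pts]})
    return SimulatedTables(demo, drug, reac, ther, outc, dele, gt, pt_soc, config)


def expected_counts(
    config: SyntheticConfig, pairs: Sequence[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Analytic expected 2x2 cells per planted signal, before duplicate or
    deletion injection.  ``pairs`` evaluates arbitrary (drug, PT) pairs
    instead — a non-planted pair has expected RR 1 (the null model).

    Expectations are over unique (report, PT) pairs: for a signal on drug g
    with PS share s and a PT with baseline beta,

        E[a] = N * s * min(1, rr * beta)
        E[c] = N * (1 - s) * beta   (plus any other signals on the same PT)

    and b/d sum the per-PT event probabilities over the remaining PTs.
    ``expected_rr`` is the report-level relative reporting ratio
    min(1, rr*beta)/beta; ``expected_ebgm`` evaluates the observed/expected
    statistic on the expected cells (the value the pipeline should recover).
    """
    config.validate()
    n = config.n_reports
    pt_names = config.pt_names()
    elevated = {(s.drug, s.pt): s.target_rr for s in config.planted_signals}
    drug_names = [d.drugname for d in config.drugs]

    def prob(drugname: str, pt: str) -> float:
        beta = config.event_prob(pt)
        rr = elevated.get((drugname, pt))
        return min(1.0, rr * beta) if rr is not None else beta

    if pairs is None:
        items = [(s.drug, s.pt, s.target_rr) for s in config.planted_signals]
    else:
        items = [(g, p, elevated.get((g, p), 1.0)) for g, p in pairs]
        for g, p, _ in items:
            if g not in drug_names:
                raise ConfigError(f"unknown drug {g!r}")
            if p not in pt_names:
                raise ConfigError(f"unknown PT {p!r}")

    rows = []
    for drug, pt, rr in items:
        s = config.ps_share(drug)
        beta = config.event_prob(pt)
        a = n * s * prob(drug, pt)
        b = n * s * sum(prob(drug, p) for p in pt_names if p != pt)
        c = n * sum(config.ps_share(g) * prob(g, pt) for g in drug_names if g != drug)
        d = n * sum(
            config.ps_share(g) * sum(prob(g, p) for p in pt_names if p != pt)
            for g in drug_names
            if g != drug
        )
        total = a + b + c + d
        ebgm = a * total / ((a + c) * (a + b)) if a > 0 else float("nan")
        rows.append(
            {
                "drug": drug,
                "pt": pt,
                "target_rr": rr,
                "expected_a": a,
                "expected_b": b,
                "expected_c": c,
                "expected_d": d,
                "expected_rr": prob(drug, pt) / beta,
                "expected_ebgm": ebgm,
            }
        )
    columns = [
        "drug", "pt", "target_rr", "expected_a", "expected_b", "expected_c",
        "expected_d", "expected_rr", "expected_ebgm",
    ]
    return pd.DataFrame(rows, columns=columns)


_TABLE_COLUMNS = {
    "demo": ["primaryid", "caseid", "fda_dt", "event_dt", "sex", "age", "age_cod",
             "occp_cod", "reporter_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "ther": ["primaryid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "outc_cod"],
    "dele": ["caseid"],
}


def _write_ascii(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    out = df[columns].astype(str)
    for col in columns:  # the dialect has no quoting; strip the delimiter
        if out[col].str.contains(r"\$", regex=True).any():
            out[col] = out[col].str.replace("$", " ", regex=False)
    out.to_csv(path, sep="$", index=False, lineterminator="\n")


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> QuarterlyFileSet:
    """Emit the simulated database as per-quarter "$"-delimited ASCII files.

    Layout: ``<out_dir>/<kind>_<quarter>.txt`` for each table kind plus
    ``ground_truth.tsv`` (planted signals with expected cells) and
    ``pt_soc_map.tsv``.  Byte-identical across runs for the same config.
    """
    tables = generate_tables(config)
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)

    quarter_of_case = tables.demo.drop_duplicates("caseid").set_index("caseid")["_quarter"]

    def quarter_of(df: pd.DataFrame) -> pd.Series:
        if "caseid" in df.columns:
            return df["caseid"].map(quarter_of_case)
        case = df["primaryid"].str[:-1]  # primaryid = caseid + version digit
        return case.map(quarter_of_case)

    paths: dict[str, dict[str, Path]] = {}
    frames = {"demo": tables.demo, "drug": tables.drug, "reac": tables.reac,
              "ther": tables.ther, "outc": tables.outc, "dele": tables.dele}
    for kind, df in frames.items():
        paths[kind] = {}
        q_series = quarter_of(df) if len(df) else pd.Series([], dtype=object)
        for q in config.quarters:
            sub = df[q_series == q] if len(df) else df
            path = root / f"{kind}_{q}.txt"
            _write_ascii(sub, _TABLE_COLUMNS[kind], path)
            paths[kind][q] = path

    gt_path = root / "ground_truth.tsv"
    tables.ground_truth.to_csv(gt_path, sep="\t", index=False, lineterminator="\n")
    map_path = root / "pt_soc_map.tsv"
    tables.pt_soc_map.to_csv(map_path, sep="\t", index=False, lineterminator="\n")
    return QuarterlyFileSet(root, list(config.quarters), paths, gt_path, map_path)


def recovery_config(target_rr: float, seed: int, n_reports: int = 20_000) -> SyntheticConfig:
    """Study configuration for planted-signal parameter recovery.

    The planted PT's baseline is set so that the elevated probability is
    0.9 (just under the cap), giving the signal cell a stable expected
    count, while the PS share (0.26%) and a heavy background event mass
    (500 null PTs) keep the drug's contribution to the PT margin small —
    without that, the observed/expected statistic on pair counts sits well
    below the planted report-level ratio.  See docs/methods.md for the
    bias algebra.
    """
    s = 0.0026
    beta_signal = 0.9 / target_rr
    n_null = 500
    pts = [("Planted event", "Synthetic SOC A")] + [
        (f"Background PT {i:03d}", "Synthetic SOC B") for i in range(n_null)
    ]
    return SyntheticConfig(
        n_reports=n_reports,
        quarters=["2020Q1", "2020Q2", "2020Q3", "2020Q4"],
        drugs=[
            DrugSpec("TARGETOMAB", "TARGETOMAB"),
            DrugSpec("OTHERDRUG", "OTHERCOMPOUND"),
        ],
        pts=pts,
        baseline_event_prob=0.1,
        pt_event_probs={"Planted event": beta_signal},
        planted_signals=[PlantedSignal("TARGETOMAB", "Planted event", target_rr)],
        drug_probs=[s, 1.0 - s],
        concomitant_rate=0.3,
        duplicate_rate=0.05,
        deleted_rate=0.02,
        seed=seed,
    )
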