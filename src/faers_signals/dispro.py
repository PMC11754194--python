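"""Disproportionality statistics for drug-event 2x2 tables.

Four signal-detection algorithms are computed from the same contingency
table of unique (report, preferred-term) pairs:

========  ==========================================  =======================
method    point estimate                              signal criterion
========  ==========================================  =======================
ROR       a*d / (b*c)                                 a >= 3 and CI95 low > 1
PRR       a*(c+d) / (c*(a+b)), with uncorrected chi2  a >= 3, PRR >= 2, chi2 >= 4
BCPNN     IC = log2( a*n / ((a+c)*(a+b)) )            IC025 > 0
MGPS      EBGM = a*n / ((a+c)*(a+b))                  EBGM05 > 2
========  ==========================================  =======================

ROR and EBGM share the log-scale standard error
``s = sqrt(1/a + 1/b + 1/c + 1/d)`` for their 95% intervals, so
``IC = log2(EBGM)`` exactly and ``ln(hi/lo)`` is identical for both.  This
EBGM is the plain observed/expected pair-reporting ratio — no Gamma-mixture
shrinkage is applied.

The IC interval ("IC +/- 2*SD") has no single canonical variance; two
methods are provided: a seeded Monte-Carlo credible interval from
independent Gamma posteriors with Jeffreys 0.5 priors on the four cells
(default), and the Bate et al. (1998) closed-form moment approximation.

Signal intensity is graded on IC025: (0, 1.5] weak (+), (1.5, 3] medium
(++), above 3 high (+++).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import PairUniverse, normalize_pt

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "SignalCriteria",
    "build_contingency",
    "compute_signal_stats",
    "evaluate_criteria",
    "grade_signal",
    "detect_signals",
    "GRADE_NONE",
    "GRADE_WEAK",
    "GRADE_MEDIUM",
    "GRADE_HIGH",
    "IC_METHODS",
]

GRADE_NONE = "none"
GRADE_WEAK = "weak(+)"
GRADE_MEDIUM = "medium(++)"
GRADE_HIGH = "high(+++)"

IC_METHODS = ("mcmc-dirichlet", "bate1998")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells: a = target pairs with the PT, b = target pairs with other
    PTs, c = non-target pairs with the PT, d = the rest."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table is empty (n = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalStats:
    """Point and interval estimates for one PT; NaN fields with an
    ``undefined_reason`` when a zero cell makes a formula undefined."""

    table: ContingencyTable
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic_lo: float
    ic_hi: float
    ebgm: float
    ebgm05: float
    ebgm95: float
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


@dataclass(frozen=True)
class SignalCriteria:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_ror and self.pass_prr and self.pass_bcpnn and self.pass_mgps


def build_contingency(universe: PairUniverse, pt: str, unit: str = "pair") -> ContingencyTable:
    """Count the 2x2 cells for one preferred term.

    ``unit='pair'`` counts unique (report, PT) pairs (a report contributes
    to both a and b when it lists the PT alongside others); ``'report'``
    counts reports, with margins a+b / c+d equal to the target and
    non-target report counts.
    """
    pairs = universe.pairs
    if len(pairs) == 0:
        raise ValueError("empty pair universe")
    key, _ = normalize_pt(pt)
    has_pt = pairs["pt_key"] == key
    tgt = pairs["is_target"]
    a = int((has_pt & tgt).sum())
    c = int((has_pt & ~tgt).sum())
    if unit == "pair":
        b = int(tgt.sum()) - a
        d = int((~tgt).sum()) - c
    elif unit == "report":
        b = universe.n_target_reports - a
        d = (universe.n_reports_total - universe.n_target_reports) - c
    else:
        raise ValueError(f"unknown counting unit {unit!r}")
    return ContingencyTable(a, b, c, d)


def _bate_ic_interval(a, b, c, d):
    """Bate et al. (1998) BCPNN moment approximation of E(IC) and V(IC).

    Priors: alpha1 = beta1 = 1 on the margins, alpha = beta = 2 on the
    total, gamma11 = 1 on the joint cell with gamma chosen so the prior
    IC expectation is 0.  Works for zero cells.  Returns (lo, hi) of
    E(IC) +/- 2*sqrt(V(IC)).
    """
    a = np.asarray(a, dtype=float)
    n = a + b + c + d
    a1 = b1 = 1.0
    al = be = 2.0
    g11 = 1.0
    row = a + b + a1
    col = a + c + b1
    gam = g11 * (n + al) * (n + be) / (row * col)
    e_ic = np.log2((a + g11) * (n + al) * (n + be) / ((n + gam) * row * col))
    v_ic = (
        (n - a + gam - g11) / ((a + g11) * (1 + n + gam))
        + (n - a - b + al - a1) / (row * (1 + n + al))
        + (n - a - c + be - b1) / (col * (1 + n + be))
    ) / (math.log(2) ** 2)
    sd = np.sqrt(v_ic)
    return e_ic - 2 * sd, e_ic + 2 * sd


def _mcmc_ic_interval(a, b, c, d, draws: int, rng: np.random.Generator):
    """Monte-Carlo 95% credible interval for IC.

    Cell probabilities get independent Gamma(cell + 0.5, 1) posteriors
    (Jeffreys-style priors, jointly a Dirichlet after normalisation); IC is
    evaluated on each draw and the 2.5/97.5 percentiles returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    m = a.size
    lo = np.empty(m)
    hi = np.empty(m)
    chunk = max(1, int(4_000_000 // max(draws, 1)))
    for s0 in range(0, m, chunk):
        sl = slice(s0, min(s0 + chunk, m))
        ga = rng.gamma(a[sl] + 0.5, 1.0, size=(draws, sl.stop - sl.start))
        gb = rng.gamma(b[sl] + 0.5, 1.0, size=(draws, sl.stop - sl.start))
        gc = rng.gamma(c[sl] + 0.5, 1.0, size=(draws, sl.stop - sl.start))
        gd = rng.gamma(d[sl] + 0.5, 1.0, size=(draws, sl.stop - sl.start))
        tot = ga + gb + gc + gd
        ic = np.log2(ga * tot / ((ga + gc) * (ga + gb)))
        q = np.percentile(ic, [2.5, 97.5], axis=0)
        lo[sl], hi[sl] = q[0], q[1]
    return lo, hi


def _stats_arrays(
    a,
    b,
    c,
    d,
    ic_method: str = "mcmc-dirichlet",
    zero_cell: str = "undefined",
    mcmc_draws: int = 100_000,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Vectorised Table-3 statistics over parallel cell arrays.

    Returns a dict of arrays including a boolean ``defined`` mask; rows
    with a zero cell are NaN under ``zero_cell='undefined'`` or evaluated
    on +0.5-shifted cells under ``'haldane'`` (the IC interval always uses
    the raw integer cells — its priors already handle zeros).
    """
    if ic_method not in IC_METHODS:
        raise ValueError(f"unknown ic_method {ic_method!r}; choose from {IC_METHODS}")
    if zero_cell not in ("undefined", "haldane"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    d = np.atleast_1d(np.asarray(d, dtype=float))
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    if zero_cell == "haldane":
        shift = np.where(zero, 0.5, 0.0)
        aa, bb, cc, dd = a + shift, b + shift, c + shift, d + shift
        defined = np.ones_like(zero, dtype=bool)
    else:
        aa, bb, cc, dd = a, b, c, d
        defined = ~zero
    n = aa + bb + cc + dd
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = aa * dd / (bb * cc)
        se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
        ror_lo = ror * np.exp(-Z95 * se)
        ror_hi = ror * np.exp(Z95 * se)
        prr = aa * (cc + dd) / (cc * (aa + bb))
        chi2 = (aa * dd - bb * cc) ** 2 * n / ((aa + bb) * (cc + dd) * (aa + cc) * (bb + dd))
        ebgm = aa * n / ((aa + cc) * (aa + bb))
        ebgm05 = ebgm * np.exp(-Z95 * se)
        ebgm95 = ebgm * np.exp(Z95 * se)
        ic = np.log2(ebgm)
    if ic_method == "bate1998":
        ic_lo, ic_hi = _bate_ic_interval(a, b, c, d)
    else:
        rng = np.random.default_rng(seed)
        ic_lo, ic_hi = _mcmc_ic_interval(a, b, c, d, mcmc_draws, rng)
    out = {
        "ror": ror, "ror_lo": ror_lo, "ror_hi": ror_hi,
        "prr": prr, "chi2": chi2,
        "ic": ic, "ic_lo": ic_lo, "ic_hi": ic_hi,
        "ebgm": ebgm, "ebgm05": ebgm05, "ebgm95": ebgm95,
    }
    for k, v in out.items():
        out[k] = np.where(defined, v, np.nan)
    out["defined"] = defined
    return out


def compute_signal_stats(
    table: ContingencyTable,
    ic_method: str = "mcmc-dirichlet",
    zero_cell: str = "undefined",
    mcmc_draws: int = 100_000,
    seed: int = 0,
) -> SignalStats:
    """All four algorithms for a single 2x2 table.

    With a zero cell and ``zero_cell='undefined'`` the result carries NaNs
    and the offending cell in ``undefined_reason`` (and fails every
    criterion) rather than raising.
    """
    arrs = _stats_arrays(
        table.a, table.b, table.c, table.d,
        ic_method=ic_method, zero_cell=zero_cell, mcmc_draws=mcmc_draws, seed=seed,
    )
    reason = None
    if not bool(arrs["defined"][0]):
        zeros = [name for name, v in zip("abcd", table.cells()) if v == 0]
        reason = f"zero cell ({', '.join(zeros)} = 0)"
    return SignalStats(
        table=table,
        ror=float(arrs["ror"][0]), ror_lo=float(arrs["ror_lo"][0]), ror_hi=float(arrs["ror_hi"][0]),
        prr=float(arrs["prr"][0]), chi2=float(arrs["chi2"][0]),
        ic=float(arrs["ic"][0]), ic_lo=float(arrs["ic_lo"][0]), ic_hi=float(arrs["ic_hi"][0]),
        ebgm=float(arrs["ebgm"][0]), ebgm05=float(arrs["ebgm05"][0]), ebgm95=float(arrs["ebgm95"][0]),
        undefined_reason=reason,
    )


def evaluate_criteria(stats: SignalStats) -> SignalCriteria:
    """Apply the four signal thresholds; NaN statistics fail their criterion."""
    a = stats.table.a

    def ok(x: float) -> bool:
        return bool(np.isfinite(x))

    return SignalCriteria(
        pass_ror=a >= 3 and ok(stats.ror_lo) and stats.ror_lo > 1.0,
        pass_prr=a >= 3 and ok(stats.prr) and stats.prr >= 2.0 and ok(stats.chi2) and stats.chi2 >= 4.0,
        pass_bcpnn=ok(stats.ic_lo) and stats.ic_lo > 0.0,
        pass_mgps=ok(stats.ebgm05) and stats.ebgm05 > 2.0,
    )


def grade_signal(ic_lo: float) -> str:
    """Signal intensity from the IC lower bound: (0,1.5] weak, (1.5,3]
    medium, >3 high; 0, negative or undefined grade as none."""
    if ic_lo is None or not np.isfinite(ic_lo) or ic_lo <= 0.0:
        return GRADE_NONE
    if ic_lo <= 1.5:
        return GRADE_WEAK
    if ic_lo <= 3.0:
        return GRADE_MEDIUM
    return GRADE_HIGH


def detect_signals(
    universe: PairUniverse,
    pts: list[str] | None = None,
    ic_method: str = "mcmc-dirichlet",
    zero_cell: str = "undefined",
    unit: str = "pair",
    mcmc_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Statistics, criteria and grade for every PT reported with the drug.

    One row per distinct PT among target pairs (or the explicit ``pts``
    list), ordered by EBGM05 descending, ties by cell a descending then PT
    name; undefined EBGM05 sorts last.  The ``pass_all`` column marks PTs
    satisfying all four algorithms simultaneously.
    """
    pairs = universe.pairs
    if len(pairs) == 0 or universe.n_target_pairs == 0:
        cols = ["pt", "a", "b", "c", "d", "ror", "ror_lo", "ror_hi", "prr", "chi2",
                "ic", "ic_lo", "ic_hi", "ebgm", "ebgm05", "ebgm95", "defined",
                "pass_ror", "pass_prr", "pass_bcpnn", "pass_mgps", "pass_all", "grade"]
        return pd.DataFrame(columns=cols)

    tgt = pairs[pairs["is_target"]]
    non = pairs[~pairs["is_target"]]
    if pts is None:
        keys = tgt.drop_duplicates("pt_key")[["pt_key", "pt"]]
    else:
        norm = [normalize_pt(p) for p in pts]
        keys = pd.DataFrame({"pt_key": [k for k, _ in norm], "pt": [dsp for _, dsp in norm]})
        keys = keys.drop_duplicates("pt_key")
    a_cnt = tgt.groupby("pt_key").size()
    c_cnt = non.groupby("pt_key").size()
    a = keys["pt_key"].map(a_cnt).fillna(0).to_numpy(dtype=np.int64)
    c = keys["pt_key"].map(c_cnt).fillna(0).to_numpy(dtype=np.int64)
    if unit == "pair":
        b = len(tgt) - a
        d = len(non) - c
    elif unit == "report":
        b = universe.n_target_reports - a
        d = (universe.n_reports_total - universe.n_target_reports) - c
    else:
        raise ValueError(f"unknown counting unit {unit!r}")

    arrs = _stats_arrays(a, b, c, d, ic_method=ic_method, zero_cell=zero_cell,
                         mcmc_draws=mcmc_draws, seed=seed)
    df = pd.DataFrame({"pt": keys["pt"].to_numpy(), "a": a, "b": b, "c": c, "d": d})
    for k in ("ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic_lo", "ic_hi",
              "ebgm", "ebgm05", "ebgm95"):
        df[k] = arrs[k]
    df["defined"] = arrs["defined"]
    fin = lambda col: np.isfinite(df[col].to_numpy(dtype=float))
    df["pass_ror"] = (df["a"] >= 3) & fin("ror_lo") & (df["ror_lo"] > 1.0)
    df["pass_prr"] = (df["a"] >= 3) & fin("prr") & (df["prr"] >= 2.0) & fin("chi2") & (df["chi2"] >= 4.0)
    df["pass_bcpnn"] = fin("ic_lo") & (df["ic_lo"] > 0.0)
    df["pass_mgps"] = fin("ebgm05") & (df["ebgm05"] > 2.0)
    df["pass_all"] = df["pass_ror"] & df["pass_prr"] & df["pass_bcpnn"] & df["pass_mgps"]
    df["grade"] = [grade_signal(x) for x in df["ic_lo"]]

    df = df.sort_values(
        ["ebgm05", "a", "pt"], ascending=[False, False, True], na_position="last",
        kind="mergesort",
    )
    return df.reset_index(drop=True)
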