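import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faers_signals.dispro import (
    GRADE_HIGH,
    GRADE_MEDIUM,
    GRADE_NONE,
    GRADE_WEAK,
    ContingencyTable,
    build_contingency,
    compute_signal_stats,
    detect_signals,
    evaluate_criteria,
    grade_signal,
)

from conftest import make_universe

Z = 1.959963984540054


def formulas(a, b, c, d):
    """Independent direct evaluation of the four point estimates and CIs."""
    n = a + b + c + d
    s = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = a * d / (b * c)
    return {
        "ror": ror,
        "ror_lo": ror * math.exp(-Z * s),
        "ror_hi": ror * math.exp(Z * s),
        "prr": a * (c + d) / (c * (a + b)),
        "chi2": (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d)),
        "ebgm": a * n / ((a + c) * (a + b)),
        "ebgm05": a * n / ((a + c) * (a + b)) * math.exp(-Z * s),
        "ic": math.log2(a * n / ((a + c) * (a + b))),
    }


class TestPointEstimates:
    def test_independence_table(self):
        s = compute_signal_stats(ContingencyTable(25, 25, 25, 25), ic_method="bate1998")
        assert s.ror == s.prr == s.ebgm == 1.0
        assert s.ic == 0.0 and s.chi2 == 0.0

    def test_hand_checked_table(self):
        s = compute_signal_stats(ContingencyTable(10, 20, 30, 40), ic_method="bate1998")
        assert s.ror == pytest.approx(2 / 3, rel=1e-12)
        assert s.ror_lo == pytest.approx(0.27253, abs=2e-4)
        assert s.ror_hi == pytest.approx(1.63085, abs=2e-4)
        assert s.prr == pytest.approx(0.77778, abs=1e-5)
        assert s.chi2 == pytest.approx(0.79365, abs=1e-5)
        assert s.ebgm == pytest.approx(0.83333, abs=1e-5)
        assert s.ic == pytest.approx(-0.26303, abs=1e-5)
        assert s.ebgm05 == pytest.approx(0.34066, abs=1e-4)

    @pytest.mark.parametrize(
        "cells",
        [(10, 20, 30, 40), (3, 997, 50, 98950), (721, 4000, 900, 140000), (1, 1, 1, 1)],
    )
    def test_matches_direct_formula_evaluation(self, cells):
        s = compute_signal_stats(ContingencyTable(*cells), ic_method="bate1998")
        ref = formulas(*cells)
        for key, want in ref.items():
            assert getattr(s, key) == pytest.approx(want, rel=1e-12), key

    def test_ic_equals_log2_ebgm_identity(self):
        for cells in [(10, 20, 30, 40), (721, 4000, 900, 140000), (5, 5, 5, 5)]:
            s = compute_signal_stats(ContingencyTable(*cells), ic_method="bate1998")
            assert abs(s.ic - math.log2(s.ebgm)) < 1e-12

    def test_ror_and_ebgm_share_log_scale_se(self):
        s = compute_signal_stats(ContingencyTable(10, 20, 30, 40), ic_method="bate1998")
        width_ror = math.log(s.ror_hi / s.ror_lo)
        width_ebgm = math.log(s.ebgm95 / s.ebgm05)
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 30 + 1 / 40)
        assert width_ror == pytest.approx(width_ebgm, rel=1e-12)
        assert width_ror == pytest.approx(2 * Z * se, rel=1e-12)

    @given(
        st.integers(1, 100), st.integers(1, 400), st.integers(1, 400), st.integers(1, 5000)
    )
    def test_increasing_a_increases_all_four(self, a, extra_b, extra_c, d):
        # Monotonicity in the signal cell holds whenever that cell does not
        # dominate its own margins (b, c >= a + 1, the spontaneous-report
        # regime); on degenerate tables like (1,1,1,6) -> (2,1,1,6) the
        # observed/expected ratio can dip because the +1 inflates both
        # margins faster than the cell.
        b, c = a + extra_b, a + extra_c
        lo = compute_signal_stats(ContingencyTable(a, b, c, d), ic_method="bate1998")
        hi = compute_signal_stats(ContingencyTable(a + 1, b, c, d), ic_method="bate1998")
        assert hi.ror > lo.ror and hi.prr > lo.prr
        assert hi.ebgm > lo.ebgm and hi.ic > lo.ic


class TestZeroCells:
    def test_zero_cell_is_undefined_not_a_crash(self):
        s = compute_signal_stats(ContingencyTable(5, 0, 3, 10), ic_method="bate1998")
        assert not s.defined and "b" in s.undefined_reason
        assert math.isnan(s.ror) and math.isnan(s.ebgm05)
        crit = evaluate_criteria(s)
        assert not (crit.pass_ror or crit.pass_prr or crit.pass_bcpnn or crit.pass_mgps)

    def test_haldane_correction_defines_the_stats(self):
        s = compute_signal_stats(
            ContingencyTable(5, 0, 3, 10), ic_method="bate1998", zero_cell="haldane"
        )
        assert s.defined
        ref = formulas(5.5, 0.5, 3.5, 10.5)
        assert s.ror == pytest.approx(ref["ror"], rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestIcIntervals:
    def test_mcmc_interval_brackets_point_and_is_seeded(self):
        t = ContingencyTable(50, 450, 100, 9400)
        s1 = compute_signal_stats(t, ic_method="mcmc-dirichlet", mcmc_draws=20_000, seed=9)
        s2 = compute_signal_stats(t, ic_method="mcmc-dirichlet", mcmc_draws=20_000, seed=9)
        assert (s1.ic_lo, s1.ic_hi) == (s2.ic_lo, s2.ic_hi)
        assert s1.ic_lo < s1.ic < s1.ic_hi

    def test_mcmc_and_bate_agree_for_large_counts(self):
        t = ContingencyTable(500, 4500, 1000, 94000)
        mc = compute_signal_stats(t, ic_method="mcmc-dirichlet", mcmc_draws=50_000, seed=4)
        bate = compute_signal_stats(t, ic_method="bate1998")
        assert mc.ic_lo == pytest.approx(bate.ic_lo, abs=0.15)
        assert mc.ic_hi == pytest.approx(bate.ic_hi, abs=0.15)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="ic_method"):
            compute_signal_stats(ContingencyTable(1, 1, 1, 1), ic_method="nope")


class TestCriteriaAndGrade:
    def test_small_a_fails_ror_despite_huge_ratio(self):
        s = compute_signal_stats(ContingencyTable(2, 2, 1, 10000), ic_method="bate1998")
        assert s.ror > 100
        assert not evaluate_criteria(s).pass_ror

    @pytest.mark.parametrize(
        "ic_lo, grade",
        [
            (-1.0, GRADE_NONE),
            (0.0, GRADE_NONE),  # interval open at 0
            (0.01, GRADE_WEAK),
            (1.5, GRADE_WEAK),
            (1.51, GRADE_MEDIUM),
            (2.0, GRADE_MEDIUM),
            (3.0, GRADE_MEDIUM),
            (3.01, GRADE_HIGH),
            (7.32, GRADE_HIGH),
            (float("nan"), GRADE_NONE),
        ],
    )
    def test_grade_bands(self, ic_lo, grade):
        assert grade_signal(ic_lo) == grade


class TestContingencyAndDetection:
    def test_single_pair_universe(self):
        uni = make_universe([("1", "Rash", True)])
        t = build_contingency(uni, "Rash")
        assert t.cells() == (1, 0, 0, 0)

    def test_absent_pt_gives_zero_a_and_c(self):
        uni = make_universe([("1", "Rash", True), ("2", "Nausea", False)])
        t = build_contingency(uni, "Vertigo")
        assert t.a == 0 and t.c == 0 and t.n == 2

    def test_report_unit_margins(self):
        uni = make_universe(
            [("1", "Rash", True), ("1", "Nausea", True), ("2", "Rash", False)]
        )
        pair = build_contingency(uni, "Rash", unit="pair")
        rep = build_contingency(uni, "Rash", unit="report")
        assert pair.cells() == (1, 1, 1, 0)
        assert rep.cells() == (1, 0, 1, 0)  # one target report, with the PT

    def test_detect_signals_matches_per_pt_brute_force(self, small_universe):
        table = detect_signals(small_universe, ic_method="bate1998")
        pairs = small_universe.pairs
        n_t = int(pairs["is_target"].sum())
        n_nt = len(pairs) - n_t
        for _, row in table.iterrows():
            sub = pairs[pairs["pt"] == row["pt"]]
            a = int((sub["is_target"]).sum())
            c = len(sub) - a
            assert (row["a"], row["b"], row["c"], row["d"]) == (a, n_t - a, c, n_nt - c)
            if row["defined"]:
                ref = formulas(row["a"], row["b"], row["c"], row["d"])
                for key in ("ror", "prr", "chi2", "ebgm", "ebgm05", "ic"):
                    assert row[key] == pytest.approx(ref[key], rel=1e-12), (row["pt"], key)

    def test_detect_signals_ordering(self):
        uni = make_universe(
            [("1", "Aaa", True), ("2", "Aaa", True), ("3", "Bbb", True), ("4", "Ccc", False)]
        )
        table = detect_signals(uni, ic_method="bate1998")
        ranks = list(table["pt"])
        eb = table.set_index("pt")["ebgm05"]
        assert ranks == sorted(
            ranks,
            key=lambda p: (-(eb[p] if np.isfinite(eb[p]) else -np.inf),
                           -table.set_index("pt")["a"][p], p),
        )

    def test_empty_target_side_yields_empty_table(self):
        uni = make_universe([("1", "Rash", False)])
        assert len(detect_signals(uni, ic_method="bate1998")) == 0

    def test_intersection_is_conservative_under_null(self, small_universe):
        table = detect_signals(small_universe, ic_method="bate1998")
        n_all = int(table["pass_all"].sum())
        for col in ("pass_ror", "pass_prr", "pass_bcpnn", "pass_mgps"):
            assert n_all <= int(table[col].sum())
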