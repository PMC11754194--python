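import random

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from faers_signals.cohort import (
    ScreeningKeywords,
    build_report_event_pairs,
    deduplicate_reports,
    normalize_pt,
    remove_deleted,
    screen_target_drug,
)
from faers_signals.faers_io import DemoRecord, DrugRecord, ReacRecord

from conftest import TARGET_KEYWORDS


def demo(primaryid, caseid, fda_dt):
    return DemoRecord(primaryid=primaryid, caseid=caseid, fda_dt=fda_dt)


class TestRemoveDeleted:
    def test_empty_dele_is_identity(self):
        records = [demo("11", "1", "20200101"), demo("21", "2", "20200101")]
        kept, n = remove_deleted(records, [])
        assert n == 0 and len(kept) == 2

    def test_all_deleted_empties_output(self):
        records = [demo("11", "1", "20200101"), demo("21", "2", "20200101")]
        dele = pd.DataFrame({"caseid": ["1", "2"]})
        kept, n = remove_deleted(records, dele)
        assert n == 2 and len(kept) == 0

    def test_random_deletion_matches_set_difference(self):
        rng = random.Random(5)
        records = [demo(f"{i}1", str(i), "20200101") for i in range(200)]
        deleted = rng.sample(range(200), 20)
        dele = pd.DataFrame({"caseid": [str(i) for i in deleted]})
        kept, n = remove_deleted(records, dele)
        assert n == 20
        assert set(kept["caseid"]) == {str(i) for i in range(200)} - {str(i) for i in deleted}


class TestDeduplicateReports:
    def test_keeps_latest_fda_dt(self):
        records = [demo("1001", "100", "20200101"), demo("1002", "100", "20200301")]
        out = deduplicate_reports(records)
        assert list(out["primaryid"]) == ["1002"]

    def test_fda_dt_tie_keeps_largest_primaryid(self):
        records = [demo("1002", "100", "20200101"), demo("1001", "100", "20200101")]
        out = deduplicate_reports(records)
        assert list(out["primaryid"]) == ["1002"]

    def test_numeric_primaryid_comparison(self):
        # lexicographically "9" > "10" but numerically 10 > 9
        records = [demo("9", "100", "20200101"), demo("10", "100", "20200101")]
        out = deduplicate_reports(records)
        assert list(out["primaryid"]) == ["10"]

    def test_no_duplicates_is_identity(self):
        records = [demo("11", "1", "20200101"), demo("21", "2", "20200201")]
        out = deduplicate_reports(records)
        assert sorted(out["primaryid"]) == ["11", "21"]

    def test_unparseable_fda_dt_sorts_lowest(self):
        records = [demo("1002", "100", "bogus"), demo("1001", "100", "20000101")]
        out = deduplicate_reports(records)
        assert list(out["primaryid"]) == ["1001"]

    def test_matches_brute_force_oracle_and_idempotent(self):
        rng = random.Random(11)
        records = []
        for case in range(300):
            versions = rng.choice([1, 1, 1, 2, 3])
            for v in range(1, versions + 1):
                records.append(
                    demo(f"{case}{v}", str(case), f"2020{rng.randint(1, 12):02d}01")
                )
        out = deduplicate_reports(records)

        oracle = {}
        for r in records:
            key = (int(r.fda_dt), int(r.primaryid))
            if r.caseid not in oracle or key > oracle[r.caseid][0]:
                oracle[r.caseid] = (key, r.primaryid)
        assert {(cid, pid) for cid, (_, pid) in oracle.items()} == set(
            zip(out["caseid"], out["primaryid"])
        )
        again = deduplicate_reports(out)
        pd.testing.assert_frame_equal(out, again)


class TestScreenTargetDrug:
    def test_trade_name_substring_primary_suspect(self):
        rows = [DrugRecord("11", "1", "PS", "Soliris 300 mg vial", "")]
        assert screen_target_drug(rows, TARGET_KEYWORDS) == {"11"}

    def test_secondary_suspect_excluded_when_ps_required(self):
        rows = [DrugRecord("11", "1", "SS", "", "ECULIZUMAB")]
        assert screen_target_drug(rows, TARGET_KEYWORDS) == set()

    def test_case_insensitive(self):
        rows = [DrugRecord("11", "1", "PS", "eculizumab", "")]
        assert screen_target_drug(rows, TARGET_KEYWORDS) == {"11"}

    def test_role_applies_to_matching_row_not_report(self):
        # the PS row is an unrelated drug; the keyword match is concomitant
        rows = [
            DrugRecord("11", "1", "PS", "ASPIRIN", ""),
            DrugRecord("11", "2", "C", "SOLIRIS", "ECULIZUMAB"),
        ]
        assert screen_target_drug(rows, TARGET_KEYWORDS) == set()
        no_role = ScreeningKeywords(("SOLIRIS",), (), None)
        assert screen_target_drug(rows, no_role) == {"11"}

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            ScreeningKeywords((), (), "PS")

    def test_adding_keyword_is_monotone(self):
        rows = [
            DrugRecord("11", "1", "PS", "SOLIRIS", ""),
            DrugRecord("21", "1", "PS", "BKEMV", "ECULIZUMAB-AEEB"),
            DrugRecord("31", "1", "PS", "ASPIRIN", ""),
        ]
        narrow = screen_target_drug(rows, ScreeningKeywords(("SOLIRIS",), (), "PS"))
        wide = screen_target_drug(rows, ScreeningKeywords(("SOLIRIS", "BKEMV"), (), "PS"))
        assert narrow <= wide


class TestPairUniverse:
    def test_duplicate_pt_in_report_counted_once(self):
        demo_records = [demo("11", "1", "20200101")]
        reac = [ReacRecord("11", "Headache"), ReacRecord("11", "HEADACHE")]
        uni = build_report_event_pairs(demo_records, reac, {"11"})
        assert uni.n_pairs == 1 and uni.n_target_pairs == 1
        assert uni.pairs["pt"].iloc[0] == "Headache"  # first-seen display form

    def test_distinct_pairs_counted(self):
        demo_records = [demo(f"{i}1", str(i), "20200101") for i in range(3)]
        reac = [ReacRecord(f"{i}1", pt) for i in range(3) for pt in ("Nausea", "Rash")]
        uni = build_report_event_pairs(demo_records, reac, set())
        assert uni.n_pairs == 6 and uni.n_target_pairs == 0

    def test_whitespace_normalisation(self):
        key1, _ = normalize_pt("  Blood  pressure   increased ")
        key2, _ = normalize_pt("blood pressure increased")
        assert key1 == key2

    def test_orphan_reac_rows_dropped(self):
        demo_records = [demo("11", "1", "20200101")]
        reac = [ReacRecord("11", "Nausea"), ReacRecord("999", "Nausea")]
        uni = build_report_event_pairs(demo_records, reac, {"11"})
        assert uni.n_pairs == 1 and uni.n_dropped_orphans == 1

    def test_counts_match_brute_force(self, small_tables, small_universe):
        # independent recount from raw tables, replaying the cleaning rules
        best = {}
        deleted = set(small_tables.dele["caseid"])
        for _, r in small_tables.demo.iterrows():
            if r["caseid"] in deleted:
                continue
            key = (int(r["fda_dt"]), int(r["primaryid"]))
            if r["caseid"] not in best or key > best[r["caseid"]][0]:
                best[r["caseid"]] = (key, r["primaryid"])
        survivors = {pid for _, pid in best.values()}
        ps = small_tables.drug[
            (small_tables.drug["role_cod"] == "PS")
            & (
                small_tables.drug["drugname"].str.upper().str.contains("SOLIRIS")
                | small_tables.drug["drugname"].str.upper().str.contains("ECULIZUMAB")
                | small_tables.drug["prod_ai"].str.upper().str.contains("ECULIZUMAB")
            )
        ]
        targets = set(ps["primaryid"]) & survivors
        pair_set = {
            (r["primaryid"], r["pt"].strip().casefold())
            for _, r in small_tables.reac.iterrows()
            if r["primaryid"] in survivors
        }
        assert small_universe.n_pairs == len(pair_set)
        assert small_universe.n_target_pairs == sum(
            1 for pid, _ in pair_set if pid in targets
        )
        assert small_universe.n_target_reports == len(targets)


@given(st.sets(st.integers(0, 50), max_size=20))
def test_remove_deleted_size_property(deleted_ids):
    records = [demo(f"{i}1", str(i), "20200101") for i in range(51)]
    dele = pd.DataFrame({"caseid": [str(i) for i in deleted_ids]})
    kept, n = remove_deleted(records, dele)
    assert n == len(deleted_ids)
    assert len(kept) == 51 - len(deleted_ids)
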