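import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from faers_signals.cohort import (
    ScreeningKeywords,
    build_report_event_pairs,
    deduplicate_reports,
    remove_deleted,
    screen_target_drug,
)
from faers_signals.synthetic import (
    DrugSpec,
    PlantedSignal,
    SyntheticConfig,
    generate_tables,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


TARGET_KEYWORDS = ScreeningKeywords(
    drugname_substrings=("SOLIRIS", "ECULIZUMAB"),
    prod_ai_substrings=("ECULIZUMAB",),
    restrict_to_role="PS",
)


def small_config(**overrides) -> SyntheticConfig:
    """A compact study: 2 drugs, 6 PTs, one strong planted signal."""
    base = dict(
        n_reports=3000,
        quarters=["2020Q1", "2020Q2"],
        drugs=[
            DrugSpec("Soliris 300 mg vial", "ECULIZUMAB"),
            DrugSpec("COMPARATOR", "OTHERCOMPOUND"),
        ],
        pts=[
            ("Hemolysis", "Blood and lymphatic system disorders"),
            ("Headache", "Nervous system disorders"),
            ("Nausea", "Gastrointestinal disorders"),
            ("Pyrexia", "General disorders"),
            ("Fatigue", "General disorders"),
            ("Anaemia", "Blood and lymphatic system disorders"),
        ],
        baseline_event_prob=0.05,
        pt_event_probs={"Hemolysis": 0.02},
        planted_signals=[PlantedSignal("Soliris 300 mg vial", "Hemolysis", 30.0)],
        drug_probs=[0.05, 0.95],
        duplicate_rate=0.1,
        deleted_rate=0.05,
        seed=42,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_tables():
    return generate_tables(small_config())


@pytest.fixture(scope="session")
def small_universe(small_tables):
    demo, _ = remove_deleted(small_tables.demo, small_tables.dele)
    demo = deduplicate_reports(demo)
    target_ids = screen_target_drug(small_tables.drug, TARGET_KEYWORDS)
    return build_report_event_pairs(demo, small_tables.reac, target_ids)


def make_universe(rows):
    """Hand-built pair universe from (primaryid, pt, is_target) triples."""
    pairs = pd.DataFrame(rows, columns=["primaryid", "pt", "is_target"])
    demo = pairs[["primaryid"]].drop_duplicates()
    demo["caseid"] = demo["primaryid"]
    demo["fda_dt"] = "20200101"
    target_ids = set(pairs.loc[pairs["is_target"], "primaryid"].astype(str))
    reac = pairs[["primaryid", "pt"]]
    return build_report_event_pairs(demo, reac, target_ids)
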