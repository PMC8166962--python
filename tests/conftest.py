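"""Shared fixtures: tiny hand-built datasets and a calibrated sim config."""

import pandas as pd
import pytest

from srspv import DrugSpec, DrugVocabulary, SimConfig, SrsDataset

FOCAL_PT = 10029331


def make_dataset(demo_rows, drug_rows, reac_rows, hist_rows=None):
    """Build a validated SrsDataset from lists of row dicts."""
    demo = pd.DataFrame(demo_rows, columns=["case_id", "sex", "age_band", "report_period"])
    drug = pd.DataFrame(
        drug_rows,
        columns=["case_id", "drug_seq", "product_name", "role_code", "start_date", "end_date"],
    )
    reac = pd.DataFrame(
        reac_rows, columns=["case_id", "pt_code", "pt_name", "onset_date", "outcome"]
    )
    hist = pd.DataFrame(hist_rows or [], columns=["case_id", "disease"])
    return SrsDataset(demo=demo, drug=drug, reac=reac, hist=hist)


@pytest.fixture
def small_dataset():
    """Three reports: one oxaliplatin case, one non-case, one unexposed case."""
    return make_dataset(
        demo_rows=[
            ("C1", "female", "60-69", "2019"),
            ("C2", "male", "50-59", "2019"),
            ("C3", "female", "70-79", "2019"),
        ],
        drug_rows=[
            ("C1", 1, "oxaliplatin", "suspected", "20190101", ""),
            ("C1", 2, "oxaliplatin", "suspected", "20190301", ""),  # duplicate Rx
            ("C1", 3, "comedication", "concomitant", "20190105", ""),
            ("C2", 1, "oxaliplatin", "suspected", "20190401", ""),
            ("C3", 1, "paclitaxel", "suspected", "201905", ""),  # partial start
        ],
        reac_rows=[
            ("C1", FOCAL_PT, "peripheral neuropathy", "20190115", "recovered"),
            ("C2", 10028813, "nausea", "20190410", "unknown"),
            ("C3", FOCAL_PT, "peripheral neuropathy", "20190520", "not_recovered"),
        ],
        hist_rows=[("C1", "colorectal cancer")],
    )


@pytest.fixture
def vocab():
    return DrugVocabulary(
        {
            "oxaliplatin": ("oxaliplatin", "L01XA03"),
            "paclitaxel": ("sb-paclitaxel", "L01CD01"),
            "paclitaxel protein-bound particles for injectable suspension": (
                "nab-paclitaxel",
                "L01CD01",
            ),
            "comedication": ("comedication", "unassigned"),
        }
    )


@pytest.fixture
def sim_config():
    """One associated drug over a null background; modest size for speed."""
    return SimConfig(
        n_reports=20_000,
        background_event_prob=0.003,
        drugs=[
            DrugSpec(
                name="oxaliplatin",
                atc_code="L01XA03",
                marginal_exposure_prob=0.014,
                event_odds_multiplier=26.0,
                latency_alpha_days=50.0,
                latency_beta=0.9,
            )
        ],
        missing_date_prob=0.05,
        duplicate_prescription_prob=0.05,
        seed=20260920,
    )
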