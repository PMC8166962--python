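"""Synthetic spontaneous-report generator with analytic oracles.

Emulates the statistical structure the downstream analyses assume:

* per-report drug exposures are independent Bernoulli draws;
* one focal adverse event (a single MedDRA PT) occurs with a background
  odds that each exposed drug multiplies on the *odds scale*, so a
  drug's configured ``event_odds_multiplier`` is exactly the estimand of
  its reporting odds ratio against the unexposed background;
* exposed case reports receive an onset latency drawn from a
  Weibull(scale=``latency_alpha_days``, shape=``latency_beta``)
  distribution, rounded to whole days (a rounded 0 is emitted as day 0);
* outcomes are categorical draws from the drug's six-category mixture;
* dates are degraded to year-month precision with a configurable
  probability, and prescription rows are duplicated with another, to
  exercise the exclusion rules.

``expected_contingency`` gives the closed-form expected 2×2 cells under
this generative model, used as the oracle in calibration tests.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .disproportionality import ContingencyTable
from .tables import SrsDataset

FOCAL_PT_CODE = 10029331  # peripheral neuropathy
FOCAL_PT_NAME = "peripheral neuropathy"
BACKGROUND_PT_CODE = 10028813
BACKGROUND_PT_NAME = "nausea"

OUTCOME_ORDER = ("death", "with_sequelae", "not_recovered", "improved", "recovered", "unknown")

# Outcome mixture for non-focal (background) reactions; immaterial to the
# analyses, which only read outcomes of focal-event reactions.
_BACKGROUND_OUTCOMES = np.array([0.02, 0.02, 0.16, 0.30, 0.40, 0.10])

_AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")


@dataclass
class DrugSpec:
    """Generative parameters for one configured drug."""

    name: str
    atc_code: str
    marginal_exposure_prob: float
    event_odds_multiplier: float = 1.0
    latency_alpha_days: float = 50.0
    latency_beta: float = 1.0
    outcome_probs: Sequence[float] = (0.02, 0.03, 0.35, 0.30, 0.25, 0.05)

    def __post_init__(self) -> None:
        if not 0.0 <= self.marginal_exposure_prob <= 1.0:
            raise ValueError(f"{self.name}: exposure probability outside [0,1]")
        if self.event_odds_multiplier <= 0:
            raise ValueError(f"{self.name}: odds multiplier must be positive")
        if self.latency_alpha_days <= 0 or self.latency_beta <= 0:
            raise ValueError(f"{self.name}: Weibull parameters must be positive")
        probs = np.asarray(self.outcome_probs, dtype=float)
        if probs.shape != (6,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: outcome_probs must be a 6-vector summing to 1")


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    n_reports: int
    background_event_prob: float
    drugs: list[DrugSpec] = field(default_factory=list)
    missing_date_prob: float = 0.0
    duplicate_prescription_prob: float = 0.0
    seed: int = 0
    start_year: int = 2015
    concomitant_drug_prob: float = 0.2

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for p, label in (
            (self.background_event_prob, "background_event_prob"),
            (self.missing_date_prob, "missing_date_prob"),
            (self.duplicate_prescription_prob, "duplicate_prescription_prob"),
            (self.concomitant_drug_prob, "concomitant_drug_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} outside [0,1]")

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        data["drugs"] = [
            d if isinstance(d, DrugSpec) else DrugSpec(**d) for d in data.get("drugs", [])
        ]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        out = {
            "n_reports": self.n_reports,
            "background_event_prob": self.background_event_prob,
            "missing_date_prob": self.missing_date_prob,
            "duplicate_prescription_prob": self.duplicate_prescription_prob,
            "seed": self.seed,
            "start_year": self.start_year,
            "concomitant_drug_prob": self.concomitant_drug_prob,
            "drugs": [
                {
                    "name": d.name,
                    "atc_code": d.atc_code,
                    "marginal_exposure_prob": d.marginal_exposure_prob,
                    "event_odds_multiplier": d.event_odds_multiplier,
                    "latency_alpha_days": d.latency_alpha_days,
                    "latency_beta": d.latency_beta,
                    "outcome_probs": list(map(float, d.outcome_probs)),
                }
                for d in self.drugs
            ],
        }
        return out


@dataclass
class SimTruth:
    """Per-report bookkeeping of the generator's latent draws."""

    exposure: np.ndarray  # (n_reports, n_drugs) bool
    event: np.ndarray  # (n_reports,) bool
    latency_days: np.ndarray  # (n_reports,) float, NaN where undefined


def _date_strings(year: np.ndarray, month: np.ndarray, day: np.ndarray) -> np.ndarray:
    return np.char.add(
        np.char.add(
            np.char.zfill(year.astype(str), 4), np.char.zfill(month.astype(str), 2)
        ),
        np.char.zfill(day.astype(str), 2),
    )


def _random_full_dates(rng: np.random.Generator, n: int, year: int) -> np.ndarray:
    """Uniform calendar days within one year, as YYYYMMDD strings."""
    start = _dt.date(year, 1, 1).toordinal()
    n_days = 366 if _dt.date(year, 12, 31).toordinal() - start == 365 else 365
    ordinals = start + rng.integers(0, n_days, size=n)
    dates = [_dt.date.fromordinal(int(o)) for o in ordinals]
    return np.array([f"{d.year:04d}{d.month:02d}{d.day:02d}" for d in dates])


def _ordinal_to_string(ordinals: np.ndarray) -> np.ndarray:
    return np.array(
        [
            (lambda d: f"{d.year:04d}{d.month:02d}{d.day:02d}")(_dt.date.fromordinal(int(o)))
            for o in ordinals
        ]
    )


def _degrade(rng: np.random.Generator, dates: np.ndarray, prob: float) -> np.ndarray:
    """Truncate a fraction of YYYYMMDD strings to YYYYMM (year-month)."""
    if prob <= 0 or len(dates) == 0:
        return dates
    hit = rng.random(len(dates)) < prob
    out = dates.copy()
    out[hit] = [d[:6] for d in out[hit]]
    return out


def generate_with_truth(config: SimConfig) -> tuple[SrsDataset, SimTruth]:
    """Generate a dataset plus the latent exposure/event bookkeeping."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    k = len(config.drugs)
    case_ids = np.array([f"R{i:08d}" for i in range(1, n + 1)])

    exposure = np.zeros((n, k), dtype=bool)
    for j, spec in enumerate(config.drugs):
        exposure[:, j] = rng.random(n) < spec.marginal_exposure_prob

    p0 = config.background_event_prob
    if p0 >= 1.0:
        odds = np.full(n, np.inf)
    else:
        odds = np.full(n, p0 / (1.0 - p0))
        for j, spec in enumerate(config.drugs):
            odds[exposure[:, j]] *= spec.event_odds_multiplier
    p_event = odds / (1.0 + odds)
    event = rng.random(n) < p_event

    # demo -------------------------------------------------------------
    demo = pd.DataFrame(
        {
            "case_id": case_ids,
            "sex": rng.choice(["male", "female"], size=n),
            "age_band": rng.choice(_AGE_BANDS, size=n),
            "report_period": np.full(n, str(config.start_year)),
        }
    )

    # drug -------------------------------------------------------------
    drug_frames = []
    start_ordinals = np.full(n, -1, dtype=np.int64)  # of the first exposed drug
    first_exposed = np.full(n, -1, dtype=np.int64)
    for j, spec in enumerate(config.drugs):
        idx = np.flatnonzero(exposure[:, j])
        if len(idx) == 0:
            continue
        starts = _random_full_dates(rng, len(idx), config.start_year)
        newly_first = idx[first_exposed[idx] < 0]
        first_exposed[newly_first] = j
        mask = first_exposed[idx] == j
        start_ordinals[idx[mask]] = [
            _dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])).toordinal()
            for s in starts[mask]
        ]
        drug_frames.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[idx],
                    "product_name": spec.name,
                    "role_code": "suspected",
                    "start_date": _degrade(rng, starts, config.missing_date_prob),
                    "end_date": "",
                }
            )
        )

    conc = np.flatnonzero(rng.random(n) < config.concomitant_drug_prob)
    if len(conc):
        drug_frames.append(
            pd.DataFrame(
                {
                    "case_id": case_ids[conc],
                    "product_name": "comedication",
                    "role_code": "concomitant",
                    "start_date": _random_full_dates(rng, len(conc), config.start_year),
                    "end_date": "",
                }
            )
        )
    drug = (
        pd.concat(drug_frames, ignore_index=True)
        if drug_frames
        else pd.DataFrame(columns=["case_id", "product_name", "role_code", "start_date", "end_date"])
    )

    # duplicate prescription rows (cloned, new drug_seq downstream)
    if config.duplicate_prescription_prob > 0 and len(drug):
        dup = drug[rng.random(len(drug)) < config.duplicate_prescription_prob]
        drug = pd.concat([drug, dup], ignore_index=True)
    drug = drug.sort_values("case_id", kind="stable").reset_index(drop=True)
    drug["drug_seq"] = drug.groupby("case_id").cumcount() + 1
    drug = drug[["case_id", "drug_seq", "product_name", "role_code", "start_date", "end_date"]]

    # reac ---------------------------------------------------------------
    # one reaction per report: the focal PT for event reports, a
    # background PT otherwise.
    latency = np.full(n, np.nan)
    onset = np.empty(n, dtype=object)
    exposed_event = event & (first_exposed >= 0)
    for j, spec in enumerate(config.drugs):
        idx = np.flatnonzero(exposed_event & (first_exposed == j))
        if len(idx) == 0:
            continue
        lat = np.round(
            spec.latency_alpha_days * rng.weibull(spec.latency_beta, size=len(idx))
        )
        latency[idx] = lat
        onset[idx] = _ordinal_to_string(start_ordinals[idx] + lat.astype(np.int64))

    rest = np.flatnonzero(~exposed_event)
    onset[rest] = _random_full_dates(rng, len(rest), config.start_year)
    onset = _degrade(rng, onset.astype(str), config.missing_date_prob)

    outcome = np.empty(n, dtype=object)
    outcome[rest] = rng.choice(OUTCOME_ORDER, size=len(rest), p=_BACKGROUND_OUTCOMES)
    for j, spec in enumerate(config.drugs):
        idx = np.flatnonzero(exposed_event & (first_exposed == j))
        if len(idx):
            outcome[idx] = rng.choice(
                OUTCOME_ORDER, size=len(idx), p=np.asarray(spec.outcome_probs, dtype=float)
            )

    reac = pd.DataFrame(
        {
            "case_id": case_ids,
            "pt_code": np.where(event, FOCAL_PT_CODE, BACKGROUND_PT_CODE),
            "pt_name": np.where(event, FOCAL_PT_NAME, BACKGROUND_PT_NAME),
            "onset_date": onset,
            "outcome": outcome.astype(str),
        }
    )

    hist = pd.DataFrame({"case_id": case_ids, "disease": "malignant neoplasm"})

    dataset = SrsDataset(demo=demo, drug=drug, reac=reac, hist=hist)
    return dataset, SimTruth(exposure=exposure, event=event, latency_days=latency)


def generate_dataset(config: SimConfig) -> SrsDataset:
    """Generate a synthetic four-table dataset (deterministic in the seed)."""
    return generate_with_truth(config)[0]


def _exposure_patterns(specs: Sequence[DrugSpec]) -> Iterator[tuple[float, float]]:
    """Yield (probability, joint odds multiplier) over all exposure subsets."""
    patterns = [(1.0, 1.0)]
    for spec in specs:
        updated = []
        for prob, mult in patterns:
            updated.append((prob * (1.0 - spec.marginal_exposure_prob), mult))
            updated.append(
                (prob * spec.marginal_exposure_prob, mult * spec.event_odds_multiplier)
            )
        patterns = updated
    yield from patterns


def _p_event(base_odds: float, multiplier: float) -> float:
    odds = base_odds * multiplier
    return odds / (1.0 + odds)


def expected_contingency(config: SimConfig, drug_name: str) -> ContingencyTable:
    """Closed-form expected 2×2 cells for one configured drug.

    Cells are real-valued expectations under the generative model,
    marginalising exactly over exposure to the other configured drugs.
    """
    names = [d.name for d in config.drugs]
    if drug_name not in names:
        raise KeyError(f"drug {drug_name!r} not in config")
    j = names.index(drug_name)
    spec = config.drugs[j]
    others = [d for i, d in enumerate(config.drugs) if i != j]
    p0 = config.background_event_prob
    base_odds = p0 / (1.0 - p0)

    p_event_exposed = sum(
        prob * _p_event(base_odds, mult * spec.event_odds_multiplier)
        for prob, mult in _exposure_patterns(others)
    )
    p_event_unexposed = sum(
        prob * _p_event(base_odds, mult) for prob, mult in _exposure_patterns(others)
    )
    n, pj = config.n_reports, spec.marginal_exposure_prob
    a = n * pj * p_event_exposed
    b = n * pj * (1.0 - p_event_exposed)
    c = n * (1.0 - pj) * p_event_unexposed
    d = n * (1.0 - pj) * (1.0 - p_event_unexposed)
    return ContingencyTable(a=a, b=b, c=c, d=d, validate_integers=False)
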