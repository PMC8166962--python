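"""Reduce a four-table dataset to the analysis set.

The analyses operate on one record per (report, canonical drug):
whether the report mentions the focal event (the *case* flag, defined
purely on the reaction table by a set of MedDRA PT codes), the earliest
complete administration start date among that drug's suspected rows,
the earliest complete onset date among focal-event reactions, and the
outcome of the focal reaction (first occurrence).

Only *suspected* drug rows enter the analysis set; concomitant and
interacting rows are dropped first.  Product names map to canonical
drug names and ATC codes through a user-supplied vocabulary — notably,
the two paclitaxel formulations ("paclitaxel" and "paclitaxel protein-
bound particles for injectable suspension") map to distinct canonical
drugs sharing ATC L01CD01, so they can be contrasted while still
pooling into the taxane class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Set

import pandas as pd

from .dates import parse_partial_date
from .tables import SrsDataset

logger = logging.getLogger(__name__)

UNASSIGNED_ATC = "unassigned"

ANALYSIS_COLUMNS = [
    "case_id",
    "drug",
    "atc_code",
    "is_case",
    "start_date",
    "onset_date",
    "outcome",
    "n_prescription_rows",
]

ATC_PREFIX_LENGTHS = (1, 3, 4, 5, 7)


@dataclass(frozen=True)
class VocabularyEntry:
    canonical_name: str
    atc_code: str


class DrugVocabulary:
    """product_name → (canonical drug name, ATC code or 'unassigned')."""

    def __init__(self, entries: Mapping[str, VocabularyEntry | tuple[str, str]]) -> None:
        self._entries: dict[str, VocabularyEntry] = {}
        for product, entry in entries.items():
            if not isinstance(entry, VocabularyEntry):
                entry = VocabularyEntry(*entry)
            if not entry.canonical_name:
                raise ValueError(f"empty canonical name for product {product!r}")
            self._entries[product] = entry

    def lookup(self, product_name: str) -> VocabularyEntry:
        """Map a product name; unknown products pass through with an
        'unassigned' ATC code (and a warning, once per product)."""
        entry = self._entries.get(product_name)
        if entry is None:
            logger.warning("product %r absent from vocabulary; ATC unassigned", product_name)
            return VocabularyEntry(product_name, UNASSIGNED_ATC)
        return entry

    def __contains__(self, product_name: str) -> bool:
        return product_name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugVocabulary":
        """Read a mapping file with columns product_name, canonical_name, atc_code."""
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"product_name", "canonical_name", "atc_code"}
        if not required <= set(table.columns):
            raise ValueError(f"vocabulary file needs columns {sorted(required)}")
        return cls(
            {
                row.product_name: VocabularyEntry(
                    row.canonical_name, row.atc_code or UNASSIGNED_ATC
                )
                for row in table.itertuples()
            }
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"product_name": k, "canonical_name": v.canonical_name, "atc_code": v.atc_code}
                for k, v in self._entries.items()
            ]
        ).to_csv(path, index=False)


def filter_suspected(dataset: SrsDataset) -> SrsDataset:
    """Keep only suspected drug rows; demo/reac/hist untouched."""
    return SrsDataset(
        demo=dataset.demo,
        drug=dataset.drug[dataset.drug["role_code"] == "suspected"].reset_index(drop=True),
        reac=dataset.reac,
        hist=dataset.hist,
    )


def flag_cases(dataset: SrsDataset, pt_codes: Set[int]) -> pd.Series:
    """Per-report case flags: True iff any reaction's PT code is focal.

    Indexed by case_id over every report in demo (reports with no
    reactions are False).  Depends on the reaction table only, so it is
    invariant under the suspected-drug filter.
    """
    if not pt_codes:
        raise ValueError("pt_codes must be non-empty")
    hits = dataset.reac.loc[dataset.reac["pt_code"].isin(pt_codes), "case_id"]
    flagged = set(hits)
    return pd.Series(
        [cid in flagged for cid in dataset.demo["case_id"]],
        index=pd.Index(dataset.demo["case_id"], name="case_id"),
        name="is_case",
    )


def _earliest(dates: Iterable[str]) -> str:
    """Earliest date string, preferring complete dates.

    Among YYYYMMDD strings the calendar-earliest complete date wins; if
    none is complete the lexicographically smallest partial is kept (it
    will be excluded, and counted, by the latency rules downstream).
    """
    dates = [d for d in dates if d]
    if not dates:
        return ""
    full = [d for d in dates if len(d) == 8]
    return min(full) if full else min(dates)


def assemble_analysis_set(
    dataset: SrsDataset,
    vocab: DrugVocabulary,
    pt_codes: Set[int],
) -> pd.DataFrame:
    """One analysis record per (report, canonical drug).

    Applies the suspected-drug filter internally; collapses duplicate
    prescription rows of the same drug (keeping the count collapsed for
    the exclusion accounting); attaches the case flag, the earliest
    complete focal-event onset, and the focal reaction's outcome (first
    occurrence in table order).
    """
    suspected = filter_suspected(dataset)
    drug = suspected.drug
    if drug.empty:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS)

    mapped = drug.copy()
    entries = [vocab.lookup(p) for p in mapped["product_name"]]
    mapped["drug"] = [e.canonical_name for e in entries]
    mapped["atc_code"] = [e.atc_code for e in entries]

    grouped = (
        mapped.groupby(["case_id", "drug"], sort=False)
        .agg(
            atc_code=("atc_code", "first"),
            start_date=("start_date", _earliest),
            n_prescription_rows=("start_date", "size"),
        )
        .reset_index()
    )

    flags = flag_cases(dataset, pt_codes)
    grouped["is_case"] = grouped["case_id"].map(flags).astype(bool)

    focal = dataset.reac[dataset.reac["pt_code"].isin(pt_codes)]
    onset_by_case = focal.groupby("case_id")["onset_date"].agg(_earliest)
    outcome_by_case = focal.groupby("case_id")["outcome"].first()
    grouped["onset_date"] = grouped["case_id"].map(onset_by_case).fillna("")
    grouped["outcome"] = grouped["case_id"].map(outcome_by_case).fillna("")
    grouped.loc[~grouped["is_case"], ["onset_date", "outcome"]] = ""

    return grouped[ANALYSIS_COLUMNS].sort_values(
        ["case_id", "drug"], kind="stable"
    ).reset_index(drop=True)


def aggregate_by_atc(records: pd.DataFrame, level: int = 5) -> pd.DataFrame:
    """Regroup analysis records under ATC prefixes of the given length.

    A report exposed to several drugs of one class becomes a single
    class-level record (set semantics — the 2×2 denominators stay
    report counts); its start date is the earliest complete start among
    the member drugs.  Drugs without an assigned ATC code are excluded
    from class groups.
    """
    if level not in ATC_PREFIX_LENGTHS:
        raise ValueError(f"ATC prefix length must be one of {ATC_PREFIX_LENGTHS}")
    assigned = records[records["atc_code"] != UNASSIGNED_ATC].copy()
    if assigned.empty:
        return pd.DataFrame(columns=ANALYSIS_COLUMNS)
    assigned["drug"] = assigned["atc_code"].str[:level]
    assigned["atc_code"] = assigned["drug"]
    out = (
        assigned.groupby(["case_id", "drug"], sort=False)
        .agg(
            atc_code=("atc_code", "first"),
            is_case=("is_case", "any"),
            start_date=("start_date", _earliest),
            onset_date=("onset_date", _earliest),
            outcome=("outcome", "first"),
            n_prescription_rows=("n_prescription_rows", "sum"),
        )
        .reset_index()
    )
    return out[ANALYSIS_COLUMNS].sort_values(
        ["case_id", "drug"], kind="stable"
    ).reset_index(drop=True)
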