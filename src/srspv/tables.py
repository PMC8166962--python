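"""Data model and I/O for the four-table spontaneous-report layout.

Spontaneous-reporting-system extracts in the JADER layout ship as four
relational tables keyed by an opaque report (case) identifier:

``demo``
    one row per report: sex, age band, reporting period;
``drug``
    one row per prescribed drug per report, with the role code the
    reporter assigned (suspected / concomitant / interacting) and
    administration start/end dates;
``reac``
    one row per adverse event per report, with the MedDRA preferred-term
    (PT) code, onset date, and outcome;
``hist``
    primary disease, read and validated but not used by any analysis.

Tables are held as pandas DataFrames with fixed column names; dates are
digit strings (``YYYYMMDD``/``YYYYMM``/``YYYY``, '' = absent) so partial
dates survive round-trips untouched.  Files are comma-separated UTF-8
with a header row by default; an ``encoding`` option exists because real
source extracts are not UTF-8.  Role and outcome codes are canonical
English tokens; a user-editable mapping (e.g. from source-language
strings) may be supplied at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .dates import DateParseError, parse_partial_date

logger = logging.getLogger(__name__)

ROLE_CODES = ("suspected", "concomitant", "interacting")
OUTCOME_CODES = (
    "death",
    "with_sequelae",
    "not_recovered",
    "improved",
    "recovered",
    "unknown",
    "",  # blank
)
SEX_CODES = ("male", "female", "unknown")

DEMO_COLUMNS = ["case_id", "sex", "age_band", "report_period"]
DRUG_COLUMNS = ["case_id", "drug_seq", "product_name", "role_code", "start_date", "end_date"]
REAC_COLUMNS = ["case_id", "pt_code", "pt_name", "onset_date", "outcome"]
HIST_COLUMNS = ["case_id", "disease"]

TABLE_COLUMNS = {
    "demo": DEMO_COLUMNS,
    "drug": DRUG_COLUMNS,
    "reac": REAC_COLUMNS,
    "hist": HIST_COLUMNS,
}

_DATE_COLUMNS = {
    "demo": ["report_period"],
    "drug": ["start_date", "end_date"],
    "reac": ["onset_date"],
    "hist": [],
}


class DatasetValidationError(ValueError):
    """A structural invariant of the four-table dataset is violated."""


@dataclass
class SrsDataset:
    """A validated four-table spontaneous-report dataset.

    ``n_reports`` (= number of demo rows) is the report denominator used
    by every downstream analysis.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    hist: pd.DataFrame
    n_rejected: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.demo = _coerce(self.demo, "demo")
        self.drug = _coerce(self.drug, "drug")
        self.reac = _coerce(self.reac, "reac")
        self.hist = _coerce(self.hist, "hist")
        self.validate()

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def validate(self) -> None:
        dup = self.demo["case_id"][self.demo["case_id"].duplicated()]
        if len(dup):
            raise DatasetValidationError(
                f"duplicate case_id in demo: {sorted(set(dup))[:5]}"
            )
        if (self.demo["case_id"] == "").any():
            raise DatasetValidationError("empty case_id in demo")
        known = set(self.demo["case_id"])
        for name, table in (("drug", self.drug), ("reac", self.reac), ("hist", self.hist)):
            orphans = set(table["case_id"]) - known
            if orphans:
                raise DatasetValidationError(
                    f"{name} rows reference case_ids absent from demo: {sorted(orphans)[:5]}"
                )
        if self.drug.duplicated(subset=["case_id", "drug_seq"]).any():
            raise DatasetValidationError("duplicate (case_id, drug_seq) in drug table")
        bad_role = ~self.drug["role_code"].isin(ROLE_CODES)
        if bad_role.any():
            raise DatasetValidationError(
                f"unknown role codes: {sorted(set(self.drug.loc[bad_role, 'role_code']))}"
            )
        bad_out = ~self.reac["outcome"].isin(OUTCOME_CODES)
        if bad_out.any():
            raise DatasetValidationError(
                f"unknown outcome codes: {sorted(set(self.reac.loc[bad_out, 'outcome']))}"
            )
        if (self.reac["pt_code"] <= 0).any():
            raise DatasetValidationError("non-positive MedDRA PT code in reac")
        for name in TABLE_COLUMNS:
            table = getattr(self, name)
            for col in _DATE_COLUMNS[name]:
                for value in table[col]:
                    parse_partial_date(value)  # raises on malformed text

    def equals(self, other: "SrsDataset") -> bool:
        return all(
            getattr(self, name)
            .reset_index(drop=True)
            .equals(getattr(other, name).reset_index(drop=True))
            for name in TABLE_COLUMNS
        )


def _coerce(table: pd.DataFrame, name: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DatasetValidationError(f"{name} table missing columns {missing}")
    table = table[cols].copy().reset_index(drop=True)
    for col in cols:
        if col in ("drug_seq", "pt_code"):
            table[col] = table[col].astype(int)
        else:
            table[col] = table[col].fillna("").astype(str)
    return table


def empty_dataset() -> SrsDataset:
    return SrsDataset(
        demo=pd.DataFrame(columns=DEMO_COLUMNS),
        drug=pd.DataFrame(columns=DRUG_COLUMNS).astype({"drug_seq": int}),
        reac=pd.DataFrame(columns=REAC_COLUMNS).astype({"pt_code": int}),
        hist=pd.DataFrame(columns=HIST_COLUMNS),
    )


def _read_table(
    path: Path,
    name: str,
    sep: str,
    encoding: str,
    code_maps: Optional[Mapping[str, Mapping[str, str]]],
) -> tuple[pd.DataFrame, int]:
    """Read one table, dropping (and counting) rows with unparseable
    mandatory fields; unknown role/outcome codes reject the record."""
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    table = pd.read_csv(path, sep=sep, encoding=encoding, dtype=str, keep_default_na=False)
    missing = [c for c in TABLE_COLUMNS[name] if c not in table.columns]
    if missing:
        raise DatasetValidationError(f"{path}: header lacks columns {missing}")

    if code_maps:
        if name == "drug" and "role_code" in code_maps:
            table["role_code"] = table["role_code"].map(
                lambda v: code_maps["role_code"].get(v, v)
            )
        if name == "reac" and "outcome" in code_maps:
            table["outcome"] = table["outcome"].map(
                lambda v: code_maps["outcome"].get(v, v)
            )

    ok = pd.Series(True, index=table.index)
    if name == "drug":
        ok &= table["drug_seq"].str.fullmatch(r"\d+").fillna(False)
        ok &= table["role_code"].isin(ROLE_CODES)
    if name == "reac":
        ok &= table["pt_code"].str.fullmatch(r"\d+").fillna(False)
        ok &= table["outcome"].isin(OUTCOME_CODES)
    for col in _DATE_COLUMNS[name]:
        def _parses(v: str) -> bool:
            try:
                parse_partial_date(v)
                return True
            except DateParseError:
                return False

        ok &= table[col].map(_parses)

    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("%s: rejected %d unparseable/unknown-code rows", path, n_rejected)
    table = table[ok]
    if name == "drug":
        table = table.astype({"drug_seq": int})
    if name == "reac":
        table = table.astype({"pt_code": int})
    return table, n_rejected


def read_dataset(
    paths: Mapping[str, str | Path],
    sep: str = ",",
    encoding: str = "utf-8",
    code_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> SrsDataset:
    """Read and validate the four tables.

    Parameters
    ----------
    paths
        Mapping with keys ``demo``, ``drug``, ``reac``, ``hist``.
    code_maps
        Optional vocabularies translating source role/outcome strings to
        the canonical tokens, e.g. ``{"role_code": {"被疑薬": "suspected"}}``.
    """
    tables, rejected = {}, {}
    for name in TABLE_COLUMNS:
        if name not in paths:
            raise KeyError(f"missing path for table {name!r}")
        tables[name], rejected[name] = _read_table(
            Path(paths[name]), name, sep, encoding, code_maps
        )
    return SrsDataset(**tables, n_rejected=rejected)


def write_dataset(
    dataset: SrsDataset,
    paths: Mapping[str, str | Path],
    sep: str = ",",
    encoding: str = "utf-8",
) -> None:
    """Write the four tables; reading them back yields an equal dataset."""
    for name in TABLE_COLUMNS:
        path = Path(paths[name])
        path.parent.mkdir(parents=True, exist_ok=True)
        getattr(dataset, name).to_csv(path, sep=sep, encoding=encoding, index=False)


def default_paths(directory: str | Path) -> dict[str, Path]:
    """Conventional file names inside a dataset directory."""
    directory = Path(directory)
    return {name: directory / f"{name}.csv" for name in TABLE_COLUMNS}
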