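"""Reading, cleaning and list-order coding of procedure records.

A *theatre list* is the ordered set of procedures one surgeon performs at
one hospital on one day.  Each case on a list receives three order codes:

``absolute_list_no``
    1-based position among all procedures on the list.
``procedure_specific_list_no``
    how many times that same procedure code has occurred on the list up to
    and including the case.
``switch``
    True iff the immediately preceding case on the list is a different
    procedure.  The first case of a list is coded False ("not applicable"):
    there is no preceding case, hence no switch cost.

Record collections are plain :class:`pandas.DataFrame` objects with the
column schema in :data:`RECORD_COLUMNS`; coded frames add the three columns
above plus a ``list_id`` grouping key.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: 8 ordered patient age bins (anonymized ages).
AGE_GROUPS = ["<=18", "19-24", "25-34", "35-44", "45-54", "55-64", "65-75", ">75"]

#: ASA physical-status grades I (healthy) to V (moribund).
ASA_GRADES = ["I", "II", "III", "IV", "V"]

#: Input CSV schema; ``method``/``complexity`` come from a separate mapping.
RECORD_COLUMNS = [
    "record_id",
    "surgeon_id",
    "hospital_id",
    "list_date",
    "start_time",
    "procedure_code",
    "age_group",
    "asa_grade",
    "duration_min",
    "los_min",
]

CODED_COLUMNS = ["absolute_list_no", "procedure_specific_list_no", "switch"]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ExclusionSummary:
    """Counts of records removed by the cleaning rules, in rule order.

    Each input row is counted once, under the first rule that excludes it:
    missing surgeon identifier, then missing start time, then duplicate of
    an earlier row (identical on every field; the earlier row is kept),
    then non-positive or missing duration, then an age-group or ASA value
    outside the recognized categories.  ``n_retained`` plus the exclusion
    counts always equals ``n_input``.
    """

    n_input: int
    n_missing_surgeon: int
    n_missing_start: int
    n_duplicates: int
    n_nonpositive_duration: int
    n_invalid_category: int
    n_retained: int

    def __post_init__(self) -> None:
        excluded = (
            self.n_missing_surgeon
            + self.n_missing_start
            + self.n_duplicates
            + self.n_nonpositive_duration
            + self.n_invalid_category
        )
        if self.n_retained != self.n_input - excluded:
            raise ValueError("exclusion counts do not partition the input")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_records(path: str | Path) -> pd.DataFrame:
    """Read a raw procedure-record CSV.

    All columns are read as strings (cleaning decides validity); a parse
    failure is fatal and reports the offending line.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, on_bad_lines="error")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"unparseable records file {path}: {exc}") from exc
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c != "los_min"]
    if missing:
        raise ValueError(f"records file {path} lacks required columns: {missing}")
    if "los_min" not in df.columns:
        df["los_min"] = ""
    return df.loc[:, RECORD_COLUMNS].copy()


def _blank(s: pd.Series) -> pd.Series:
    return s.isna() | (s.astype(str).str.strip() == "")


def clean_records(raw: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionSummary]:
    """Apply the exclusion flow and return (retained records, summary).

    Retained rows have parsed types: ``list_date`` as datetime64,
    ``duration_min``/``los_min`` numeric (``los_min`` may be NaN), category
    columns validated against :data:`AGE_GROUPS` / :data:`ASA_GRADES`.
    """
    df = raw.copy().reset_index(drop=True)
    n_input = len(df)
    alive = np.ones(n_input, dtype=bool)

    miss_surgeon = _blank(df["surgeon_id"]).to_numpy()
    n_missing_surgeon = int((alive & miss_surgeon).sum())
    alive &= ~miss_surgeon

    miss_start = _blank(df["start_time"]).to_numpy()
    n_missing_start = int((alive & miss_start).sum())
    alive &= ~miss_start

    # duplicate = identical to an earlier row on every field, among rows
    # not already excluded; the earlier copy is kept
    dup = df.loc[alive].astype(str).duplicated(keep="first")
    dup_full = np.zeros(n_input, dtype=bool)
    dup_full[dup.index[dup]] = True
    n_duplicates = int(dup_full.sum())
    alive &= ~dup_full

    duration = pd.to_numeric(df["duration_min"], errors="coerce")
    bad_dur = (duration.isna() | (duration <= 0)).to_numpy()
    n_nonpositive = int((alive & bad_dur).sum())
    alive &= ~bad_dur

    bad_cat = (~df["age_group"].isin(AGE_GROUPS) | ~df["asa_grade"].isin(ASA_GRADES)).to_numpy()
    n_invalid = int((alive & bad_cat).sum())
    alive &= ~bad_cat

    out = df.loc[alive].copy()
    out["list_date"] = pd.to_datetime(out["list_date"], format="%Y-%m-%d", errors="raise")
    out["duration_min"] = pd.to_numeric(out["duration_min"])
    out["los_min"] = pd.to_numeric(out["los_min"].replace("", np.nan))
    out = out.reset_index(drop=True)

    summary = ExclusionSummary(
        n_input=n_input,
        n_missing_surgeon=n_missing_surgeon,
        n_missing_start=n_missing_start,
        n_duplicates=n_duplicates,
        n_nonpositive_duration=n_nonpositive,
        n_invalid_category=n_invalid,
        n_retained=len(out),
    )
    return out, summary


def build_lists(records: pd.DataFrame, include_hospital: bool = True) -> pd.DataFrame:
    """Partition cleaned records into theatre lists.

    Grouping key is (surgeon_id, hospital_id, list_date); set
    ``include_hospital=False`` to treat a surgeon's whole day as one list
    regardless of site.  Within a list, cases are ordered by start time,
    ties broken by record_id so the ordering is total and reproducible.
    Returns the records sorted in list order with an integer ``list_id``.
    """
    key = ["surgeon_id", "list_date"] + (["hospital_id"] if include_hospital else [])
    df = records.sort_values(key + ["start_time", "record_id"], kind="mergesort").reset_index(
        drop=True
    )
    df["list_id"] = df.groupby(key, sort=False).ngroup()
    return df


def assign_list_numbers(lists: pd.DataFrame) -> pd.DataFrame:
    """Assign absolute/procedure-specific list numbers and switch flags.

    Expects the output of :func:`build_lists` (a ``list_id`` column with
    rows already in within-list order).  Idempotent: re-coding a coded
    frame yields the same codes.
    """
    df = lists.copy()
    if df.empty:
        for c in CODED_COLUMNS:
            df[c] = pd.Series(dtype=int if c != "switch" else bool)
        return df
    grp = df.groupby("list_id", sort=False)
    df["absolute_list_no"] = grp.cumcount() + 1
    df["procedure_specific_list_no"] = (
        df.groupby(["list_id", "procedure_code"], sort=False).cumcount() + 1
    )
    prev_code = grp["procedure_code"].shift(1)
    df["switch"] = prev_code.notna() & (prev_code != df["procedure_code"])
    return df


def classify(records: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Attach method/complexity strata from a procedure-code mapping.

    ``mapping`` is ``{code: {"method": ..., "complexity": ...}}``.  Codes
    absent from the mapping are retained with both strata set to
    ``"unclassified"``; stratified analyses drop them and report the count.
    """
    df = records.copy()
    method = {c: str(v["method"]) for c, v in mapping.items()}
    complexity = {c: str(v["complexity"]) for c, v in mapping.items()}
    df["method"] = df["procedure_code"].map(method).fillna(UNCLASSIFIED)
    df["complexity"] = df["procedure_code"].map(complexity).fillna(UNCLASSIFIED)
    return df


def load_mapping(path: str | Path) -> dict:
    """Read a YAML/JSON procedure-code → (method, complexity) mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"mapping file {path} must be a mapping keyed by procedure code")
    return {str(k): {"method": v["method"], "complexity": v["complexity"]} for k, v in data.items()}


def save_mapping(mapping: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(mapping, sort_keys=True))


def switch_fraction(coded: pd.DataFrame) -> float:
    """Fraction of coded cases that switched from the preceding procedure."""
    if len(coded) == 0:
        raise ValueError("switch_fraction undefined on empty input")
    return float(coded["switch"].mean())


def code_records(
    records: pd.DataFrame, include_hospital: bool = True
) -> pd.DataFrame:
    """Convenience: build lists and assign codes in one step."""
    return assign_list_numbers(build_lists(records, include_hospital=include_hospital))
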