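"""Claims data model: tables, code maps, readers/writers and validation.

The package works on four delimited tables (patients, eligibility periods,
diagnosis claims, pharmacy claims) plus a YAML configuration of code groups.
Dates are parsed at the I/O boundary and carried internally as integer day
offsets from a fixed epoch, because every downstream rule (washout windows,
episode gaps, regimen locks, grace periods) is plain day arithmetic.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

#: Epoch for internal day offsets. Any fixed date works; this one keeps
#: offsets small and positive for claims data from the 2000s.
EPOCH = _dt.date(2000, 1, 1)

#: Therapeutic classes. ADAP = antidepressant + antipsychotic/antimanic
#: drugs, the only classes that enter regimen construction.
DRUG_CLASSES = (
    "SSRI",
    "SNRI",
    "ATYPICAL_AD",
    "AD_OTHERS",
    "AP",
    "LITHIUM",
    "MAOI",
    "OTHER_NON_ADAP",
)
ADAP_CLASSES = frozenset(c for c in DRUG_CLASSES if c != "OTHER_NON_ADAP")
#: Antidepressant classes proper: used for the index-date washout and for
#: episode-relevant prescription events (antipsychotics and lithium are
#: ADAP but not antidepressants).
AD_CLASSES = frozenset({"SSRI", "SNRI", "ATYPICAL_AD", "AD_OTHERS", "MAOI"})

MRU_CATEGORIES = (
    "hospitalization",
    "pharmacy",
    "office_gp",
    "office_psych",
    "er",
    "lab",
    "other_outpatient",
    "psychotherapy",
)


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class RowError(ValueError):
    """A row-level failure (e.g. an unparseable date), with line numbers."""


def to_day(d: _dt.date | str) -> int:
    """Convert a calendar date (or ISO-8601 string) to an epoch day offset."""
    if isinstance(d, str):
        d = _dt.date.fromisoformat(d)
    return (d - EPOCH).days


def from_day(day: int) -> _dt.date:
    """Convert an epoch day offset back to a calendar date."""
    return EPOCH + _dt.timedelta(days=int(day))


def canonical_dx(code: str) -> str:
    """Canonicalize an ICD-9-CM code to dotted form.

    Claims files carry both dotted ("296.20") and undotted ("29620") forms;
    groups are configured as dotted prefixes. Canonicalization inserts the
    dot after the 3-character head (4 characters for E-codes) and is
    idempotent on already-dotted codes.
    """
    code = str(code).strip().upper()
    if not code or "." in code:
        return code
    head = 4 if code.startswith("E") else 3
    if len(code) > head:
        return code[:head] + "." + code[head:]
    return code


def code_in_group(code: str, prefixes: Iterable[str]) -> bool:
    """True iff the canonical code starts with any canonical prefix."""
    c = canonical_dx(code)
    return any(c.startswith(canonical_dx(p)) for p in prefixes)


@dataclass(frozen=True)
class Issue:
    """One validation finding: table, row index, rule id, human message."""

    table: str
    row: int
    rule: str
    message: str


@dataclass
class CodeMaps:
    """Configured code groups driving every classification step.

    ``inclusion_dx`` / ``exclusion_dx`` are ICD-9 prefixes defining the
    depressive-disorder cohort and the schizophrenia / schizoaffective /
    bipolar exclusions. ``drug_class`` maps opaque drug ids to therapeutic
    classes. ``comorbidity_groups`` maps condition names to dx prefixes.
    ``mru_categories`` maps claim ``setting`` keys to resource-use
    categories.
    """

    inclusion_dx: frozenset[str]
    exclusion_dx: frozenset[str]
    drug_class: dict[str, str]
    comorbidity_groups: dict[str, frozenset[str]] = field(default_factory=dict)
    mru_categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.inclusion_dx = frozenset(canonical_dx(c) for c in self.inclusion_dx)
        self.exclusion_dx = frozenset(canonical_dx(c) for c in self.exclusion_dx)
        overlap = {
            i
            for i in self.inclusion_dx
            for e in self.exclusion_dx
            if i.startswith(e) or e.startswith(i)
        }
        if overlap:
            raise ValueError(f"inclusion/exclusion prefixes overlap: {sorted(overlap)}")
        bad = {c for c in self.drug_class.values() if c not in DRUG_CLASSES}
        if bad:
            raise ValueError(f"unknown drug classes: {sorted(bad)}")
        self.comorbidity_groups = {
            g: frozenset(canonical_dx(c) for c in codes)
            for g, codes in self.comorbidity_groups.items()
        }

    # -- queries -----------------------------------------------------------
    def klass(self, drug_id: str) -> str:
        """Therapeutic class of a drug; unknown drugs fall back to
        OTHER_NON_ADAP (retained in data, excluded from regimens)."""
        return self.drug_class.get(drug_id, "OTHER_NON_ADAP")

    def is_adap(self, drug_id: str) -> bool:
        return self.klass(drug_id) in ADAP_CLASSES

    def is_antidepressant(self, drug_id: str) -> bool:
        return self.klass(drug_id) in AD_CLASSES

    def is_inclusion(self, code: str) -> bool:
        return code_in_group(code, self.inclusion_dx)

    def is_exclusion(self, code: str) -> bool:
        return code_in_group(code, self.exclusion_dx)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMaps":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("inclusion_dx", "exclusion_dx", "drug_class"):
            if key not in raw:
                raise SchemaError(f"codemaps file missing key {key!r}")
        return cls(
            inclusion_dx=frozenset(raw["inclusion_dx"]),
            exclusion_dx=frozenset(raw["exclusion_dx"]),
            drug_class=dict(raw["drug_class"]),
            comorbidity_groups={
                g: frozenset(v) for g, v in raw.get("comorbidity_groups", {}).items()
            },
            mru_categories=dict(raw.get("mru_categories", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "inclusion_dx": sorted(self.inclusion_dx),
            "exclusion_dx": sorted(self.exclusion_dx),
            "drug_class": dict(sorted(self.drug_class.items())),
            "comorbidity_groups": {
                g: sorted(v) for g, v in sorted(self.comorbidity_groups.items())
            },
            "mru_categories": dict(sorted(self.mru_categories.items())),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


#: required columns per table (date columns are converted to *_day offsets)
_SCHEMAS = {
    "patients": ["patient_id", "sex", "birth_date"],
    "eligibility": ["patient_id", "start_date", "end_date"],
    "dx_claims": ["patient_id", "service_date", "dx_code", "setting", "paid_amount"],
    "rx_claims": ["patient_id", "fill_date", "drug_id", "days_supply", "paid_amount"],
}
_DATE_COLS = {
    "patients": ["birth_date"],
    "eligibility": ["start_date", "end_date"],
    "dx_claims": ["service_date"],
    "rx_claims": ["fill_date"],
}


@dataclass
class ClaimsDataset:
    """The universe every pipeline stage consumes.

    Tables are pandas DataFrames with dates as integer ``*_day`` epoch
    offsets and an ``order`` column preserving input row order as the
    stable tie-break. ``load_issues`` records rows rejected at load time.
    """

    patients: pd.DataFrame
    eligibility: pd.DataFrame
    dx_claims: pd.DataFrame
    rx_claims: pd.DataFrame
    code_maps: CodeMaps
    load_issues: list[Issue] = field(default_factory=list)


_STR_COLS = {"patient_id": str, "sex": str, "dx_code": str, "setting": str,
             "drug_id": str}


def _read_table(path: str | Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=_STR_COLS)
    for col in _SCHEMAS[table]:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")
    for col in _DATE_COLS[table]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()] + 2  # 1-based + header
        if len(bad):
            raise RowError(
                f"{table}: unparseable {col} at line(s) {list(bad[:10])}"
            )
        day_col = col.replace("_date", "_day")
        df[day_col] = (parsed - pd.Timestamp(EPOCH)).dt.days.astype("Int64")
    df["order"] = range(len(df))
    return df


def load_dataset(
    paths: Mapping[str, str | Path] | str | Path, codemap_path: str | Path
) -> ClaimsDataset:
    """Load and validate the four claims tables plus the code maps.

    ``paths`` is either a directory containing the canonically named CSVs
    (patients.csv, eligibility.csv, dx_claims.csv, rx_claims.csv) or a
    mapping of table name to file path. Rows violating hard invariants
    (e.g. ``days_supply < 1``) are rejected and reported in
    ``load_issues``; claims are sorted by (patient_id, date) with input
    order as the stable tie-break.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f"{t}.csv" for t in _SCHEMAS}
    tables = {t: _read_table(paths[t], t) for t in _SCHEMAS}
    issues: list[Issue] = []

    rx = tables["rx_claims"]
    bad_supply = rx["days_supply"] < 1
    for i in rx.index[bad_supply]:
        issues.append(
            Issue("rx_claims", int(i), "invalid_days_supply",
                  f"days_supply={rx.at[i, 'days_supply']} < 1; row rejected")
        )
    rx = rx.loc[~bad_supply].copy()

    dx = tables["dx_claims"]
    dx["dx_code"] = dx["dx_code"].map(canonical_dx)

    patients = tables["patients"].sort_values(["patient_id", "order"], kind="stable")
    eligibility = tables["eligibility"].sort_values(
        ["patient_id", "start_day", "order"], kind="stable"
    )
    dx = dx.sort_values(["patient_id", "service_day", "order"], kind="stable")
    rx = rx.sort_values(["patient_id", "fill_day", "order"], kind="stable")

    return ClaimsDataset(
        patients=patients.reset_index(drop=True),
        eligibility=eligibility.reset_index(drop=True),
        dx_claims=dx.reset_index(drop=True),
        rx_claims=rx.reset_index(drop=True),
        code_maps=CodeMaps.from_yaml(codemap_path),
        load_issues=issues,
    )


def write_dataset(ds: ClaimsDataset, out_dir: str | Path) -> None:
    """Write the dataset back to the canonical CSV set + codemaps.yaml."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for table, df in (
        ("patients", ds.patients),
        ("eligibility", ds.eligibility),
        ("dx_claims", ds.dx_claims),
        ("rx_claims", ds.rx_claims),
    ):
        cols = _SCHEMAS[table]
        frame = df.copy()
        for col in _DATE_COLS[table]:
            day_col = col.replace("_date", "_day")
            frame[col] = frame[day_col].map(lambda d: from_day(d).isoformat())
        frame[cols].to_csv(out / f"{table}.csv", index=False)
    ds.code_maps.to_yaml(out / "codemaps.yaml")


def merge_periods(periods: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge inclusive [start, end] day periods that overlap or abut.

    Periods with ``next.start <= prev.end + 1`` merge, so back-to-back
    enrollment segments count as continuous coverage.
    """
    merged: list[tuple[int, int]] = []
    for s, e in sorted(periods):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def validate_dataset(ds: ClaimsDataset) -> list[Issue]:
    """Check type invariants; returns an empty list iff the dataset is clean.

    Validation never raises on content: every finding is an :class:`Issue`
    with the table, row and rule id. Load-time rejections are included.
    """
    issues = list(ds.load_issues)
    known = set(ds.patients["patient_id"])

    dup = ds.patients["patient_id"].duplicated()
    for i in ds.patients.index[dup]:
        issues.append(Issue("patients", int(i), "duplicate_patient",
                            f"patient_id {ds.patients.at[i, 'patient_id']!r} repeated"))

    bad = ~ds.eligibility["patient_id"].isin(known)
    for i in ds.eligibility.index[bad]:
        issues.append(Issue("eligibility", int(i), "orphan_claim", "unknown patient_id"))
    rev = ds.eligibility["start_day"] > ds.eligibility["end_day"]
    for i in ds.eligibility.index[rev]:
        issues.append(Issue("eligibility", int(i), "reversed_period",
                            "start_date after end_date"))

    birth = dict(zip(ds.patients["patient_id"], ds.patients["birth_day"]))
    for table, day_col in (("dx_claims", "service_day"), ("rx_claims", "fill_day")):
        df: pd.DataFrame = getattr(ds, table)
        orphan = ~df["patient_id"].isin(known)
        for i in df.index[orphan]:
            issues.append(Issue(table, int(i), "orphan_claim", "unknown patient_id"))
        ok = df.loc[~orphan]
        before = ok[day_col] < ok["patient_id"].map(birth)
        for i in ok.index[before]:
            issues.append(Issue(table, int(i), "claim_before_birth",
                                "claim predates patient birth_date"))
        neg = df["paid_amount"] < 0
        for i in df.index[neg]:
            issues.append(Issue(table, int(i), "negative_paid", "paid_amount < 0"))

    unmapped = ~ds.rx_claims["drug_id"].isin(ds.code_maps.drug_class)
    for i in ds.rx_claims.index[unmapped]:
        issues.append(Issue("rx_claims", int(i), "unmapped_drug",
                            f"drug_id {ds.rx_claims.at[i, 'drug_id']!r} not in class map; "
                            "claim retained as OTHER_NON_ADAP"))
    return issues
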