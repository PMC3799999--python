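"""Cohort selection: exclusion cascade and Index Diagnosis Date.

A patient enters the cohort if they have no schizophrenia / schizoaffective
/ bipolar exclusion diagnosis at any time, are 18-64 years old at index,
and have an Index Diagnosis Date: the first depressive-disorder inclusion
diagnosis with a 120-day clean period before it (no inclusion diagnosis, no
antidepressant fill) and continuous insurance eligibility from 120 days
before to 720 days after.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import ClaimsDataset, CodeMaps, merge_periods

WASHOUT_DAYS = 120
ELIG_PRE_DAYS = 120
ELIG_POST_DAYS = 720
AGE_MIN, AGE_MAX = 18, 64


@dataclass
class SelectionCascade:
    """Patient counts surviving each filter, in filter order."""

    initial: int = 0
    after_exclusion_dx: int = 0
    after_age: int = 0
    after_index_date: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "initial": self.initial,
            "after_exclusion_dx": self.after_exclusion_dx,
            "after_age": self.after_age,
            "after_index_date": self.after_index_date,
        }


def has_exclusion_diagnosis(dx_codes, code_maps: CodeMaps) -> bool:
    """True iff any diagnosis in the patient's history (previous or
    comorbid, at any time) matches an exclusion prefix."""
    return any(code_maps.is_exclusion(c) for c in dx_codes)


def age_at(birth_day: int, day: int) -> int:
    """Completed years between two epoch-day offsets."""
    from .model import from_day

    b, d = from_day(birth_day), from_day(day)
    years = d.year - b.year
    if (d.month, d.day) < (b.month, b.day):
        years -= 1
    return years


def _candidate_index_dates(
    inclusion_days: list[int],
    ad_fill_days: list[int],
    washout: int = WASHOUT_DAYS,
) -> list[int]:
    """Inclusion-diagnosis dates whose prior washout window is clean.

    A candidate day d has no inclusion diagnosis and no antidepressant
    fill in [d - washout, d - 1].
    """
    events = sorted(set(inclusion_days) | set(ad_fill_days))
    out = []
    for d in sorted(set(inclusion_days)):
        lo = d - washout
        if not any(lo <= e < d for e in events):
            out.append(d)
    return out


def find_index_date(
    inclusion_days: list[int],
    ad_fill_days: list[int],
    eligibility: list[tuple[int, int]],
    washout: int = WASHOUT_DAYS,
    elig_pre: int = ELIG_PRE_DAYS,
    elig_post: int = ELIG_POST_DAYS,
) -> int | None:
    """Earliest inclusion-dx day with a clean washout and full eligibility.

    Eligibility periods are merged (adjacent periods are continuous); a
    candidate qualifies if one merged period covers
    [d - elig_pre, d + elig_post] entirely.
    """
    merged = merge_periods(eligibility)
    for d in _candidate_index_dates(inclusion_days, ad_fill_days, washout):
        if any(s <= d - elig_pre and e >= d + elig_post for s, e in merged):
            return d
    return None


def select_cohort(
    ds: ClaimsDataset,
    washout: int = WASHOUT_DAYS,
    elig_pre: int = ELIG_PRE_DAYS,
    elig_post: int = ELIG_POST_DAYS,
) -> tuple[pd.DataFrame, SelectionCascade]:
    """Apply the full selection cascade to every patient.

    Filter order: exclusion diagnosis, then age (evaluated at the earliest
    washout-clean candidate index date), then index-date confirmation
    (eligibility coverage). Returns one record per patient with columns
    patient_id, index_day, age_at_index, included, exclusion_reason, and
    the stage-by-stage cascade counts.
    """
    cm = ds.code_maps
    dx_by_pat = {
        pid: grp for pid, grp in ds.dx_claims.groupby("patient_id", sort=False)
    }
    ad_ids = {d for d in ds.rx_claims["drug_id"].unique() if cm.is_antidepressant(d)}
    rx_ad = ds.rx_claims[ds.rx_claims["drug_id"].isin(ad_ids)]
    ad_days_by_pat = {
        pid: grp["fill_day"].tolist()
        for pid, grp in rx_ad.groupby("patient_id", sort=False)
    }
    elig_by_pat = {
        pid: list(zip(grp["start_day"].astype(int), grp["end_day"].astype(int)))
        for pid, grp in ds.eligibility.groupby("patient_id", sort=False)
    }

    records = []
    cascade = SelectionCascade(initial=len(ds.patients))
    for _, pat in ds.patients.iterrows():
        pid = pat["patient_id"]
        dx = dx_by_pat.get(pid)
        codes = dx["dx_code"].tolist() if dx is not None else []
        days = dx["service_day"].tolist() if dx is not None else []
        inclusion_days = [int(d) for d, c in zip(days, codes) if cm.is_inclusion(c)]
        ad_days = [int(d) for d in ad_days_by_pat.get(pid, [])]

        rec = {
            "patient_id": pid,
            "index_day": pd.NA,
            "age_at_index": pd.NA,
            "included": False,
            "exclusion_reason": "none",
        }
        if has_exclusion_diagnosis(codes, cm):
            rec["exclusion_reason"] = "exclusion_dx"
            records.append(rec)
            continue
        candidates = _candidate_index_dates(inclusion_days, ad_days, washout)
        if not candidates:
            rec["exclusion_reason"] = "no_index_date"
            records.append(rec)
            continue
        age0 = age_at(int(pat["birth_day"]), candidates[0])
        if not (AGE_MIN <= age0 <= AGE_MAX):
            rec["exclusion_reason"] = "age"
            rec["age_at_index"] = age0
            records.append(rec)
            continue
        index_day = find_index_date(
            inclusion_days, ad_days, elig_by_pat.get(pid, []),
            washout, elig_pre, elig_post,
        )
        if index_day is None:
            rec["exclusion_reason"] = "no_index_date"
            records.append(rec)
            continue
        age = age_at(int(pat["birth_day"]), index_day)
        if not (AGE_MIN <= age <= AGE_MAX):
            # aged out between the earliest candidate and the first
            # eligibility-confirmed candidate
            rec["exclusion_reason"] = "age"
            rec["age_at_index"] = age
            records.append(rec)
            continue
        rec.update(index_day=index_day, age_at_index=age, included=True)
        records.append(rec)

    cohort = pd.DataFrame.from_records(records) if records else pd.DataFrame(
        columns=["patient_id", "index_day", "age_at_index", "included",
                 "exclusion_reason"]
    )
    cohort["included"] = cohort["included"].astype(bool)
    reasons = cohort["exclusion_reason"] if len(cohort) else pd.Series(dtype=object)
    n_excl = int((reasons == "exclusion_dx").sum())
    n_age = int((reasons == "age").sum())
    n_noidx = int((reasons == "no_index_date").sum())
    cascade.after_exclusion_dx = cascade.initial - n_excl
    cascade.after_age = cascade.after_exclusion_dx - n_age
    cascade.after_index_date = cascade.after_age - n_noidx
    return cohort, cascade
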