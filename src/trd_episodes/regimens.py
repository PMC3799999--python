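"""Regimen segmentation and line-of-therapy derivation.

Pharmacy fills of ADAP drugs (antidepressants plus antipsychotic/antimanic
agents) are first turned into per-drug validity intervals: a fill opens a
supply window, a refill within the 60-day grace period after a window ends
bridges the gap (validity runs continuously through it), and a later refill
opens a new interval.

Regimens are then maximal stretches with a constant concurrent drug set:

* A regimen, once established, is locked for 30 days; any drug becoming
  valid during the locked interim (through day start+30 inclusive) joins
  the combination retroactively, so the regimen's composition is the union
  of drugs valid during its first 30 days.
* After the lock, the regimen is re-evaluated at every prescription date
  strictly after start+30 and whenever a member drug's validity ends; a
  composition change ends the regimen at that date. A pure drop with no
  addition is a step-down.
* When all member validity expires, a successor starting within 30 days
  extends the regimen to its commencement; otherwise the regimen ends 30
  days after its validity and a blank (no-therapy) regimen spans the gap.
* Regimens are truncated at the episode end and tile the episode from the
  first regimen start.

Each non-blank regimen, in order, is one line of therapy (LOT); blank
regimens do not increment the LOT counter. Composition is tracked at the
level of individual drugs, not classes: switching drugs within a class is
a regimen change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ClaimsDataset, CodeMaps

LOCK_DAYS = 30
GRACE_DAYS = 60
BLANK_AFTER_DAYS = 30


@dataclass
class DrugExposure:
    """Grace-resolved validity intervals for one drug (half-open days)."""

    drug_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Regimen:
    ordinal: int
    drug_set: frozenset[str]
    start: int
    end: int  # exclusive
    is_blank: bool = False
    is_step_down_of_prev: bool = False
    failed: bool | None = None  # set by the TRD classifier

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class LineOfTherapy:
    lot_number: int  # 1-based
    drug_set: frozenset[str]
    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start


def validity_intervals(
    fills: Iterable[tuple[int, int]], grace: int = GRACE_DAYS
) -> list[tuple[int, int]]:
    """Merge fills (day, days_supply) into validity intervals.

    A fill at f with supply d covers [f, f+d). A fill starting no more
    than ``grace`` days after the current validity end bridges the gap;
    later fills open a new interval. Supply does not stockpile: an early
    refill extends validity to max(current end, f+d).
    """
    out: list[tuple[int, int]] = []
    for f, d in sorted(fills):
        if d < 1:
            raise ValueError(f"days_supply must be >= 1, got {d}")
        if out and f <= out[-1][1] + grace:
            out[-1] = (out[-1][0], max(out[-1][1], f + d))
        else:
            out.append((f, f + d))
    return out


def segment_regimens(
    exposures: Sequence[DrugExposure],
    ep_start: int,
    ep_end: int,
    lock: int = LOCK_DAYS,
    blank_after: int = BLANK_AFTER_DAYS,
) -> list[Regimen]:
    """Segment an episode's ADAP validity intervals into tiling regimens.

    Exposures are truncated to [ep_start, ep_end). With no ADAP exposure
    at all the whole episode is a single blank regimen; otherwise regimens
    tile [first validity start, ep_end) without overlap.
    """
    ivs: list[tuple[int, int, str]] = []
    for exp in exposures:
        for s, e in exp.intervals:
            s2, e2 = max(s, ep_start), min(e, ep_end)
            if e2 > s2:
                ivs.append((s2, e2, exp.drug_id))
    if not ivs:
        return [Regimen(0, frozenset(), ep_start, ep_end, is_blank=True)]

    starts = sorted({s for s, _, _ in ivs})
    bdays = sorted({s for s, _, _ in ivs} | {e for _, e, _ in ivs})

    def valid_at(u: int) -> frozenset[str]:
        return frozenset(d for s, e, d in ivs if s <= u < e)

    def next_boundary(u: int) -> int | None:
        for b in bdays:
            if b > u:
                return b
        return None

    def next_start_after(u: int) -> int | None:
        for s in starts:
            if s > u:
                return s
        return None

    regs: list[Regimen] = []

    def emit(drugs: frozenset[str], s: int, e: int, blank: bool = False) -> None:
        regs.append(Regimen(len(regs), drugs, s, e, is_blank=blank))

    t = starts[0]
    while t < ep_end:
        lock_hi = t + lock
        # interim combination: everything valid at any point through the
        # locked window, inclusive of a fill landing exactly on day t+lock
        comp = frozenset(d for s, e, d in ivs if s <= lock_hi and e > t)
        u = lock_hi
        while True:
            if u >= ep_end:
                emit(comp, t, ep_end)
                t = ep_end
                break
            cur = valid_at(u)
            if cur == comp:
                nb = next_boundary(u)
                u = nb if nb is not None else ep_end
                continue
            if cur:
                # composition changed while therapy continues: switch,
                # augmentation or step-down boundary at the change date
                emit(comp, t, u)
                t = u
                break
            # no member valid at u: regimen validity has expired; the
            # expiry date is the latest interval end at or before u
            v = max(e for _, e, _ in ivs if e <= u)
            f = next_start_after(u)
            if f is not None and f <= v + blank_after and f < ep_end:
                emit(comp, t, f)  # successor within 30 days: extend to it
                t = f
                break
            reg_end = min(v + blank_after, ep_end)
            emit(comp, t, reg_end)
            if reg_end >= ep_end:
                t = ep_end
            elif f is None or f >= ep_end:
                emit(frozenset(), reg_end, ep_end, blank=True)
                t = ep_end
            else:
                emit(frozenset(), reg_end, f, blank=True)
                t = f
            break

    mark_step_downs(regs)
    return regs


def is_step_down(prev: frozenset[str], nxt: frozenset[str]) -> bool:
    """True iff nxt is a non-empty proper subset of prev (one or more
    drugs discontinued, none added)."""
    return bool(nxt) and nxt < prev


def mark_step_downs(regimens: list[Regimen]) -> None:
    """Flag regimens that step down from their immediate predecessor.

    A blank regimen breaks step-down adjacency: a non-blank regimen
    following a blank is never a step-down of the therapy before the gap.
    """
    for prev, cur in zip(regimens, regimens[1:]):
        cur.is_step_down_of_prev = (
            not prev.is_blank
            and not cur.is_blank
            and is_step_down(prev.drug_set, cur.drug_set)
        )


def derive_lots(regimens: Sequence[Regimen]) -> list[LineOfTherapy]:
    """Number the non-blank regimens 1..k as lines of therapy.

    Blank regimens are skipped without incrementing the counter; a
    non-blank regimen after a blank is a new LOT even if its composition
    equals the regimen before the gap.
    """
    lots: list[LineOfTherapy] = []
    for r in regimens:
        if not r.is_blank:
            lots.append(LineOfTherapy(len(lots) + 1, r.drug_set, r.start, r.end))
    return lots


def adap_exposures_for_episode(
    fills: Iterable[tuple[int, str, int]],
    code_maps: CodeMaps,
    ep_start: int,
    ep_end: int,
    grace: int = GRACE_DAYS,
) -> list[DrugExposure]:
    """Build grace-resolved exposures from (day, drug_id, days_supply)
    fills, keeping ADAP-class drugs with fills inside [ep_start, ep_end)."""
    by_drug: dict[str, list[tuple[int, int]]] = {}
    for day, drug, supply in fills:
        if ep_start <= day < ep_end and code_maps.is_adap(drug):
            by_drug.setdefault(drug, []).append((day, supply))
    return [
        DrugExposure(d, validity_intervals(f, grace))
        for d, f in sorted(by_drug.items())
    ]


def build_all_regimens(
    ds: ClaimsDataset,
    episodes,
    lock: int = LOCK_DAYS,
    grace: int = GRACE_DAYS,
    blank_after: int = BLANK_AFTER_DAYS,
) -> dict[tuple[str, int], list[Regimen]]:
    """Segment regimens for every episode; keyed by (patient_id,
    episode_index)."""
    rx_by_pat = {p: g for p, g in ds.rx_claims.groupby("patient_id", sort=False)}
    out: dict[tuple[str, int], list[Regimen]] = {}
    for ep in episodes:
        rx = rx_by_pat.get(ep.patient_id)
        fills = (
            list(zip(rx["fill_day"].astype(int), rx["drug_id"],
                     rx["days_supply"].astype(int)))
            if rx is not None
            else []
        )
        exposures = adap_exposures_for_episode(
            fills, ds.code_maps, ep.start, ep.end, grace
        )
        out[(ep.patient_id, ep.episode_index)] = segment_regimens(
            exposures, ep.start, ep.end, lock, blank_after
        )
    return out


def regimens_frame(
    regimens_by_episode: Mapping[tuple[str, int], Sequence[Regimen]]
) -> pd.DataFrame:
    rows = []
    for (pid, epi), regs in regimens_by_episode.items():
        for r in regs:
            rows.append(
                {
                    "patient_id": pid,
                    "episode_index": epi,
                    "regimen_ordinal": r.ordinal,
                    "drug_ids": ";".join(sorted(r.drug_set)),
                    "start": r.start,
                    "end": r.end,
                    "is_blank": r.is_blank,
                    "is_step_down_of_prev": r.is_step_down_of_prev,
                    "failed": r.failed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "episode_index", "regimen_ordinal", "drug_ids",
                 "start", "end", "is_blank", "is_step_down_of_prev", "failed"],
    ).astype({"is_blank": bool, "is_step_down_of_prev": bool})


def lots_frame(
    lots_by_episode: Mapping[tuple[str, int], Sequence[LineOfTherapy]]
) -> pd.DataFrame:
    rows = []
    for (pid, epi), lots in lots_by_episode.items():
        for l in lots:
            rows.append(
                {
                    "patient_id": pid,
                    "episode_index": epi,
                    "lot_number": l.lot_number,
                    "drug_ids": ";".join(sorted(l.drug_set)),
                    "start": l.start,
                    "end": l.end,
                    "duration_days": l.duration,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "episode_index", "lot_number", "drug_ids",
                 "start", "end", "duration_days"],
    )
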