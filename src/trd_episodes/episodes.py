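"""MDD episode construction via the 120-day gap rule.

An episode begins at an inclusion diagnosis not preceded by any relevant
event (inclusion diagnosis or antidepressant fill) in the prior 120 days,
chains together relevant events separated by at most 120 days, and ends
120 days after its last relevant event. Intervals are half-open
[start, end), so every episode lasts at least 120 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import ClaimsDataset, CodeMaps

GAP_DAYS = 120


@dataclass(frozen=True)
class RelevantEvent:
    """A dated event that can belong to an episode.

    kind is "inclusion_dx" (a depressive-disorder inclusion diagnosis) or
    "ad_rx" (an antidepressant fill). Only inclusion_dx events may start
    an episode; dx events carry the diagnosis code.
    """

    day: int
    kind: str
    code: str | None = None


@dataclass
class Episode:
    patient_id: str
    episode_index: int
    start: int
    end: int  # exclusive; = last relevant event + gap
    first_dx_code: str | None = None
    treated: bool = False
    trd: bool = False
    trd_onset_day: int | None = None  # days from episode start

    @property
    def duration(self) -> int:
        return self.end - self.start


def build_episodes(
    events: Sequence[RelevantEvent], gap: int = GAP_DAYS
) -> list[Episode]:
    """Segment one patient's ordered relevant events into episodes.

    Consecutive events at most ``gap`` days apart belong to the same
    episode (a gap of exactly ``gap`` days continues it; only a full clear
    period of more than ``gap`` days breaks the chain). An episode can
    only start at an inclusion_dx event; ad_rx events not chained to a
    preceding inclusion_dx start nothing and are discarded.
    """
    episodes: list[Episode] = []
    start: int | None = None
    first_code: str | None = None
    last: int | None = None
    for ev in sorted(events, key=lambda e: (e.day, e.kind)):
        if start is not None and ev.day - last <= gap:
            last = max(last, ev.day)
            continue
        if start is not None:
            episodes.append(
                Episode("", len(episodes), start, last + gap, first_code)
            )
            start = None
        if ev.kind == "inclusion_dx":
            start, last, first_code = ev.day, ev.day, ev.code
    if start is not None:
        episodes.append(Episode("", len(episodes), start, last + gap, first_code))
    return episodes


def label_treated(
    episode: Episode, rx_fills: Iterable[tuple[int, str]], code_maps: CodeMaps
) -> Episode:
    """Set treated = True iff at least one ADAP-class fill falls in
    [start, end)."""
    episode.treated = any(
        episode.start <= day < episode.end and code_maps.is_adap(drug)
        for day, drug in rx_fills
    )
    return episode


def build_all_episodes(
    ds: ClaimsDataset, cohort: pd.DataFrame, gap: int = GAP_DAYS
) -> list[Episode]:
    """Build and treatment-label episodes for every included patient.

    Episodes are constructed from each patient's Index Diagnosis Date
    forward; earlier claims never contribute events (the index date is by
    definition washout-clean).
    """
    cm = ds.code_maps
    included = cohort[cohort["included"]]
    index_by_pat = dict(zip(included["patient_id"], included["index_day"]))

    dx_by_pat = {p: g for p, g in ds.dx_claims.groupby("patient_id", sort=False)}
    rx_by_pat = {p: g for p, g in ds.rx_claims.groupby("patient_id", sort=False)}

    out: list[Episode] = []
    for pid, index_day in index_by_pat.items():
        index_day = int(index_day)
        events: list[RelevantEvent] = []
        dx = dx_by_pat.get(pid)
        if dx is not None:
            for day, code in zip(dx["service_day"], dx["dx_code"]):
                if day >= index_day and cm.is_inclusion(code):
                    events.append(RelevantEvent(int(day), "inclusion_dx", code))
        rx = rx_by_pat.get(pid)
        fills: list[tuple[int, str]] = []
        if rx is not None:
            fills = [(int(d), str(g)) for d, g in zip(rx["fill_day"], rx["drug_id"])]
            for day, drug in fills:
                if day >= index_day and cm.is_antidepressant(drug):
                    events.append(RelevantEvent(day, "ad_rx"))
        for ep in build_episodes(events, gap):
            ep.patient_id = pid
            label_treated(ep, fills, cm)
            out.append(ep)
    return out


def episodes_frame(episodes: list[Episode]) -> pd.DataFrame:
    """Tabular view of episodes (one row each)."""
    return pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "episode_index": e.episode_index,
                "start": e.start,
                "end": e.end,
                "duration_days": e.duration,
                "first_dx_code": e.first_dx_code,
                "treated": e.treated,
                "trd": e.trd,
                "trd_onset_day": e.trd_onset_day,
            }
            for e in episodes
        ],
        columns=[
            "patient_id", "episode_index", "start", "end", "duration_days",
            "first_dx_code", "treated", "trd", "trd_onset_day",
        ],
    ).astype({"treated": bool, "trd": bool})
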