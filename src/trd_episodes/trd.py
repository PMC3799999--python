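"""Treatment-resistant depression classification.

Every non-blank regimen in an episode counts as a failure (a treatment
switch or discontinuation) except:

a) the last regimen of the episode, and
b) any regimen whose composition is, anywhere in the episode, immediately
   succeeded by a step-down regimen (one or more drugs discontinued and
   none added) -- that composition is exempt in *all* its instances.

An episode is TRD iff it contains at least two distinct failed regimen
compositions (repeated failures of the same drug set count once); by
construction a TRD episode always has at least three lines of therapy.
The TRD onset is the commencement of the regimen that confirms the second
distinct composition as failed -- a failure only becomes knowable at the
switch or discontinuation that follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .episodes import Episode
from .regimens import Regimen, is_step_down

MIN_DISTINCT_FAILURES = 2


@dataclass
class FailureAssessment:
    failed: list[bool] = field(default_factory=list)  # parallel to regimens
    distinct_failed_compositions: set[frozenset[str]] = field(default_factory=set)
    trd: bool = False
    trd_onset: int | None = None  # absolute day offset


def assess_failures(
    regimens: Sequence[Regimen],
    composition_wide_exemption: bool = True,
    min_distinct_failures: int = MIN_DISTINCT_FAILURES,
) -> FailureAssessment:
    """Assign per-regimen failure flags and classify the episode.

    With ``composition_wide_exemption`` (the default) a composition ever
    followed by a step-down is exempt in all its instances; the
    alternative exempts only the specific instances directly followed by
    a step-down. Blank regimens are never failures; a regimen followed by
    a blank gap and then further treatment is a failure (discontinuation),
    while therapy tapering out through the episode end is covered by the
    last-regimen exemption. Failure flags are also written back onto the
    regimen objects.
    """
    out = FailureAssessment(failed=[False] * len(regimens))
    nonblank_idx = [i for i, r in enumerate(regimens) if not r.is_blank]
    if not nonblank_idx:
        return out

    stepped_down = {
        regimens[i].drug_set
        for i, j in zip(nonblank_idx, nonblank_idx[1:])
        if j == i + 1 and is_step_down(regimens[i].drug_set, regimens[j].drug_set)
    }

    last_nb = nonblank_idx[-1]
    for pos, i in enumerate(nonblank_idx):
        if i == last_nb:
            continue
        if composition_wide_exemption:
            exempt = regimens[i].drug_set in stepped_down
        else:
            j = nonblank_idx[pos + 1]
            exempt = j == i + 1 and is_step_down(
                regimens[i].drug_set, regimens[j].drug_set
            )
        out.failed[i] = not exempt

    for i, r in enumerate(regimens):
        r.failed = out.failed[i]

    out.distinct_failed_compositions = {
        regimens[i].drug_set for i in nonblank_idx if out.failed[i]
    }
    out.trd = classify_trd(out, min_distinct_failures)
    if out.trd:
        seen: set[frozenset[str]] = set()
        for i in nonblank_idx:
            if not out.failed[i]:
                continue
            seen.add(regimens[i].drug_set)
            if len(seen) >= min_distinct_failures:
                # the failure is confirmed when the successor commences
                out.trd_onset = regimens[i + 1].start
                break
    return out


def classify_trd(
    assessment: FailureAssessment,
    min_distinct_failures: int = MIN_DISTINCT_FAILURES,
) -> bool:
    """TRD iff the episode holds at least ``min_distinct_failures``
    distinct failed drug-set compositions."""
    return len(assessment.distinct_failed_compositions) >= min_distinct_failures


def time_to_trd(
    episode: Episode, assessment: FailureAssessment
) -> int | None:
    """Days from episode start to TRD onset; None for non-TRD episodes."""
    if not assessment.trd or assessment.trd_onset is None:
        return None
    return assessment.trd_onset - episode.start


def label_episodes(
    episodes: Sequence[Episode],
    regimens_by_episode,
    composition_wide_exemption: bool = True,
    min_distinct_failures: int = MIN_DISTINCT_FAILURES,
) -> dict[tuple[str, int], FailureAssessment]:
    """Run failure assessment over all episodes, writing trd flags and
    onset (days from episode start) back onto the Episode objects."""
    assessments = {}
    for ep in episodes:
        regs = regimens_by_episode[(ep.patient_id, ep.episode_index)]
        a = assess_failures(regs, composition_wide_exemption, min_distinct_failures)
        ep.trd = a.trd
        ep.trd_onset_day = time_to_trd(ep, a)
        assessments[(ep.patient_id, ep.episode_index)] = a
    return assessments


def trd_patients(episodes: Sequence[Episode]) -> set[str]:
    """A patient is a TRD patient iff at least one of their episodes is
    TRD."""
    return {e.patient_id for e in episodes if e.trd}
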