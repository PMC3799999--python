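"""Failure flags, TRD classification and time to TRD."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trd_episodes.episodes import Episode
from trd_episodes.regimens import Regimen, derive_lots, mark_step_downs
from trd_episodes.trd import (
    assess_failures,
    classify_trd,
    time_to_trd,
    trd_patients,
)


def make_regimens(seq):
    """seq: list of (drugs-string-or-tuple, start, end); '' means blank."""
    regs = []
    for i, (drugs, a, b) in enumerate(seq):
        ds = frozenset(drugs) if drugs else frozenset()
        regs.append(Regimen(i, ds, a, b, is_blank=not ds))
    mark_step_downs(regs)
    return regs


class TestFailureRules:
    def test_two_switches_make_trd(self):
        regs = make_regimens([("A", 0, 70), ("B", 70, 140), ("C", 140, 260)])
        a = assess_failures(regs)
        assert [r.failed for r in regs] == [True, True, False]
        assert a.distinct_failed_compositions == {frozenset("A"), frozenset("B")}
        assert a.trd

    def test_step_down_exempts_composition(self):
        regs = make_regimens([("A", 0, 60), ("AB", 60, 120), ("A", 120, 200)])
        a = assess_failures(regs)
        # {A,B} is exempt via its step-down; final {A} is the last regimen
        assert [r.failed for r in regs] == [True, False, False]
        assert len(a.distinct_failed_compositions) == 1
        assert not a.trd
        assert len(derive_lots(regs)) == 3

    def test_single_regimen_never_fails(self):
        regs = make_regimens([("A", 0, 120)])
        a = assess_failures(regs)
        assert not any(r.failed for r in regs)
        assert not a.trd

    def test_repeated_composition_counts_once(self):
        regs = make_regimens(
            [("A", 0, 60), ("", 60, 100), ("A", 100, 160), ("", 160, 200),
             ("A", 200, 260)]
        )
        a = assess_failures(regs)
        # both early {A} instances fail (discontinued, then more treatment)
        assert [r.failed for r in regs] == [True, False, True, False, False]
        assert len(a.distinct_failed_compositions) == 1
        assert not a.trd

    def test_blank_to_episode_end_leaves_last_regimen_exempt(self):
        regs = make_regimens([("A", 0, 60), ("B", 60, 120), ("", 120, 260)])
        a = assess_failures(regs)
        assert [r.failed for r in regs] == [True, False, False]
        assert not a.trd

    def test_exemption_is_composition_wide_by_default(self):
        # {A,B} steps down once; its later instance ends in a switch
        seq = [("AB", 0, 60), ("A", 60, 120), ("AB", 120, 180), ("Z", 180, 260)]
        wide = make_regimens(seq)
        a_wide = assess_failures(wide)
        assert [r.failed for r in wide] == [False, True, False, False]
        assert not a_wide.trd
        local = make_regimens(seq)
        a_local = assess_failures(local, composition_wide_exemption=False)
        assert [r.failed for r in local] == [False, True, True, False]
        assert a_local.trd

    def test_non_adjacent_distinct_failures_count(self):
        # failures need not be consecutive
        regs = make_regimens(
            [("A", 0, 60), ("AB", 60, 120), ("A", 120, 180), ("B", 180, 240),
             ("C", 240, 330)]
        )
        a = assess_failures(regs)
        # {A,B} exempt; {A} (both), {B} fail -> 2 distinct
        assert a.trd


class TestTimeToTrd:
    def test_onset_is_confirming_successor_start(self):
        regs = make_regimens([("A", 0, 70), ("B", 70, 140), ("C", 140, 260)])
        a = assess_failures(regs)
        ep = Episode("P", 0, 0, 260)
        assert a.trd_onset == 140
        assert time_to_trd(ep, a) == 140

    def test_none_for_non_trd(self):
        regs = make_regimens([("A", 0, 120)])
        a = assess_failures(regs)
        assert time_to_trd(Episode("P", 0, 0, 120), a) is None

    def test_second_distinct_failure_with_combination(self):
        # {A},{B},{A,C},{D}: {B}'s failure is confirmed at day 90 when
        # {A,C} commences, which is already the second distinct failure
        regs = make_regimens(
            [("A", 0, 40), ("B", 40, 90), ("AC", 90, 150), ("D", 150, 260)]
        )
        a = assess_failures(regs)
        assert a.distinct_failed_compositions == {
            frozenset("A"), frozenset("B"), frozenset("AC")
        }
        assert a.trd_onset == 90

    def test_onset_skips_exempt_compositions(self):
        # {X,Y} steps down so only {X} and {Z} fail; the second distinct
        # failure is confirmed when the last regimen starts
        regs = make_regimens(
            [("X", 0, 60), ("XY", 60, 120), ("X", 120, 180), ("Z", 180, 240),
             ("W", 240, 330)]
        )
        a = assess_failures(regs)
        assert a.distinct_failed_compositions == {frozenset("X"), frozenset("Z")}
        assert a.trd_onset == 240


def test_trd_patient_labelling():
    eps = [Episode("P1", 0, 0, 200, trd=True), Episode("P1", 1, 300, 500),
           Episode("P2", 0, 0, 200)]
    assert trd_patients(eps) == {"P1"}


comp_strategy = st.lists(
    st.sampled_from(["A", "B", "C", "AB", "AC", "BC", "ABC", ""]),
    min_size=1, max_size=8,
)


@settings(max_examples=300, derandomize=True)
@given(comp_strategy)
def test_trd_implies_at_least_three_lots(comps):
    regs = []
    day = 0
    for i, c in enumerate(comps):
        regs.append(Regimen(i, frozenset(c), day, day + 50, is_blank=not c))
        day += 50
    mark_step_downs(regs)
    a = assess_failures(regs)
    if a.trd:
        assert len(derive_lots(regs)) >= 3


@settings(max_examples=300, derandomize=True)
@given(comp_strategy)
def test_appending_failures_never_unmakes_trd(comps):
    """Adding a fresh distinct composition terminated by a switch keeps a
    TRD episode TRD."""
    regs = []
    day = 0
    for i, c in enumerate(comps):
        regs.append(Regimen(i, frozenset(c), day, day + 50, is_blank=not c))
        day += 50
    mark_step_downs(regs)
    base = assess_failures(make_regimens([(c, i * 50, i * 50 + 50)
                                          for i, c in enumerate(comps)]))
    if not base.trd:
        return
    extended = comps + ["D", "E"]
    regs2 = make_regimens([(c, i * 50, i * 50 + 50)
                           for i, c in enumerate(extended)])
    assert assess_failures(regs2).trd
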