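"""Validity intervals, regimen segmentation and lines of therapy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trd_episodes.regimens import (
    DrugExposure,
    Regimen,
    derive_lots,
    is_step_down,
    mark_step_downs,
    segment_regimens,
    validity_intervals,
)

from _oracle import oracle_segment, random_fill_case


def seg(exposures, start, end, **kw):
    regs = segment_regimens(
        [DrugExposure(d, ivs) for d, ivs in exposures.items()], start, end, **kw
    )
    return [(set(r.drug_set), r.start, r.end, r.is_blank) for r in regs]


class TestValidityIntervals:
    def test_refill_within_grace_bridges(self):
        # day-45 refill is within 30+60, validity runs through to 75
        assert validity_intervals([(0, 30), (45, 30)]) == [(0, 75)]

    def test_refill_beyond_grace_opens_new_interval(self):
        assert validity_intervals([(0, 30), (100, 30)]) == [(0, 30), (100, 130)]

    def test_exact_grace_boundary(self):
        assert validity_intervals([(0, 30), (90, 30)]) == [(0, 120)]
        assert validity_intervals([(0, 30), (91, 30)]) == [(0, 30), (91, 121)]

    def test_single_fill(self):
        assert validity_intervals([(0, 30)]) == [(0, 30)]

    def test_early_refill_does_not_stockpile(self):
        assert validity_intervals([(0, 30), (10, 30)]) == [(0, 40)]

    def test_zero_supply_rejected(self):
        with pytest.raises(ValueError):
            validity_intervals([(0, 0)])


class TestSegmentation:
    def test_lock_augment_stepdown_blank_trace(self):
        """Combination joins at the first fill after the 30-day lock, the
        partner's validity end produces a step-down, and therapy running
        out opens a blank regimen 30 days after validity."""
        exposures = {
            "A": validity_intervals([(0, 30), (30, 30), (60, 30)]),
            "B": validity_intervals([(45, 30)]),
        }
        assert seg(exposures, 0, 300) == [
            ({"A"}, 0, 45, False),
            ({"A", "B"}, 45, 75, False),
            ({"A"}, 75, 120, False),
            (set(), 120, 300, True),
        ]

    def test_interim_combination_joins_from_start(self):
        # B filled on day 10 is within A's locked interim: one combination
        # regimen from day 0
        exposures = {"A": [(0, 30)], "B": [(10, 40)]}
        out = seg(exposures, 0, 160)
        assert out[0] == ({"A", "B"}, 0, 30, False)

    def test_fill_exactly_at_lock_end_joins_combination(self):
        exposures = {"A": [(0, 90)], "B": [(30, 60)]}
        assert seg(exposures, 0, 200)[0][0] == {"A", "B"}
        # one day later it is a new regimen boundary instead
        exposures = {"A": [(0, 90)], "B": [(31, 61)]}
        out = seg(exposures, 0, 200)
        assert out[0] == ({"A"}, 0, 31, False)
        assert out[1][0] == {"A", "B"}

    def test_no_fills_single_blank(self):
        assert seg({}, 0, 250) == [(set(), 0, 250, True)]

    def test_successor_within_30_days_extends_previous(self):
        exposures = {"A": [(0, 60)], "B": [(80, 110)]}
        # A's validity ends day 60; B commences day 80 <= 90: A's regimen
        # extends to 80, no blank
        assert seg(exposures, 0, 300) == [
            ({"A"}, 0, 80, False),
            ({"B"}, 80, 140, False),
            (set(), 140, 300, True),
        ]

    def test_successor_beyond_30_days_opens_blank(self):
        exposures = {"A": [(0, 60)], "B": [(100, 130)]}
        assert seg(exposures, 0, 300) == [
            ({"A"}, 0, 90, False),
            (set(), 90, 100, True),
            ({"B"}, 100, 160, False),
            (set(), 160, 300, True),
        ]

    def test_truncation_at_episode_end(self):
        exposures = {"A": [(0, 500)]}
        assert seg(exposures, 0, 200) == [({"A"}, 0, 200, False)]


class TestStepDown:
    def test_proper_subset(self):
        assert is_step_down(frozenset("AB"), frozenset("A"))

    def test_addition_is_not(self):
        assert not is_step_down(frozenset("A"), frozenset("AB"))

    def test_swap_is_not(self):
        assert not is_step_down(frozenset("AB"), frozenset("AC"))

    def test_equal_or_empty_is_not(self):
        assert not is_step_down(frozenset("A"), frozenset("A"))
        assert not is_step_down(frozenset("A"), frozenset())

    def test_blank_breaks_adjacency(self):
        regs = [
            Regimen(0, frozenset("AB"), 0, 60),
            Regimen(1, frozenset(), 60, 100, is_blank=True),
            Regimen(2, frozenset("A"), 100, 160),
        ]
        mark_step_downs(regs)
        assert not regs[2].is_step_down_of_prev


class TestLots:
    def test_blanks_skipped(self):
        regs = [
            Regimen(0, frozenset("A"), 0, 60),
            Regimen(1, frozenset("AB"), 60, 120),
            Regimen(2, frozenset("A"), 120, 180),
            Regimen(3, frozenset(), 180, 300, is_blank=True),
        ]
        lots = derive_lots(regs)
        assert [l.lot_number for l in lots] == [1, 2, 3]

    def test_same_composition_after_blank_is_new_lot(self):
        regs = [
            Regimen(0, frozenset("A"), 0, 90),
            Regimen(1, frozenset(), 90, 140, is_blank=True),
            Regimen(2, frozenset("A"), 140, 200),
        ]
        assert [l.lot_number for l in derive_lots(regs)] == [1, 2]

    def test_blank_only_episode_has_no_lots(self):
        assert derive_lots([Regimen(0, frozenset(), 0, 200, is_blank=True)]) == []


def _engine_vs_oracle(rng, n_cases):
    for _ in range(n_cases):
        fills, s0, e0 = random_fill_case(rng)
        by_drug = {}
        for d, drug, sup in fills:
            by_drug.setdefault(drug, []).append((d, sup))
        exposures = {drug: validity_intervals(f) for drug, f in by_drug.items()}
        engine = segment_regimens(
            [DrugExposure(d, iv) for d, iv in exposures.items()], s0, e0
        )
        eng = [(r.drug_set, r.start, r.end, r.is_blank) for r in engine]
        assert eng == oracle_segment(exposures, s0, e0), fills
        yield engine, s0, e0


def test_engine_matches_day_by_day_oracle():
    rng = np.random.default_rng(2024)
    for _ in _engine_vs_oracle(rng, 300):
        pass


def test_structural_invariants_on_random_cases():
    rng = np.random.default_rng(7)
    for regs, s0, e0 in _engine_vs_oracle(rng, 200):
        # tiling: regimens cover [first start, episode end) without gaps
        assert regs[-1].end == e0
        for a, b in zip(regs, regs[1:]):
            assert a.end == b.start
            if not a.is_blank and not b.is_blank:
                assert a.drug_set != b.drug_set
        for r in regs:
            assert r.end > r.start
            if not r.is_blank and r.end < e0:
                assert r.duration >= 30  # only episode-end truncation may cut


def test_determinism_under_fill_row_shuffle():
    rng = np.random.default_rng(55)
    for _ in range(50):
        fills, s0, e0 = random_fill_case(rng)
        perm = list(fills)
        rng.shuffle(perm)

        def run(fs):
            by_drug = {}
            for d, drug, sup in fs:
                by_drug.setdefault(drug, []).append((d, sup))
            return seg(
                {drug: validity_intervals(f) for drug, f in by_drug.items()},
                s0, e0,
            )

        assert run(fills) == run(perm)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 200), st.sampled_from("ABC"),
                  st.integers(1, 60)),
        min_size=1, max_size=6,
    )
)
def test_engine_matches_oracle_property(fills):
    by_drug = {}
    for d, drug, sup in fills:
        by_drug.setdefault(drug, []).append((d, sup))
    exposures = {drug: validity_intervals(f) for drug, f in by_drug.items()}
    engine = segment_regimens(
        [DrugExposure(d, iv) for d, iv in exposures.items()], 0, 280
    )
    eng = [(r.drug_set, r.start, r.end, r.is_blank) for r in engine]
    assert eng == oracle_segment(exposures, 0, 280)
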