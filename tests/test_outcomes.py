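"""Comparison surfaces: group summaries, usage shares, comorbidity, MRU."""

import numpy as np
import pandas as pd
import pytest

from trd_episodes.outcomes import (
    class_usage_share,
    comorbidity_profile,
    lot_distribution,
    mru_summary,
    regimen_mix,
    summarize_groups,
    trd_rates,
)
from trd_episodes.simulate import default_code_maps

CM = default_code_maps()


def episodes_df(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "episode_index", "start", "end",
                 "duration_days", "treated", "trd", "trd_onset_day"],
    )


def regimens_df(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "episode_index", "regimen_ordinal", "drug_ids",
                 "start", "end", "is_blank"],
    )


class TestTrdRates:
    def test_headline_rate_from_printed_counts(self):
        rate, _ = trd_rates(3134, 47654)
        assert round(rate, 1) == 6.6

    def test_prevalence_from_rounded_means(self):
        rate, prev = trd_rates(3134, 47654, 1004, 44520, 452)
        assert round(prev, 1) == 13.5

    def test_zero_trd(self):
        assert trd_rates(0, 100, None, 100, None) == (0.0, 0.0)

    def test_zero_denominator_flagged(self):
        rate, prev = trd_rates(5, 0)
        assert np.isnan(rate) and np.isnan(prev)


class TestGroupSummaries:
    def _fixture(self):
        eps = episodes_df([
            ("T1", 0, 0, 900, 900, True, True, 400),
            ("T2", 0, 0, 700, 700, True, True, 300),
            ("N1", 0, 0, 300, 300, True, False, None),
            ("N2", 0, 0, 500, 500, True, False, None),
            ("U1", 0, 0, 200, 200, False, False, None),  # untreated: excluded
        ])
        pats = pd.DataFrame({
            "patient_id": ["T1", "T2", "N1", "N2", "U1"],
            "sex": ["F", "M", "F", "F", "M"],
            "age_at_index": [30, 40, 52, 20, 45],
        })
        return eps, pats

    def test_means_and_medians_match_brute_force(self):
        eps, pats = self._fixture()
        g = summarize_groups(eps, pats)
        assert g["TRD"]["n_episodes"] == 2
        assert g["TRD"]["duration_mean"] == pytest.approx(800.0)
        assert g["TRD"]["duration_median"] == pytest.approx(800.0)
        assert g["nonTRD"]["duration_mean"] == pytest.approx(400.0)
        assert g["TRD"]["female_n"] == 1
        assert g["nonTRD"]["female_share"] == pytest.approx(1.0)
        assert g["nonTRD"]["age_51_64_n"] == 1
        assert g["TRD"]["days_to_trd_mean"] == pytest.approx(350.0)

    def test_single_episode_mean_equals_median(self):
        eps = episodes_df([("A", 0, 0, 400, 400, True, True, 100),
                           ("B", 0, 0, 250, 250, True, False, None)])
        pats = pd.DataFrame({"patient_id": ["A", "B"], "sex": ["F", "F"],
                             "age_at_index": [30, 30]})
        g = summarize_groups(eps, pats)
        assert g["TRD"]["duration_mean"] == g["TRD"]["duration_median"] == 400


def test_lot_distribution_bins_and_excludes_untreated():
    eps = episodes_df([
        ("A", 0, 0, 400, 400, True, False, None),
        ("U", 0, 0, 400, 400, False, False, None),
    ])
    lots = pd.DataFrame({
        "patient_id": ["A", "A"], "episode_index": [0, 0],
        "lot_number": [1, 2], "duration_days": [100, 60],
        "start": [0, 100], "end": [100, 160], "drug_ids": ["x", "y"],
    })
    hist, summary = lot_distribution(eps, lots)
    assert hist.to_dict(orient="records") == [
        {"group": "nonTRD", "n_lots": 2, "n_episodes": 1}
    ]
    assert set(summary["lot_number"]) == {1, 2}


class TestClassUsage:
    def test_half_episode_on_ssri(self):
        eps = episodes_df([("A", 0, 0, 200, 200, True, False, None)])
        regs = regimens_df([
            ("A", 0, 0, "ssri_sertraline", 0, 100, False),
            ("A", 0, 1, "", 100, 200, True),
        ])
        out = class_usage_share(eps, regs, CM).set_index("drug_class")
        assert out.loc["SSRI", "share_nonTRD"] == pytest.approx(0.5)
        assert out.loc["SNRI", "share_nonTRD"] == pytest.approx(0.0)

    def test_combination_shares_overlap(self):
        eps = episodes_df([("A", 0, 0, 100, 100, True, False, None)])
        regs = regimens_df([
            ("A", 0, 0, "ssri_sertraline;ap_quetiapine", 0, 100, False),
        ])
        out = class_usage_share(eps, regs, CM).set_index("drug_class")
        assert out.loc["SSRI", "share_nonTRD"] == pytest.approx(1.0)
        assert out.loc["AP", "share_nonTRD"] == pytest.approx(1.0)


def test_regimen_mix_labels_and_mono_share():
    eps = episodes_df([("A", 0, 0, 400, 400, True, False, None)])
    regs = regimens_df([
        ("A", 0, 0, "ssri_sertraline", 0, 100, False),
        ("A", 0, 1, "ssri_sertraline;ap_quetiapine", 100, 200, False),
        ("A", 0, 2, "", 200, 400, True),
    ])
    mono, by_lot = regimen_mix(eps, regs, CM)
    m = mono.set_index("group").loc["nonTRD"]
    assert m["monotherapy_share"] == pytest.approx(0.5)
    lot2 = by_lot[(by_lot["lot_number"] == 2)]
    assert list(lot2["label"]) == ["AP & SSRI"]


def test_comorbidity_patient_level_counted_once():
    dx = pd.DataFrame({
        "patient_id": ["T", "T", "N"],
        "service_day": [10, 20, 10],
        "dx_code": ["300.0", "300.0", "719.4"],
    })
    out = comorbidity_profile({"T"}, {"N"}, dx, CM.comorbidity_groups)
    out = out.set_index("comorbidity")
    assert out.loc["anxiety_panic", "pct_TRD"] == pytest.approx(100.0)
    assert out.loc["anxiety_panic", "pct_nonTRD"] == pytest.approx(0.0)
    assert out.loc["muscle_joint_pain", "pct_nonTRD"] == pytest.approx(100.0)


class TestMru:
    def test_basic_arithmetic(self):
        # 3 visits, $300 paid, one 300-day episode -> B=1.0, C=100, D=300
        eps = episodes_df([("A", 0, 0, 300, 300, True, False, None)])
        dx = pd.DataFrame({
            "patient_id": ["A"] * 3, "service_day": [10, 50, 100],
            "dx_code": ["V70.0"] * 3, "setting": ["office_gp"] * 3,
            "paid_amount": [100.0, 100.0, 100.0],
        })
        rx = pd.DataFrame(columns=["patient_id", "fill_day", "drug_id",
                                   "days_supply", "paid_amount"])
        table, extras = mru_summary(eps, dx, rx, CM)
        row = table.set_index("category").loc["office_gp"]
        assert row["A_nonTRD"] == pytest.approx(300.0)
        assert row["B_nonTRD"] == pytest.approx(1.0)
        assert row["C_nonTRD"] == pytest.approx(100.0)
        assert row["D_nonTRD"] == pytest.approx(300.0)
        # identity D = A * (B/100) * C holds exactly pre-rounding
        assert row["D_nonTRD"] == pytest.approx(
            row["A_nonTRD"] * row["B_nonTRD"] / 100 * row["C_nonTRD"]
        )

    def test_out_of_episode_claims_go_to_residual_and_costs_conserve(self):
        eps = episodes_df([("A", 0, 0, 100, 100, True, False, None)])
        dx = pd.DataFrame({
            "patient_id": ["A", "A"], "service_day": [50, 500],
            "dx_code": ["V70.0", "V70.0"], "setting": ["lab", "lab"],
            "paid_amount": [40.0, 60.0],
        })
        rx = pd.DataFrame({
            "patient_id": ["A"], "fill_day": [20], "drug_id": ["x"],
            "days_supply": [30], "paid_amount": [12.0],
        })
        table, extras = mru_summary(eps, dx, rx, CM)
        assert extras["residual"] == {"n_claims": 1, "paid": 60.0}
        in_ep = extras["per_episode"]["paid"].sum()
        assert in_ep + extras["residual"]["paid"] == pytest.approx(
            extras["total_input_paid"]
        )

    def test_cost_multiple(self):
        eps = episodes_df([
            ("T", 0, 0, 100, 100, True, True, 50),
            ("N", 0, 0, 100, 100, True, False, None),
        ])
        dx = pd.DataFrame({
            "patient_id": ["T", "N"], "service_day": [10, 10],
            "dx_code": ["786.50"] * 2, "setting": ["inpatient"] * 2,
            "paid_amount": [6000.0, 2000.0],
        })
        rx = pd.DataFrame(columns=["patient_id", "fill_day", "drug_id",
                                   "days_supply", "paid_amount"])
        table, _ = mru_summary(eps, dx, rx, CM)
        row = table.set_index("category").loc["hospitalization"]
        assert row["multiple"] == pytest.approx(3.0)
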