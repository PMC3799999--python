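"""Seeded synthetic claims generator with ground-truth labels.

The generator emulates the statistical structure a claims-based episode
analysis assumes: per-patient streams of depressive-disorder diagnoses and
pharmacy fills with a 30-day-dominant days supply, a majority of untreated
episodes, single-line responders, augment-then-step-down trajectories, and
multi-line treatment-resistant trajectories in which at least two distinct
regimens are each terminated by a switch. It also plants comorbidity
claims and resource-utilization events with group-specific rates and
costs, and emits the intended episode boundaries, line counts and TRD
labels so recovery tests can compare pipeline output against ground truth.

Within-patient refill gaps are bridgeable by default (the 60-day grace
covers them); a configurable fraction of gaps falls in the breaking range,
which legitimately inserts a blank regimen and an extra line of therapy.
The ground truth accounts for every break it deals, so intended line
counts and TRD flags remain exact; only the TRD onset day can drift when
a break lands inside a later treatment line.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import ClaimsDataset, CodeMaps

# --------------------------------------------------------------------------
# default catalog and code maps

DRUG_CATALOG: dict[str, str] = {
    "ssri_sertraline": "SSRI",
    "ssri_fluoxetine": "SSRI",
    "ssri_escitalopram": "SSRI",
    "ssri_citalopram": "SSRI",
    "snri_venlafaxine": "SNRI",
    "snri_duloxetine": "SNRI",
    "atyp_bupropion": "ATYPICAL_AD",
    "atyp_vilazodone": "ATYPICAL_AD",
    "oth_mirtazapine": "AD_OTHERS",
    "oth_amitriptyline": "AD_OTHERS",
    "maoi_phenelzine": "MAOI",
    "maoi_tranylcypromine": "MAOI",
    "ap_risperidone": "AP",
    "ap_quetiapine": "AP",
    "li_carbonate": "LITHIUM",
    "li_citrate": "LITHIUM",
    "non_zolpidem": "OTHER_NON_ADAP",
    "non_alprazolam": "OTHER_NON_ADAP",
}

INCLUSION_DX = ("296.2", "296.3", "300.4", "309.1", "311")
EXCLUSION_DX = (
    "295", "296.0", "296.1", "296.4", "296.5", "296.6", "296.7",
    "296.8", "296.9", "298",
)
COMORBIDITY_GROUPS: dict[str, tuple[str, ...]] = {
    "muscle_joint_pain": ("719.4", "729.1"),
    "anxiety_panic": ("300.0", "300.2"),
    "fatigue": ("780.7",),
    "headache_migraine": ("784.0", "346"),
    "sleep_disorder": ("780.5", "307.4"),
    "back_pain": ("724.2", "724.5"),
    "obesity_weight_gain": ("278.0",),
}
MRU_SETTING_MAP: dict[str, str] = {
    "inpatient": "hospitalization",
    "office_gp": "office_gp",
    "office_psych": "office_psych",
    "er": "er",
    "lab": "lab",
    "outpatient": "other_outpatient",
    "psychotherapy": "psychotherapy",
}
#: generic (non-inclusion, non-exclusion, non-comorbidity) dx codes used
#: on utilization claims, per setting
MRU_DX_CODE = {
    "inpatient": "786.50",
    "office_gp": "V70.0",
    "office_psych": "V79.0",
    "er": "789.00",
    "lab": "790.6",
    "outpatient": "V58.69",
    "psychotherapy": "V79.0",
}


def default_code_maps() -> CodeMaps:
    """Code maps matching the synthetic drug catalog and code groups."""
    return CodeMaps(
        inclusion_dx=frozenset(INCLUSION_DX),
        exclusion_dx=frozenset(EXCLUSION_DX),
        drug_class=dict(DRUG_CATALOG),
        comorbidity_groups={g: frozenset(v) for g, v in COMORBIDITY_GROUPS.items()},
        mru_categories=dict(MRU_SETTING_MAP),
    )


# --------------------------------------------------------------------------
# scenario

class Scenario(BaseModel):
    """Study conditions for one synthetic cohort.

    Defaults follow the population-level frequencies the analysis targets:
    68% female, 62% of episodes untreated, ~6.6% of treated episodes
    TRD-like, 80% of fills with a 30-day supply, comorbidity rates and
    per-category utilization rates/costs of the magnitudes seen in
    commercially insured MDD cohorts.
    """

    n_patients: int = Field(500, ge=1)
    seed: int = 0
    female_share: float = Field(0.68, ge=0, le=1)
    age_band_probs: tuple[float, float, float] = (0.30, 0.41, 0.29)
    trajectory_mix: dict[str, float] = {
        "untreated": 0.62,
        "single_lot_responder": 0.255,
        "multi_lot_non_trd": 0.10,
        "trd_like": 0.025,
    }
    excluded_dx_share: float = Field(0.04, ge=0, le=1)
    underage_share: float = Field(0.03, ge=0, le=1)
    no_index_share: float = Field(0.03, ge=0, le=1)
    second_episode_prob: float = Field(0.15, ge=0, le=1)
    days_supply_30_share: float = Field(0.8, ge=0, le=1)
    alt_days_supply: tuple[int, ...] = (15, 60, 90)
    #: probability that a refill gap lands in the non-bridgeable range,
    #: inserting a blank regimen and an extra line
    breaking_gap_prob: float = Field(0.0, ge=0, le=0.5)
    only_index_dx_share: float = Field(0.68, ge=0, le=1)
    trd_like_lines: dict[int, float] = {3: 0.35, 4: 0.40, 5: 0.25}
    combo_line_prob: float = Field(0.35, ge=0, le=1)
    comorbidity_rates: dict[str, tuple[float, float]] = {  # (TRD, non-TRD)
        "muscle_joint_pain": (0.61, 0.36),
        "anxiety_panic": (0.50, 0.29),
        "fatigue": (0.43, 0.23),
        "headache_migraine": (0.35, 0.17),
        "sleep_disorder": (0.34, 0.17),
        "back_pain": (0.25, 0.12),
        "obesity_weight_gain": (0.19, 0.10),
    }
    #: per category: (TRD rate / 100 days, non-TRD rate / 100 days,
    #: median insurer-paid cost per visit in USD)
    mru_rates: dict[str, tuple[float, float, float]] = {
        "inpatient": (0.06, 0.04, 11000.0),
        "office_gp": (0.81, 0.71, 59.0),
        "office_psych": (0.73, 0.33, 71.0),
        "er": (0.13, 0.09, 450.0),
        "lab": (0.87, 0.71, 70.0),
        "outpatient": (2.04, 1.66, 325.0),
        "psychotherapy": (1.60, 0.90, 80.0),
    }
    adap_fill_cost_median: float = Field(90.0, gt=0)
    other_rx_rate_per_100d: float = Field(0.5, ge=0)

    @field_validator("trajectory_mix")
    @classmethod
    def _mix_sums_to_one(cls, v):
        if abs(sum(v.values()) - 1.0) > 1e-9 or any(p < 0 for p in v.values()):
            raise ValueError("trajectory probabilities must be >= 0 and sum to 1")
        known = {"untreated", "single_lot_responder", "multi_lot_non_trd", "trd_like"}
        if set(v) - known:
            raise ValueError(f"unknown trajectories: {sorted(set(v) - known)}")
        return v

    @field_validator("trd_like_lines")
    @classmethod
    def _enough_lines(cls, v):
        if any(k < 3 for k in v):
            raise ValueError(
                "trd_like trajectories need >= 3 intended lines of therapy"
            )
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("trd_like line probabilities must sum to 1")
        return v

    @model_validator(mode="after")
    def _rates_nonnegative(self):
        for name, (a, b) in self.comorbidity_rates.items():
            if a < 0 or b < 0 or a > 1 or b > 1:
                raise ValueError(f"comorbidity rate out of [0,1] for {name}")
        for name, (a, b, c) in self.mru_rates.items():
            if a < 0 or b < 0 or c <= 0:
                raise ValueError(f"invalid utilization rates for {name}")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age band probabilities must sum to 1")
        return self


AGE_BANDS = ((18, 35), (36, 50), (51, 64))
AD_DRUGS = [d for d, c in DRUG_CATALOG.items()
            if c in ("SSRI", "SNRI", "ATYPICAL_AD", "AD_OTHERS", "MAOI")]
ADAP_DRUGS = [d for d, c in DRUG_CATALOG.items() if c != "OTHER_NON_ADAP"]
NON_ADAP_DRUGS = [d for d, c in DRUG_CATALOG.items() if c == "OTHER_NON_ADAP"]
#: responder/line primary drugs are drawn with SSRIs dominant
_AD_WEIGHTS = {"SSRI": 0.60, "ATYPICAL_AD": 0.16, "SNRI": 0.14,
               "AD_OTHERS": 0.09, "MAOI": 0.01}


class _Emitter:
    """Accumulates claim rows for one generation run."""

    def __init__(self) -> None:
        self.patients: list[tuple] = []
        self.eligibility: list[tuple] = []
        self.dx: list[tuple] = []
        self.rx: list[tuple] = []
        self.truth: list[dict] = []

    def dx_claim(self, pid, day, code, setting, paid) -> None:
        self.dx.append((pid, int(day), code, setting, round(float(paid), 2)))

    def rx_claim(self, pid, day, drug, supply, paid) -> None:
        self.rx.append((pid, int(day), drug, int(supply), round(float(paid), 2)))


def _lognormal(rng, median: float, sigma: float = 0.5) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _pick_ad(rng) -> str:
    classes = list(_AD_WEIGHTS)
    cls = rng.choice(classes, p=[_AD_WEIGHTS[c] for c in classes])
    pool = [d for d in AD_DRUGS if DRUG_CATALOG[d] == cls]
    return str(rng.choice(pool))


def _supply(rng, sc: Scenario) -> int:
    if rng.random() < sc.days_supply_30_share:
        return 30
    return int(rng.choice(list(sc.alt_days_supply)))


def _fill_schedule(
    rng, sc: Scenario, start: int, n_fills: int, allow_breaks: bool,
    fixed_supply: int | None = None,
) -> tuple[list[tuple[int, int]], int]:
    """Fill (day, supply) sequence with bridgeable gaps; returns the fills
    and the number of breaking gaps dealt."""
    fills = []
    day = start
    breaks = 0
    for i in range(n_fills):
        supply = fixed_supply if fixed_supply is not None else _supply(rng, sc)
        fills.append((day, supply))
        if i == n_fills - 1:
            break
        if allow_breaks and supply == 30 and rng.random() < sc.breaking_gap_prob:
            gap = int(rng.integers(91, 116))  # > supply + grace, < episode gap
            breaks += 1
        else:
            gap = supply + int(rng.integers(-5, 26))
            gap = max(gap, 7)
        day += gap
    return fills, breaks


def _emit_fills(em, rng, sc, pid, drugs, fills) -> int:
    """Emit the same fill schedule for each drug in the line; returns the
    validity end (last fill + its supply)."""
    for day, supply in fills:
        for d in drugs:
            em.rx_claim(pid, day, d, supply,
                        _lognormal(rng, sc.adap_fill_cost_median, 0.4))
    last_day, last_supply = fills[-1]
    return last_day + last_supply


def _gen_treated_lines(
    em: _Emitter, rng, sc: Scenario, pid: str, t0: int, trajectory: str
) -> tuple[int, int, int | None, int]:
    """Emit fills for a treated trajectory.

    Returns (last_relevant_event_day, expected_lots, expected_onset_day
    relative to t0 or None, n_breaks).
    """
    if trajectory == "single_lot_responder":
        drug = _pick_ad(rng)
        fills, breaks = _fill_schedule(
            rng, sc, t0 + int(rng.integers(0, 21)), int(rng.integers(3, 9)),
            allow_breaks=True,
        )
        _emit_fills(em, rng, sc, pid, [drug], fills)
        return fills[-1][0], 1 + breaks, None, breaks

    if trajectory == "multi_lot_non_trd":
        x = _pick_ad(rng)
        partner_pool = [d for d in ADAP_DRUGS if d != x]
        y = str(rng.choice(partner_pool))
        x0 = t0 + int(rng.integers(0, 16))
        # X runs continuously under a clean 30-day schedule; Y joins after
        # the first regimen's lock and stops while X carries on
        n_x = int(rng.integers(6, 10))
        x_fills = []
        day = x0
        for _ in range(n_x):
            x_fills.append((day, 30))
            day += 30 + int(rng.integers(-3, 16))
        x_end = _emit_fills(em, rng, sc, pid, [x], x_fills)
        y0 = x0 + int(rng.integers(36, 61))
        y_fills = [(y0, 30), (y0 + 30 + int(rng.integers(-3, 11)), 30)]
        y_end = _emit_fills(em, rng, sc, pid, [y], y_fills)
        # X must stay valid past Y's end so a step-down regimen forms
        assert x_end > y_end + 5, "generator produced an unusable overlap"
        return x_fills[-1][0], 3, None, 0

    if trajectory == "trd_like":
        ks = sorted(sc.trd_like_lines)
        k = int(rng.choice(ks, p=[sc.trd_like_lines[i] for i in ks]))
        primaries = [str(d) for d in rng.choice(AD_DRUGS, size=k, replace=False)]
        partner_pool = [d for d in ADAP_DRUGS if d not in primaries]
        rng.shuffle(partner_pool)
        partners = iter(partner_pool)
        start = t0 + int(rng.integers(0, 16))
        lots = 0
        breaks_total = 0
        onset: int | None = None
        last_fill = start
        line_starts: list[int] = []
        for i in range(k):
            drugs = [primaries[i]]
            if rng.random() < sc.combo_line_prob:
                drugs.append(next(partners))
            n_fills = int(rng.integers(2, 6))
            # 30-day supply keeps switch timing exact against the line plan
            fills, breaks = _fill_schedule(rng, sc, start, n_fills,
                                           allow_breaks=True, fixed_supply=30)
            v_end = _emit_fills(em, rng, sc, pid, drugs, fills)
            line_starts.append(start)
            lots += 1 + breaks
            breaks_total += breaks
            last_fill = fills[-1][0]
            if rng.random() < 0.6:  # diagnosis recorded at a switch visit
                em.dx_claim(pid, start, str(rng.choice(INCLUSION_DX)),
                            "office_psych", _lognormal(rng, 71, 0.4))
            start = v_end + int(rng.integers(1, 26))
        onset = line_starts[2] - t0  # third line confirms the second failure
        return last_fill, lots, onset, breaks_total

    raise ValueError(f"unknown trajectory {trajectory!r}")


def _gen_episode(
    em: _Emitter, rng, sc: Scenario, pid: str, episode_index: int,
    t0: int, trajectory: str,
) -> tuple[int, int]:
    """Emit one episode's relevant events; returns (episode_end,
    last_relevant_day)."""
    # index/continuation diagnosis opening the episode
    setting = "office_psych" if rng.random() < 0.4 else "office_gp"
    em.dx_claim(pid, t0, str(rng.choice(INCLUSION_DX)), setting,
                _lognormal(rng, 60, 0.4))
    breaks = 0
    onset = None
    if trajectory == "untreated":
        last = t0
        if rng.random() > sc.only_index_dx_share:
            for _ in range(int(rng.integers(1, 4))):
                last += int(rng.integers(20, 111))
                em.dx_claim(pid, last, str(rng.choice(INCLUSION_DX)),
                            "office_gp", _lognormal(rng, 60, 0.4))
        lots = 0
        trd = False
    else:
        last, lots, onset, breaks = _gen_treated_lines(em, rng, sc, pid, t0,
                                                       trajectory)
        trd = trajectory == "trd_like"
    end = last + 120
    em.truth.append(
        {
            "patient_id": pid,
            "episode_index": episode_index,
            "trajectory": trajectory,
            "episode_start": t0,
            "episode_end": end,
            "expected_lots": lots,
            "expected_trd": trd,
            "expected_onset_day": onset,
            "n_breaking_gaps": breaks,
        }
    )
    return end, last


def _gen_mru(em, rng, sc: Scenario, pid: str, start: int, end: int,
             trd: bool) -> None:
    dur = end - start
    for setting, (r_trd, r_non, median_cost) in sc.mru_rates.items():
        rate = r_trd if trd else r_non
        n = int(rng.poisson(rate * dur / 100.0))
        sigma = 0.8 if setting == "inpatient" else 0.5
        for _ in range(n):
            day = int(rng.integers(start, end))
            em.dx_claim(pid, day, MRU_DX_CODE[setting], setting,
                        _lognormal(rng, median_cost, sigma))
    n_rx = int(rng.poisson(sc.other_rx_rate_per_100d * dur / 100.0))
    for _ in range(n_rx):
        day = int(rng.integers(start, end))
        em.rx_claim(pid, day, str(rng.choice(NON_ADAP_DRUGS)),
                    30, _lognormal(rng, 40, 0.5))


def _gen_comorbidities(em, rng, sc: Scenario, pid: str,
                       spans: list[tuple[int, int]], trd_patient: bool) -> None:
    for name, (p_trd, p_non) in sc.comorbidity_rates.items():
        p = p_trd if trd_patient else p_non
        if rng.random() < p:
            for _ in range(1 + int(rng.poisson(1.0))):
                s, e = spans[int(rng.integers(0, len(spans)))]
                day = int(rng.integers(s, e))
                code = str(rng.choice(list(COMORBIDITY_GROUPS[name])))
                em.dx_claim(pid, day, code, "outpatient",
                            _lognormal(rng, 120, 0.5))


def _birth_day(rng, index_day: int, age_lo: int, age_hi: int) -> int:
    age = int(rng.integers(age_lo, age_hi + 1))
    return index_day - int(round(age * 365.25)) - int(rng.integers(30, 300))


def generate_cohort(scenario: Scenario) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a synthetic claims dataset plus per-episode ground truth.

    Deterministic given the scenario (including its seed): the same
    scenario always produces identical tables.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    em = _Emitter()
    traj_names = sorted(sc.trajectory_mix)
    traj_probs = [sc.trajectory_mix[t] for t in traj_names]

    for i in range(sc.n_patients):
        pid = f"P{i:06d}"
        sex = "F" if rng.random() < sc.female_share else "M"
        t0 = int(rng.integers(400, 2201))
        u = rng.random()
        if u < sc.excluded_dx_share:
            role = "excluded_dx"
        elif u < sc.excluded_dx_share + sc.underage_share:
            role = "underage"
        elif u < sc.excluded_dx_share + sc.underage_share + sc.no_index_share:
            role = "no_index"
        else:
            role = "included"

        band = AGE_BANDS[int(rng.choice(3, p=list(sc.age_band_probs)))]
        if role == "underage":
            birth = _birth_day(rng, t0, 16, 17)
        else:
            birth = _birth_day(rng, t0, *band)
        em.patients.append((pid, sex, birth))

        if role == "no_index":
            elig = (t0 - 120 - int(rng.integers(0, 200)),
                    t0 + int(rng.integers(100, 600)))
            em.eligibility.append((pid, *elig))
            em.dx_claim(pid, t0, str(rng.choice(INCLUSION_DX)), "office_gp",
                        _lognormal(rng, 60, 0.4))
            continue
        if role == "excluded_dx":
            em.eligibility.append((pid, t0 - 200, t0 + 900))
            em.dx_claim(pid, t0, str(rng.choice(INCLUSION_DX)), "office_gp",
                        _lognormal(rng, 60, 0.4))
            em.dx_claim(pid, t0 + int(rng.integers(10, 101)),
                        str(rng.choice(EXCLUSION_DX)), "office_psych",
                        _lognormal(rng, 80, 0.4))
            continue

        # included (or underage, whose events look like a normal patient)
        n_eps = 1 if role == "underage" else (
            2 if rng.random() < sc.second_episode_prob else 1
        )
        spans = []
        trajs = []
        start = t0
        any_trd = False
        for epi in range(n_eps):
            traj = str(rng.choice(traj_names, p=traj_probs))
            end, _ = _gen_episode(em, rng, sc, pid, epi, start, traj)
            spans.append((start, end))
            trajs.append(traj)
            any_trd = any_trd or traj == "trd_like"
            start = end + int(rng.integers(10, 301))
        if role == "underage":
            # not part of the cohort: drop the planted expectations
            del em.truth[-n_eps:]

        elig_start = t0 - 120 - int(rng.integers(0, 200))
        elig_end = max(t0 + 720, spans[-1][1]) + int(rng.integers(30, 200))
        if rng.random() < 0.2:  # split into two adjacent periods
            mid = int(rng.integers(elig_start + 30, elig_end - 30))
            em.eligibility.append((pid, elig_start, mid))
            em.eligibility.append((pid, mid + 1, elig_end))
        else:
            em.eligibility.append((pid, elig_start, elig_end))

        if role == "included":
            for (s, e), t in zip(spans, trajs):
                _gen_mru(em, rng, sc, pid, s, e, t == "trd_like")
            _gen_comorbidities(em, rng, sc, pid, spans, any_trd)

    patients = pd.DataFrame(em.patients,
                            columns=["patient_id", "sex", "birth_day"])
    eligibility = pd.DataFrame(em.eligibility,
                               columns=["patient_id", "start_day", "end_day"])
    dx = pd.DataFrame(em.dx,
                      columns=["patient_id", "service_day", "dx_code",
                               "setting", "paid_amount"])
    rx = pd.DataFrame(em.rx,
                      columns=["patient_id", "fill_day", "drug_id",
                               "days_supply", "paid_amount"])
    for df in (patients, eligibility, dx, rx):
        df["order"] = range(len(df))
    dx = dx.sort_values(["patient_id", "service_day", "order"],
                        kind="stable").reset_index(drop=True)
    rx = rx.sort_values(["patient_id", "fill_day", "order"],
                        kind="stable").reset_index(drop=True)
    eligibility = eligibility.sort_values(
        ["patient_id", "start_day", "order"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        em.truth,
        columns=["patient_id", "episode_index", "trajectory", "episode_start",
                 "episode_end", "expected_lots", "expected_trd",
                 "expected_onset_day", "n_breaking_gaps"],
    )
    ds = ClaimsDataset(
        patients=patients,
        eligibility=eligibility,
        dx_claims=dx,
        rx_claims=rx,
        code_maps=default_code_maps(),
    )
    return ds, truth


def expected_labels(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Per-episode comparison targets for recovery tests.

    ``onset_tolerance`` is "exact" when the intended TRD onset day is
    reliable and "may_shift_earlier" when a breaking refill gap landed
    inside a TRD-like trajectory (an early blank can confirm the second
    failure sooner); intended line counts and TRD flags are always exact
    because the generator counts the breaks it deals.
    """
    out = ground_truth[
        ["patient_id", "episode_index", "trajectory", "expected_trd",
         "expected_lots", "expected_onset_day", "episode_start", "episode_end"]
    ].copy()
    noisy = (ground_truth["n_breaking_gaps"] > 0) & ground_truth["expected_trd"]
    out["onset_tolerance"] = np.where(noisy, "may_shift_earlier", "exact")
    return out


def write_scenario_outputs(ds: ClaimsDataset, truth: pd.DataFrame,
                           out_dir) -> None:
    """Write the standard CSV set, codemaps.yaml and ground_truth.csv."""
    from .model import write_dataset
    from pathlib import Path

    out = Path(out_dir)
    write_dataset(ds, out)
    truth.to_csv(out / "ground_truth.csv", index=False)
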