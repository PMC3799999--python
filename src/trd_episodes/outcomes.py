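"""Comparison surfaces: episode characteristics, treatment patterns,
comorbidity profiles and medical resource utilization (MRU).

All comparisons contrast TRD episodes against treated (>= 1 ADAP claim)
non-TRD episodes; patient-level views use the distinct patients behind
each episode group. Every summary is a plain pandas computation so small
fixtures can be recomputed by hand.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ADAP_CLASSES, CodeMaps, code_in_group
from . import stats as _stats

log = logging.getLogger(__name__)

GROUP_TRD = "TRD"
GROUP_NONTRD = "nonTRD"
AGE_BANDS = ((18, 35), (36, 50), (51, 64))


def comparison_episodes(episodes: pd.DataFrame) -> pd.DataFrame:
    """Restrict to treated episodes and attach the comparison group."""
    df = episodes[episodes["treated"]].copy()
    df["group"] = np.where(df["trd"], GROUP_TRD, GROUP_NONTRD)
    return df


def _quartiles(x: pd.Series) -> tuple[float, float, float]:
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return float(q1), float(med), float(q3)


def summarize_groups(
    episodes: pd.DataFrame, patients: pd.DataFrame
) -> dict[str, dict]:
    """Per-group episode counts, duration summaries and patient mix.

    ``patients`` must carry patient_id, sex and age_at_index. Patient
    counts are distinct patients per group; female and age-band shares
    are computed over those patients.
    """
    comp = comparison_episodes(episodes)
    pat = patients.set_index("patient_id")
    out: dict[str, dict] = {}
    for group, grp in comp.groupby("group"):
        dur = grp["duration_days"]
        pids = grp["patient_id"].unique()
        sub = pat.loc[pat.index.intersection(pids)]
        n_pat = len(sub)
        q1, med, q3 = _quartiles(dur) if len(dur) else (np.nan,) * 3
        summary = {
            "n_episodes": int(len(grp)),
            "n_patients": int(n_pat),
            "duration_mean": float(dur.mean()) if len(dur) else np.nan,
            "duration_sd": float(dur.std(ddof=1)) if len(dur) > 1 else np.nan,
            "duration_median": med,
            "duration_q1": q1,
            "duration_q3": q3,
            "female_n": int((sub["sex"] == "F").sum()),
            "female_share": float((sub["sex"] == "F").mean()) if n_pat else np.nan,
        }
        for lo, hi in AGE_BANDS:
            mask = (sub["age_at_index"] >= lo) & (sub["age_at_index"] <= hi)
            summary[f"age_{lo}_{hi}_n"] = int(mask.sum())
            summary[f"age_{lo}_{hi}_share"] = (
                float(mask.mean()) if n_pat else np.nan
            )
        onset = grp["trd_onset_day"].dropna()
        if len(onset):
            o1, omed, o3 = _quartiles(onset)
            summary.update(
                days_to_trd_mean=float(onset.mean()),
                days_to_trd_median=omed,
                days_to_trd_q1=o1,
                days_to_trd_q3=o3,
                share_over_360_days_to_trd=float((onset > 360).mean()),
            )
        out[group] = summary
    return out


def lot_distribution(
    episodes: pd.DataFrame, lots: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of episodes by LOT count, and per-LOT duration summary.

    Returns (hist, lot_summary): hist has group / n_lots / n_episodes;
    lot_summary mirrors the duration-by-line layout (n, median, quartiles
    and mean duration per LOT number and group).
    """
    comp = comparison_episodes(episodes)
    key = ["patient_id", "episode_index"]
    counts = (
        lots.groupby(key)["lot_number"].max().rename("n_lots").reset_index()
    )
    merged = comp.merge(counts, on=key, how="left").fillna({"n_lots": 0})
    hist = (
        merged.groupby(["group", "n_lots"]).size().rename("n_episodes")
        .reset_index()
        .astype({"n_lots": int})
    )

    lt = lots.merge(comp[key + ["group"]], on=key, how="inner")
    rows = []
    for (group, lot_number), grp in lt.groupby(["group", "lot_number"]):
        q1, med, q3 = _quartiles(grp["duration_days"])
        rows.append(
            {
                "group": group,
                "lot_number": int(lot_number),
                "n": int(len(grp)),
                "median_duration": med,
                "q1": q1,
                "q3": q3,
                "mean_duration": float(grp["duration_days"].mean()),
                "sd_duration": float(grp["duration_days"].std(ddof=1))
                if len(grp) > 1 else np.nan,
            }
        )
    return hist, pd.DataFrame(rows)


def _regimen_classes(drug_ids: str, code_maps: CodeMaps) -> frozenset[str]:
    drugs = [d for d in str(drug_ids).split(";") if d]
    return frozenset(code_maps.klass(d) for d in drugs)


def class_usage_share(
    episodes: pd.DataFrame, regimens: pd.DataFrame, code_maps: CodeMaps
) -> pd.DataFrame:
    """Share of episode-days on which each drug class is part of the
    active regimen, per group.

    The denominator is the total episode-days of the group; shares of
    different classes overlap under combination therapy and need not sum
    to one.
    """
    comp = comparison_episodes(episodes)
    key = ["patient_id", "episode_index"]
    total_days = comp.groupby("group")["duration_days"].sum()
    reg = regimens[~regimens["is_blank"]].merge(
        comp[key + ["group"]], on=key, how="inner"
    )
    reg["days"] = reg["end"] - reg["start"]
    acc: dict[tuple[str, str], int] = {}
    for group, drug_ids, days in zip(reg["group"], reg["drug_ids"], reg["days"]):
        for klass in _regimen_classes(drug_ids, code_maps):
            acc[(klass, group)] = acc.get((klass, group), 0) + int(days)
    classes = sorted(ADAP_CLASSES)
    rows = []
    for klass in classes:
        row = {"drug_class": klass}
        for group in (GROUP_TRD, GROUP_NONTRD):
            denom = int(total_days.get(group, 0))
            row[f"days_{group}"] = acc.get((klass, group), 0)
            row[f"share_{group}"] = (
                acc.get((klass, group), 0) / denom if denom else np.nan
            )
            row[f"episode_days_{group}"] = denom
        rows.append(row)
    return pd.DataFrame(rows)


def regimen_label(drug_ids: str, code_maps: CodeMaps) -> str:
    """Human label of a regimen by the classes present, e.g. "SSRI only"
    or "SSRI & AP"."""
    classes = sorted(_regimen_classes(drug_ids, code_maps))
    if not classes:
        return "blank"
    if len(classes) == 1:
        return f"{classes[0]} only"
    return " & ".join(classes)


def regimen_mix(
    episodes: pd.DataFrame, regimens: pd.DataFrame, code_maps: CodeMaps
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monotherapy vs combination shares, and regimen-type share by LOT.

    Returns (mono, by_lot): mono has per-group counts and shares of
    single-drug regimens; by_lot has the share of each regimen type
    within each LOT column, per group.
    """
    comp = comparison_episodes(episodes)
    key = ["patient_id", "episode_index"]
    reg = regimens[~regimens["is_blank"]].merge(
        comp[key + ["group"]], on=key, how="inner"
    )
    reg = reg.sort_values(key + ["regimen_ordinal"])
    reg["lot_number"] = reg.groupby(key).cumcount() + 1
    reg["n_drugs"] = reg["drug_ids"].map(lambda s: len([d for d in s.split(";") if d]))
    reg["label"] = reg["drug_ids"].map(lambda s: regimen_label(s, code_maps))

    mono_rows = []
    for group, grp in reg.groupby("group"):
        mono_rows.append(
            {
                "group": group,
                "n_regimens": int(len(grp)),
                "n_monotherapy": int((grp["n_drugs"] == 1).sum()),
                "monotherapy_share": float((grp["n_drugs"] == 1).mean()),
                "combination_share": float((grp["n_drugs"] > 1).mean()),
            }
        )

    by_lot = (
        reg.groupby(["group", "lot_number", "label"]).size().rename("n")
        .reset_index()
    )
    totals = by_lot.groupby(["group", "lot_number"])["n"].transform("sum")
    by_lot["share"] = by_lot["n"] / totals
    return pd.DataFrame(mono_rows), by_lot


def comorbidity_profile(
    trd_patients: set[str],
    nontrd_patients: set[str],
    dx_claims: pd.DataFrame,
    comorbidity_groups: Mapping[str, frozenset[str]],
) -> pd.DataFrame:
    """Percent of each patient group with >= 1 diagnosis claim matching
    each comorbidity code group, at any time (patient-level: claim count
    beyond the first is irrelevant)."""
    rows = []
    by_pat = dx_claims.groupby("patient_id")["dx_code"].agg(set)
    for name, prefixes in sorted(comorbidity_groups.items()):
        row = {"comorbidity": name}
        for group, pats in ((GROUP_TRD, trd_patients), (GROUP_NONTRD, nontrd_patients)):
            hit = sum(
                1
                for p in pats
                if p in by_pat.index
                and any(code_in_group(c, prefixes) for c in by_pat[p])
            )
            row[f"n_{group}"] = hit
            row[f"n_patients_{group}"] = len(pats)
            row[f"pct_{group}"] = 100.0 * hit / len(pats) if pats else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _attribute_claims(
    claims: pd.DataFrame, day_col: str, episodes: pd.DataFrame
) -> pd.DataFrame:
    """Tag claims with the (patient_id, episode_index, group) of the
    episode whose [start, end) contains their date; unattributed claims
    keep episode_index = -1."""
    eps = episodes[["patient_id", "episode_index", "start", "end", "group"]]
    merged = claims.reset_index(drop=True).reset_index(names="_claim").merge(
        eps, on="patient_id", how="left"
    )
    inside = (merged[day_col] >= merged["start"]) & (merged[day_col] < merged["end"])
    merged = merged[inside]
    out = claims.reset_index(drop=True).copy()
    out["episode_index"] = -1
    out["group"] = None
    out.loc[merged["_claim"], "episode_index"] = merged["episode_index"].values
    out.loc[merged["_claim"], "group"] = merged["group"].values
    return out


def mru_summary(
    episodes: pd.DataFrame,
    dx_claims: pd.DataFrame,
    rx_claims: pd.DataFrame,
    code_maps: CodeMaps,
) -> tuple[pd.DataFrame, dict]:
    """Medical resource utilization per category and group.

    For each category: A = mean episode duration, B = visits per 100
    episode-days (ratio of sums), C = cost per visit, D = cost per
    episode, and the TRD/non-TRD multiple of D. Diagnosis claims map to
    categories through the claim ``setting`` and the configured category
    map (unmapped settings fall into other_outpatient); every pharmacy
    fill is one pharmacy claim. Claims outside any comparison episode go
    to a residual bucket so that costs are conserved. Psychotherapy
    sessions per episode are emitted alongside the category table.

    Returns (table, extras) where extras carries the residual bucket,
    per-episode frames for inference, and psychotherapy sessions per
    episode.
    """
    comp = comparison_episodes(episodes)
    dx = dx_claims.copy()
    dx["category"] = dx["setting"].map(
        lambda s: code_maps.mru_categories.get(s, "other_outpatient")
    )
    dx["day"] = dx["service_day"]
    rx = rx_claims.copy()
    rx["category"] = "pharmacy"
    rx["day"] = rx["fill_day"]
    cols = ["patient_id", "day", "category", "paid_amount"]
    parts = [f[cols] for f in (dx, rx) if len(f)]
    claims = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=cols)
    )
    tagged = _attribute_claims(claims, "day", comp)
    outside = tagged["episode_index"] == -1
    residual = {
        "n_claims": int(outside.sum()),
        "paid": float(tagged.loc[outside, "paid_amount"].sum()),
    }
    inside = tagged[~outside]

    key = ["patient_id", "episode_index"]
    per_ep = (
        inside.groupby(key + ["group", "category"])
        .agg(visits=("paid_amount", "size"), paid=("paid_amount", "sum"))
        .reset_index()
    )
    # complete the per-episode grid with zeros so rates/costs average
    # over all episodes of a group, not only those with any use
    grid = (
        comp[key + ["group", "duration_days"]]
        .merge(pd.DataFrame({"category": list(dict.fromkeys(
            list(code_maps.mru_categories.values()) + ["pharmacy"]))}), how="cross")
    )
    per_ep = grid.merge(per_ep, on=key + ["group", "category"], how="left").fillna(
        {"visits": 0, "paid": 0.0}
    )

    rows = []
    group_stats = comp.groupby("group").agg(
        n_episodes=("duration_days", "size"),
        total_days=("duration_days", "sum"),
        mean_duration=("duration_days", "mean"),
    )
    for category, cgrp in per_ep.groupby("category"):
        row = {"category": category}
        for group in (GROUP_TRD, GROUP_NONTRD):
            g = cgrp[cgrp["group"] == group]
            if group not in group_stats.index or not len(g):
                row.update({f"{k}_{group}": np.nan for k in "ABCD"})
                continue
            n_eps = float(group_stats.loc[group, "n_episodes"])
            days = float(group_stats.loc[group, "total_days"])
            visits = float(g["visits"].sum())
            paid = float(g["paid"].sum())
            row[f"A_{group}"] = float(group_stats.loc[group, "mean_duration"])
            row[f"B_{group}"] = 100.0 * visits / days if days else np.nan
            row[f"C_{group}"] = paid / visits if visits else np.nan
            row[f"D_{group}"] = paid / n_eps if n_eps else np.nan
        d_t, d_n = row.get(f"D_{GROUP_TRD}"), row.get(f"D_{GROUP_NONTRD}")
        row["multiple"] = (
            d_t / d_n if d_t is not None and d_n not in (None, 0) and not (
                isinstance(d_n, float) and (np.isnan(d_n) or d_n == 0))
            else np.nan
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    psy = per_ep[per_ep["category"] == "psychotherapy"]
    sessions = {
        group: float(g["visits"].mean()) if len(g) else np.nan
        for group, g in psy.groupby("group")
    }
    extras = {
        "residual": residual,
        "per_episode": per_ep,
        "psychotherapy_sessions_per_episode": sessions,
        "total_input_paid": float(claims["paid_amount"].sum()),
    }
    return table, extras


def trd_rates(
    n_trd: int,
    n_treated: int,
    mean_dur_trd: float | None = None,
    n_nontrd: int | None = None,
    mean_dur_nontrd: float | None = None,
) -> tuple[float, float]:
    """TRD episode rate and duration-adjusted prevalence, in percent.

    rate = n_trd / n_treated x 100. prevalence weights each group by
    episode-days (count x mean duration):
    prevalence = T / (T + N) x 100 with T = n_trd x mean_dur_trd and
    N = n_nontrd x mean_dur_nontrd. Zero denominators yield 0 when the
    numerator is 0 and NaN (logged) otherwise.
    """
    if n_treated <= 0:
        if n_trd == 0:
            return 0.0, 0.0
        log.warning("trd_rates: zero treated-episode denominator")
        return float("nan"), float("nan")
    rate = 100.0 * n_trd / n_treated
    if n_trd == 0:
        return rate, 0.0
    if not all(v is not None for v in (mean_dur_trd, n_nontrd, mean_dur_nontrd)):
        return rate, float("nan")
    t_days = n_trd * mean_dur_trd
    n_days = n_nontrd * mean_dur_nontrd
    if t_days + n_days == 0:
        log.warning("trd_rates: zero episode-day denominator")
        return rate, float("nan")
    prevalence = 100.0 * t_days / (t_days + n_days)
    return rate, prevalence


def _t_comparison(name, g1, g2):
    """Summary-statistic t-test comparison record (auto variance rule)."""
    mean1, sd1, n1 = g1
    mean2, sd2, n2 = g2
    if n1 < 2 or n2 < 2 or any(
        isinstance(v, float) and np.isnan(v) for v in (mean1, sd1, mean2, sd2)
    ):
        return None
    r = _stats.two_sample_t(mean1, sd1, int(n1), mean2, sd2, int(n2))
    return {
        "comparison": name,
        "method": r.method,
        "statistic": r.statistic,
        "df": r.degrees_of_freedom,
        "p_value": r.p_value,
    }


def _prop_comparison(name, k1, n1, k2, n2):
    if min(n1, n2) <= 0:
        return None
    r = _stats.two_proportion_test(int(round(k1)), int(round(n1)),
                                   int(round(k2)), int(round(n2)))
    return {
        "comparison": name,
        "method": r.method,
        "statistic": r.statistic,
        "df": None,
        "p_value": r.p_value,
    }


def build_report(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    regimens: pd.DataFrame,
    lots: pd.DataFrame,
    dx_claims: pd.DataFrame,
    rx_claims: pd.DataFrame,
    code_maps: CodeMaps,
    alpha: float = 0.05,
    bonferroni_n: int | None = None,
) -> dict:
    """Assemble every comparison surface plus inference annotations.

    Returns a JSON-ready dict with the group summaries, LOT distribution
    and durations, class-usage shares, regimen mix, comorbidity profile,
    MRU table, TRD rate/prevalence, and a comparison list annotated with
    Bonferroni-adjusted significance. The Bonferroni family defaults to
    the number of comparisons actually emitted; the family size used is
    recorded in the report.
    """
    comp = comparison_episodes(episodes)
    groups = summarize_groups(episodes, patients)
    hist, lot_summary = lot_distribution(episodes, lots)
    usage = class_usage_share(episodes, regimens, code_maps)
    mono, by_lot = regimen_mix(episodes, regimens, code_maps)
    trd_pats = set(comp.loc[comp["trd"], "patient_id"])
    non_pats = set(comp.loc[~comp["trd"], "patient_id"]) - trd_pats
    comorbidity = comorbidity_profile(
        trd_pats, non_pats, dx_claims, code_maps.comorbidity_groups
    )
    mru, mru_extras = mru_summary(episodes, dx_claims, rx_claims, code_maps)

    g_t = groups.get(GROUP_TRD, {})
    g_n = groups.get(GROUP_NONTRD, {})
    n_treated = int(comp.shape[0])
    n_trd = int(g_t.get("n_episodes", 0))
    rate, prevalence = trd_rates(
        n_trd, n_treated,
        g_t.get("duration_mean"), g_n.get("n_episodes", 0),
        g_n.get("duration_mean"),
    )

    comparisons = []

    def add(rec):
        if rec is not None:
            comparisons.append(rec)

    if g_t and g_n:
        add(_prop_comparison("female_share",
                             g_t["female_n"], g_t["n_patients"],
                             g_n["female_n"], g_n["n_patients"]))
        for lo, hi in AGE_BANDS:
            add(_prop_comparison(f"age_{lo}_{hi}_share",
                                 g_t[f"age_{lo}_{hi}_n"], g_t["n_patients"],
                                 g_n[f"age_{lo}_{hi}_n"], g_n["n_patients"]))
        add(_t_comparison(
            "episode_duration",
            (g_t["duration_mean"], g_t["duration_sd"], g_t["n_episodes"]),
            (g_n["duration_mean"], g_n["duration_sd"], g_n["n_episodes"]),
        ))
        piv = lot_summary.set_index(["group", "lot_number"]) if len(lot_summary) else None
        if piv is not None:
            lot_numbers = sorted(
                set(lot_summary.loc[lot_summary["group"] == GROUP_TRD, "lot_number"])
                & set(lot_summary.loc[lot_summary["group"] == GROUP_NONTRD,
                                      "lot_number"])
            )
            for ln in lot_numbers[:10]:
                a = piv.loc[(GROUP_TRD, ln)]
                b = piv.loc[(GROUP_NONTRD, ln)]
                add(_t_comparison(
                    f"lot_{ln}_duration",
                    (a["mean_duration"], a["sd_duration"], a["n"]),
                    (b["mean_duration"], b["sd_duration"], b["n"]),
                ))
        for _, row in usage.iterrows():
            add(_prop_comparison(
                f"class_usage_{row['drug_class']}",
                row[f"days_{GROUP_TRD}"], row[f"episode_days_{GROUP_TRD}"],
                row[f"days_{GROUP_NONTRD}"], row[f"episode_days_{GROUP_NONTRD}"],
            ))
        if len(mono) == 2:
            m = mono.set_index("group")
            add(_prop_comparison(
                "monotherapy_share",
                m.loc[GROUP_TRD, "n_monotherapy"], m.loc[GROUP_TRD, "n_regimens"],
                m.loc[GROUP_NONTRD, "n_monotherapy"],
                m.loc[GROUP_NONTRD, "n_regimens"],
            ))
        for _, row in comorbidity.iterrows():
            add(_prop_comparison(
                f"comorbidity_{row['comorbidity']}",
                row[f"n_{GROUP_TRD}"], row[f"n_patients_{GROUP_TRD}"],
                row[f"n_{GROUP_NONTRD}"], row[f"n_patients_{GROUP_NONTRD}"],
            ))
        per_ep = mru_extras["per_episode"]
        per_ep = per_ep.assign(
            rate=100.0 * per_ep["visits"] / per_ep["duration_days"]
        )
        for category, cgrp in per_ep.groupby("category"):
            for metric in ("paid", "rate"):
                sub = {
                    g: (float(x[metric].mean()), float(x[metric].std(ddof=1)),
                        len(x))
                    for g, x in cgrp.groupby("group")
                }
                if GROUP_TRD in sub and GROUP_NONTRD in sub:
                    label = "cost_per_episode" if metric == "paid" else \
                        "visit_rate_per_100d"
                    add(_t_comparison(f"mru_{category}_{label}",
                                      sub[GROUP_TRD], sub[GROUP_NONTRD]))

    family = bonferroni_n if bonferroni_n else max(len(comparisons), 1)
    cutoff = _stats.bonferroni_threshold(alpha, family)
    for rec in comparisons:
        rec["significant"] = bool(rec["p_value"] < cutoff)

    return {
        "groups": groups,
        "trd_episode_rate_pct": rate,
        "trd_prevalence_pct": prevalence,
        "n_treated_episodes": n_treated,
        "lot_distribution": hist.to_dict(orient="records"),
        "lot_durations": lot_summary.to_dict(orient="records"),
        "class_usage": usage.to_dict(orient="records"),
        "regimen_mix": mono.to_dict(orient="records"),
        "regimen_mix_by_lot": by_lot.to_dict(orient="records"),
        "comorbidity": comorbidity.to_dict(orient="records"),
        "mru": mru.to_dict(orient="records"),
        "mru_residual": mru_extras["residual"],
        "psychotherapy_sessions_per_episode":
            mru_extras["psychotherapy_sessions_per_episode"],
        "stats": {
            "alpha": alpha,
            "bonferroni_n": family,
            "cutoff": cutoff,
            "comparisons": comparisons,
        },
    }
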