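"""Tissue-dependent splicing patterns.

Switch score: max pairwise |PSI| difference between expressing tissues
(equivalently max minus min of tissue-level PSI), with five
tissue-regulatory groups. Scenario classification of tissue-dependent
allelic divergence looks at the tissue pair maximizing the difference in
allelic divergence (ddPSI = |dPSI_allelic(T1) - dPSI_allelic(T2)|) and
compares each allele's between-tissue change dPSI_T = PSI(T1) - PSI(T2):

  scenario 1 - both alleles change more than the cutoff, opposite signs
  scenario 2 - both change more than the cutoff, same sign
  scenario 3 - exactly one allele changes more than the cutoff
  scenario 4 - neither does

"greater than the cutoff" is strict, matching the classification rule;
ties in the maximizing pair are broken by lexicographic tissue order.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ranksums

SWITCH_GROUPS = (
    (0.5, "Switch-Like"),
    (0.3, "Moderate-High"),
    (0.2, "Moderate-Low"),
    (0.1, "Low"),
    (0.0, "Non-Differential"),
)


def switch_group(score: float) -> str:
    for bound, name in SWITCH_GROUPS:
        if score >= bound:
            return name
    return "Non-Differential"


def switch_score(psi_by_tissue: pd.DataFrame, min_tissues: int = 2) -> pd.DataFrame:
    """Switch score and tissue-regulatory group per event.

    psi_by_tissue: (event_id, tissue, psi) at tissue level (replicate-mean
    PSI). Events with fewer than min_tissues tissues are excluded.
    """
    sub = psi_by_tissue.dropna(subset=["psi"])
    g = sub.groupby("event_id")["psi"].agg(["max", "min", "count"])
    g = g[g["count"] >= min_tissues]
    score = g["max"] - g["min"]
    return pd.DataFrame({
        "event_id": g.index,
        "switch_score": score,
        "group": [switch_group(s) for s in score],
    }).reset_index(drop=True)


def classify_scenario_pair(dpsi_t_bl6: float, dpsi_t_spr: float, cutoff: float) -> int:
    """Scenario of one tissue pair from the two alleles' between-tissue
    PSI changes."""
    big_b = abs(dpsi_t_bl6) > cutoff
    big_s = abs(dpsi_t_spr) > cutoff
    if big_b and big_s:
        return 1 if np.sign(dpsi_t_bl6) != np.sign(dpsi_t_spr) else 2
    if big_b or big_s:
        return 3
    return 4


def classify_scenarios(calls: pd.DataFrame, cutoff: float = 0.1,
                       min_tissues: int = 2) -> pd.DataFrame:
    """Scenario call per event.

    calls: per event x tissue with psi_bl6, psi_spr, delta_psi, divergent
    (the divergence-call table). Events expressed in >= min_tissues
    tissues and divergent in >= 1 are classified on the tissue pair with
    the largest ddPSI.
    """
    if not 0.1 <= cutoff <= 0.2:
        raise ValueError("cutoff must be within [0.1, 0.2]")
    rows = []
    for event_id, sub in calls.groupby("event_id"):
        sub = sub.dropna(subset=["psi_bl6", "psi_spr"])
        if len(sub) < min_tissues or not sub["divergent"].any():
            continue
        sub = sub.set_index("tissue").sort_index()
        best = None
        for t1, t2 in combinations(sub.index, 2):  # lexicographic order
            ddpsi = abs(sub.at[t1, "delta_psi"] - sub.at[t2, "delta_psi"])
            if best is None or ddpsi > best[0]:
                best = (ddpsi, t1, t2)
        ddpsi, t1, t2 = best
        db = sub.at[t1, "psi_bl6"] - sub.at[t2, "psi_bl6"]
        ds = sub.at[t1, "psi_spr"] - sub.at[t2, "psi_spr"]
        rows.append((event_id, t1, t2, ddpsi, db, ds,
                     classify_scenario_pair(db, ds, cutoff), cutoff))
    return pd.DataFrame(rows, columns=[
        "event_id", "tissue_1", "tissue_2", "ddpsi",
        "dpsi_t_bl6", "dpsi_t_spr", "scenario", "cutoff"])


def scenario_magnitudes(scenarios: pd.DataFrame) -> tuple:
    """Per-scenario distribution of max(|dPSI_T BL6|, |dPSI_T SPR|).

    Returns (per-scenario medians as a Series, one-sided rank-sum p that
    scenario 2 magnitudes exceed scenario 3).
    """
    mag = np.maximum(scenarios["dpsi_t_bl6"].abs(), scenarios["dpsi_t_spr"].abs())
    df = scenarios.assign(magnitude=mag)
    medians = df.groupby("scenario")["magnitude"].median()
    s2 = df.loc[df["scenario"] == 2, "magnitude"]
    s3 = df.loc[df["scenario"] == 3, "magnitude"]
    if len(s2) and len(s3):
        p = ranksums(s2, s3, alternative="greater").pvalue
    else:
        p = np.nan
    return medians, float(p)


def microexon_enrichment(categories: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Micro-exon enrichment per category (each vs the rest, Fisher).

    categories: (event_id, category); events: frame with event_id and
    microexon (bool). Returns per category counts, percentage of
    micro-exons, odds ratio and two-sided Fisher p.
    """
    df = categories.merge(events[["event_id", "microexon"]], on="event_id")
    rows = []
    for cat, sub in df.groupby("category"):
        rest = df[df["category"] != cat]
        a = int(sub["microexon"].sum())
        b = int((~sub["microexon"]).sum())
        c = int(rest["microexon"].sum())
        d = int((~rest["microexon"]).sum())
        if a + b == 0:
            continue
        if min(a + c, b + d) == 0:
            oddsr, p = np.nan, np.nan
        else:
            oddsr, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((cat, a, b, 100.0 * a / (a + b), oddsr, p))
    return pd.DataFrame(rows, columns=[
        "category", "n_microexon", "n_regular", "pct_microexon", "odds_ratio", "p_value"])


def pairwise_divergence_pattern(selected_tissue: str, calls: pd.DataFrame) -> pd.Series:
    """Divergence pattern of events expressed in the selected tissue plus
    exactly one other tissue.

    Returns proportions over {selected-only, other-only, both, neither};
    empty Series when no event qualifies.
    """
    counts = {"selected-only": 0, "other-only": 0, "both": 0, "neither": 0}
    total = 0
    for _, sub in calls.groupby("event_id"):
        if len(sub) != 2 or selected_tissue not in set(sub["tissue"]):
            continue
        sel = bool(sub.loc[sub["tissue"] == selected_tissue, "divergent"].iloc[0])
        oth = bool(sub.loc[sub["tissue"] != selected_tissue, "divergent"].iloc[0])
        key = ("both" if sel and oth else "selected-only" if sel
               else "other-only" if oth else "neither")
        counts[key] += 1
        total += 1
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series({k: v / total for k, v in counts.items()})


def allele_switch_concordance(per_allele_switch: pd.DataFrame,
                              groups: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate per-allele tissue-regulatory group against the
    cross-tissue divergence group.

    per_allele_switch: (event_id, allele, group) from switch_score applied
    to each allele's PSI; groups: (event_id, group) divergence groups.
    """
    df = per_allele_switch.merge(groups[["event_id", "group"]],
                                 on="event_id", suffixes=("_switch", "_divergence"))
    if df.empty:
        return pd.DataFrame()
    return pd.crosstab(df["group_switch"], df["group_divergence"])
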