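"""Candidate filtering, group-comparison statistics, and the spliceosome
perturbation (DMSO vs pladienolide B) comparison.

Candidates for functionally relevant divergent splicing must combine a
large allelic difference (|dPSI| >= 0.5 in some tissue), solid expression
where the divergence occurs (TPM >= 30 and at least the gene's average),
and a conserved alternative exon (mean PhastCons >= 0.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, ks_2samp, mannwhitneyu, wilcoxon

CANDIDATE_MIN_DELTA = 0.5
CANDIDATE_MIN_TPM = 30.0
CANDIDATE_MIN_CONS = 0.8


def candidate_filter(calls: pd.DataFrame, features: pd.DataFrame,
                     tpm_long: pd.DataFrame, event_genes: pd.DataFrame,
                     min_delta: float = CANDIDATE_MIN_DELTA,
                     min_tpm: float = CANDIDATE_MIN_TPM,
                     min_cons: float = CANDIDATE_MIN_CONS) -> pd.DataFrame:
    """Events that are strong functional candidates.

    Rules: max tissue |dPSI| >= min_delta; TPM >= min_tpm in every tissue
    with |dPSI| >= min_delta; the max TPM among those tissues at least the
    gene's mean TPM across the event's expressing tissues; exon mean
    conservation >= min_cons (events without a conservation value are
    skipped).
    """
    feats = features.set_index("event_id")
    df = calls.merge(event_genes[["event_id", "gene_id"]], on="event_id")
    df = df.merge(tpm_long, on=["gene_id", "tissue"], how="left")
    rows = []
    for event_id, sub in df.groupby("event_id"):
        big = sub[sub["delta_psi"].abs() >= min_delta]
        if big.empty:
            continue
        if event_id not in feats.index:
            continue
        cons = feats.at[event_id, "exon_mean_phastcons"]
        if not np.isfinite(cons):
            continue
        if (big["tpm"] < min_tpm).any():
            continue
        if big["tpm"].max() < sub["tpm"].mean():
            continue
        if cons < min_cons:
            continue
        rows.append((event_id, str(sub["gene_id"].iloc[0]),
                     float(sub["delta_psi"].abs().max()), float(cons)))
    return pd.DataFrame(rows, columns=["event_id", "gene_id", "max_abs_delta_psi",
                                       "exon_mean_phastcons"])


def fisher_or(a: int, b: int, c: int, d: int) -> dict:
    """Sample (cross-product) odds ratio and two-sided Fisher exact p for
    the 2x2 table [[a, b], [c, d]].

    A zero marginal yields absent results; when exactly one cell is zero
    the odds ratio uses the Haldane +0.5 correction (flagged).
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any() or not np.allclose(cells, np.round(cells)):
        raise ValueError("cells must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        return {"odds_ratio": np.nan, "p_value": np.nan, "haldane": False}
    haldane = (cells == 0).sum() == 1
    if haldane:
        a_, b_, c_, d_ = cells + 0.5
    else:
        a_, b_, c_, d_ = cells
    if b_ * c_ == 0:
        oddsr = np.inf
    else:
        oddsr = (a_ * d_) / (b_ * c_)
    p = fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
    return {"odds_ratio": float(oddsr), "p_value": float(p), "haldane": bool(haldane)}


def group_compare(x, y, test: str = "ranksum", alternative: str = "two-sided") -> dict:
    """Standard two-group comparison.

    test: "ranksum" (Wilcoxon rank-sum), "signedrank" (paired Wilcoxon
    signed-rank) or "ks" (two-sample Kolmogorov-Smirnov, two-sided).
    Returns statistic and p; absent for empty groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        return {"statistic": np.nan, "p_value": np.nan, "n1": len(x), "n2": len(y)}
    if test == "ranksum":
        # exact null distribution for small untied samples, else the
        # continuity-corrected normal approximation
        res = mannwhitneyu(x, y, alternative=alternative, method="auto")
    elif test == "signedrank":
        if len(x) != len(y):
            raise ValueError("signed-rank requires paired samples")
        if np.all(x == y):
            return {"statistic": 0.0, "p_value": 1.0, "n1": len(x), "n2": len(y)}
        res = wilcoxon(x, y, alternative=alternative)
    elif test == "ks":
        res = ks_2samp(x, y)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue),
            "n1": len(x), "n2": len(y)}


def perturbation_compare(calls_control: pd.DataFrame, calls_treatment: pd.DataFrame,
                         tissue_calls: pd.DataFrame | None = None,
                         min_delta: float = 0.1) -> tuple:
    """Classify events by allelic divergence in control vs treatment.

    calls_*: divergence-call tables of the perturbed cell line (one
    "tissue" each: DMSO control and pladB treatment), sharing an event
    universe. Categories: both / treatment-only / control-only / neither
    at fdr < 0.05 and |dPSI| >= min_delta. For treatment-only events with
    baseline tissue data, direction consistency compares the sign of the
    treatment dPSI with the sign of the tissue dPSI of largest magnitude.

    Returns (per-event frame, summary dict).
    """
    ctrl = calls_control.set_index("event_id")
    trt = calls_treatment.set_index("event_id")
    shared = ctrl.index.intersection(trt.index)
    ctrl, trt = ctrl.loc[shared], trt.loc[shared]
    div_c = ctrl["divergent"].astype(bool)
    div_t = trt["divergent"].astype(bool)
    category = np.where(div_c & div_t, "both",
                        np.where(div_t, "treatment-only",
                                 np.where(div_c, "control-only", "neither")))
    out = pd.DataFrame({
        "event_id": shared,
        "delta_psi_control": ctrl["delta_psi"].to_numpy(),
        "delta_psi_treatment": trt["delta_psi"].to_numpy(),
        "divergent_control": div_c.to_numpy(),
        "divergent_treatment": div_t.to_numpy(),
        "category": category,
    })
    out["direction_consistent"] = np.nan
    if tissue_calls is not None:
        # per event: tissue dPSI with max |dPSI| across baseline tissues
        t = tissue_calls.dropna(subset=["delta_psi"]).copy()
        t["abs"] = t["delta_psi"].abs()
        top = t.loc[t.groupby("event_id")["abs"].idxmax(), ["event_id", "delta_psi"]]
        top = top.rename(columns={"delta_psi": "tissue_delta"})
        out = out.merge(top, on="event_id", how="left")
        mask = (out["category"] == "treatment-only") & out["tissue_delta"].notna()
        out.loc[mask, "direction_consistent"] = (
            np.sign(out.loc[mask, "delta_psi_treatment"])
            == np.sign(out.loc[mask, "tissue_delta"])
        ).astype(float)
    summary = {
        "n_shared": int(len(out)),
        "n_both": int((out["category"] == "both").sum()),
        "n_treatment_only": int((out["category"] == "treatment-only").sum()),
        "n_control_only": int((out["category"] == "control-only").sum()),
        "n_neither": int((out["category"] == "neither").sum()),
        "direction_consistency": float(out["direction_consistent"].mean())
        if out["direction_consistent"].notna().any() else np.nan,
    }
    return out, summary


def splicing_class_shift(class_levels: pd.DataFrame) -> pd.DataFrame:
    """Per-AS-class paired shift between conditions.

    class_levels: (as_class, event_id, level_control, level_treatment),
    pre-summarized per event. Returns per-class mean shift and signed-rank
    p; classes present in only one condition are absent.
    """
    rows = []
    for as_class, sub in class_levels.groupby("as_class"):
        sub = sub.dropna(subset=["level_control", "level_treatment"])
        if sub.empty:
            continue
        shift = (sub["level_treatment"] - sub["level_control"]).mean()
        res = group_compare(sub["level_treatment"], sub["level_control"],
                            test="signedrank", alternative="greater")
        rows.append((as_class, float(shift), res["p_value"], len(sub)))
    return pd.DataFrame(rows, columns=["as_class", "mean_shift", "p_value", "n_events"])
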