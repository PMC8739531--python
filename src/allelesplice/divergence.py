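"""Allelic splicing divergence: delta-PSI, the replicate-aware test,
per-tissue divergence calls, cross-tissue groups, gene-level SDS and the
expression-buffering correlations.

dPSI_allelic = mean(PSI_BL6 over replicates) - mean(PSI_SPR over
replicates) within a tissue. An event is divergent in a tissue when
FDR < alpha AND |dPSI_allelic| >= min_delta (BH correction within tissue
by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon
from statsmodels.stats.multitest import multipletests

from .betabinom import betabinom_lrt
from .events import EffectiveLengths
from .psi import estimate_psi

ALPHA = 0.05
MIN_DELTA = 0.1


def _row_mean(a: np.ndarray) -> np.ndarray:
    """Row-wise mean over finite entries; NaN for all-missing rows."""
    mask = np.isfinite(a)
    c = mask.sum(axis=1)
    s = np.where(mask, a, 0.0).sum(axis=1)
    return np.where(c > 0, s / np.maximum(c, 1), np.nan)


def _allele_wide(counts: pd.DataFrame, condition: str) -> tuple:
    """Pivot allelic counts to aligned (E,) index and (E, R) arrays per allele."""
    sub = counts[(counts["allele"].isin(("BL6", "SPR"))) & (counts["condition"] == condition)]
    wide = sub.pivot_table(index=["event_id", "tissue"],
                           columns=["allele", "replicate"],
                           values=["inclusion", "skipping"], fill_value=0)
    kb = wide["inclusion"]["BL6"].to_numpy(float)
    nb = kb + wide["skipping"]["BL6"].to_numpy(float)
    ks = wide["inclusion"]["SPR"].to_numpy(float)
    ns = ks + wide["skipping"]["SPR"].to_numpy(float)
    return wide.index, kb, nb, ks, ns


def call_divergence(counts: pd.DataFrame,
                    expressed: pd.DataFrame | None = None,
                    lengths: EffectiveLengths = EffectiveLengths(),
                    condition: str = "baseline",
                    alpha: float = ALPHA, min_delta: float = MIN_DELTA,
                    fdr_scope: str = "tissue") -> pd.DataFrame:
    """Divergence calls per event x tissue.

    Tests BL6 vs SPR replicate counts with the moderated beta-binomial
    LRT, applies Benjamini-Hochberg within each tissue (``fdr_scope`` =
    "tissue") or over all tests at once ("global"), and flags events with
    fdr < alpha and |delta_psi| >= min_delta. When an expression map is
    given (event_id, tissue, expressed), only expressed cells are tested.
    """
    if fdr_scope not in ("tissue", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    idx, kb, nb, ks, ns = _allele_wide(counts, condition)

    psi_b = _row_mean(estimate_psi(kb, nb - kb, lengths))
    psi_s = _row_mean(estimate_psi(ks, ns - ks, lengths))
    out = pd.DataFrame({
        "event_id": idx.get_level_values("event_id"),
        "tissue": idx.get_level_values("tissue"),
        "psi_bl6": psi_b,
        "psi_spr": psi_s,
        "delta_psi": psi_b - psi_s,
    })
    keep = np.ones(len(out), dtype=bool)
    if expressed is not None:
        exp = expressed[expressed["expressed"]][["event_id", "tissue"]]
        keep = out.merge(exp, on=["event_id", "tissue"], how="left", indicator=True
                         )["_merge"].eq("both").to_numpy()
    out = out[keep].reset_index(drop=True)
    p, lr = betabinom_lrt(kb[keep], nb[keep], ks[keep], ns[keep])
    out["p_value"] = p
    out["fdr"] = np.nan
    if fdr_scope == "tissue":
        for tissue, sub in out.groupby("tissue"):
            ok = sub["p_value"].notna()
            if ok.any():
                out.loc[sub.index[ok], "fdr"] = multipletests(
                    sub.loc[ok, "p_value"], method="fdr_bh")[1]
    else:
        ok = out["p_value"].notna()
        if ok.any():
            out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["divergent"] = (out["fdr"] < alpha) & (out["delta_psi"].abs() >= min_delta)
    return out


def divergence_groups(calls: pd.DataFrame, min_tissues: int = 2) -> pd.DataFrame:
    """Cross-tissue divergence group per event.

    All-Divergent: divergent in every expressing tissue; Non-Divergent:
    in none; Some-Divergent otherwise. Events expressed (tested) in fewer
    than ``min_tissues`` tissues are excluded.
    """
    g = calls.groupby("event_id")["divergent"].agg(["sum", "count"])
    g = g[g["count"] >= min_tissues]
    group = np.where(g["sum"] == g["count"], "All-Divergent",
                     np.where(g["sum"] == 0, "Non-Divergent", "Some-Divergent"))
    return pd.DataFrame({"event_id": g.index, "n_divergent": g["sum"].astype(int),
                         "n_expressed": g["count"].astype(int), "group": group}
                        ).reset_index(drop=True)


def sds(calls: pd.DataFrame, event_genes: pd.DataFrame, min_tissues: int = 2) -> pd.DataFrame:
    """Gene-level splicing divergence score.

    SDS = (sum_i d_i/e_i) / n * 100 over the gene's events expressed in
    >= min_tissues tissues, where d_i counts divergent and e_i expressing
    tissues of event i. Groups: Non-Divergent (SDS = 0), Low Divergence
    (0 < SDS < 50), High Divergence (SDS >= 50).
    """
    per_event = calls.groupby("event_id")["divergent"].agg(d="sum", e="count").reset_index()
    per_event = per_event[per_event["e"] >= min_tissues]
    per_event = per_event.merge(event_genes[["event_id", "gene_id"]], on="event_id")
    if per_event.empty:
        return pd.DataFrame(columns=["gene_id", "sds", "group"])
    per_event["frac"] = per_event["d"] / per_event["e"]
    agg = per_event.groupby("gene_id")["frac"].mean().mul(100.0).rename("sds").reset_index()
    agg["group"] = np.where(agg["sds"] == 0, "Non-Divergent",
                            np.where(agg["sds"] < 50, "Low Divergence", "High Divergence"))
    return agg


def buffering_correlation(calls: pd.DataFrame, tpm_long: pd.DataFrame,
                          event_genes: pd.DataFrame,
                          min_tissues: int = 3) -> tuple:
    """Per-event Spearman correlation across tissues between |dPSI| and TPM.

    Restricted to events expressed in >= min_tissues tissues and divergent
    in at least one. Returns (per-event frame with rho, cohort one-sided
    Wilcoxon signed-rank p for median rho < 0).
    """
    df = calls.merge(event_genes[["event_id", "gene_id"]], on="event_id")
    df = df.merge(tpm_long, on=["gene_id", "tissue"])
    rows = []
    for event_id, sub in df.groupby("event_id"):
        if len(sub) < min_tissues or not sub["divergent"].any():
            continue
        adp = sub["delta_psi"].abs()
        if adp.nunique() < 2 or sub["tpm"].nunique() < 2:
            rows.append((event_id, np.nan, len(sub)))
            continue
        rho = spearmanr(adp, sub["tpm"]).statistic
        rows.append((event_id, rho, len(sub)))
    per_event = pd.DataFrame(rows, columns=["event_id", "rho", "n_tissues"])
    rhos = per_event["rho"].dropna()
    if len(rhos) >= 10 and (rhos != 0).any():
        p = wilcoxon(rhos, alternative="less").pvalue
    else:
        p = np.nan
    return per_event, float(p)


def paired_expression_comparison(calls: pd.DataFrame, groups: pd.DataFrame,
                                 tpm_long: pd.DataFrame,
                                 event_genes: pd.DataFrame) -> tuple:
    """For Some-Divergent events, mean TPM in non-divergent vs divergent
    tissues, with a one-sided signed-rank test (non-divergent > divergent).
    """
    some = groups.loc[groups["group"] == "Some-Divergent", "event_id"]
    df = calls[calls["event_id"].isin(some)].merge(
        event_genes[["event_id", "gene_id"]], on="event_id")
    df = df.merge(tpm_long, on=["gene_id", "tissue"])
    agg = df.groupby(["event_id", "divergent"])["tpm"].mean().unstack()
    agg = agg.dropna()
    pairs = pd.DataFrame({
        "event_id": agg.index,
        "tpm_nondivergent": agg[False].to_numpy(),
        "tpm_divergent": agg[True].to_numpy(),
    }).reset_index(drop=True)
    diff = pairs["tpm_nondivergent"] - pairs["tpm_divergent"]
    if len(pairs) >= 10 and (diff != 0).any():
        p = wilcoxon(pairs["tpm_nondivergent"], pairs["tpm_divergent"],
                     alternative="greater").pvalue
    else:
        p = np.nan
    return pairs, float(p)
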