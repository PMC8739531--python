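"""PSI / PDI estimation and the expression, constitutive and consistency
filters.

PSI for a skipped-exon event is the effective-length-weighted inclusion
fraction psi = (I/L_I) / (I/L_I + S/L_S), where I and S are the junction
reads supporting the inclusion and skipping isoform. At junction
resolution the defaults are L_I = 2, L_S = 1 (two inclusion junctions vs
one skipping junction). PSI is undefined (NaN) when no informative reads
are present — never zero.

Allele sets: "BL6" / "SPR" are the two parental alleles, "allelic" pools
the unambiguously assigned reads of both, "total" additionally pools the
reads shared by both genomes ("common").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .betabinom import betabinom_lrt
from .events import EffectiveLengths

MIN_READS = 20  # minimum informative reads per replicate for "expressed"

ALLELE_SETS = {
    "BL6": ("BL6",),
    "SPR": ("SPR",),
    "allelic": ("BL6", "SPR"),
    "total": ("BL6", "SPR", "common"),
}


def estimate_psi(I, S, lengths: EffectiveLengths = EffectiveLengths()):
    """Length-weighted inclusion fraction; NaN where I + S = 0."""
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    if ((I < 0) | (S < 0)).any():
        raise ValueError("negative counts")
    wi = I / lengths.L_I
    ws = S / lengths.L_S
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(I + S > 0, wi / (wi + ws), np.nan)
    return psi


def compute_pdi(psi):
    """Percent dominant isoform: PDI = |PSI - 0.5| + 0.5, in [0.5, 1]."""
    psi = np.asarray(psi, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((psi < 0) | (psi > 1)):
            raise ValueError("PSI outside [0, 1]")
    return np.abs(psi - 0.5) + 0.5


def pooled_counts(counts: pd.DataFrame, allele_set: str, condition: str = "baseline") -> pd.DataFrame:
    """Sum inclusion/skipping over the alleles of ``allele_set`` per
    event x tissue x replicate."""
    alleles = ALLELE_SETS[allele_set]
    sub = counts[(counts["allele"].isin(alleles)) & (counts["condition"] == condition)]
    out = (sub.groupby(["event_id", "tissue", "replicate"], as_index=False)
              [["inclusion", "skipping"]].sum())
    out["allele_set"] = allele_set
    return out


def psi_table(counts: pd.DataFrame, lengths: EffectiveLengths = EffectiveLengths(),
              condition: str = "baseline",
              allele_sets: tuple = ("BL6", "SPR", "allelic", "total")) -> pd.DataFrame:
    """PSI per event x tissue x replicate x allele set, with the
    informative-read count."""
    frames = []
    for aset in allele_sets:
        sub = pooled_counts(counts, aset, condition)
        sub["psi"] = estimate_psi(sub["inclusion"], sub["skipping"], lengths)
        sub["informative_reads"] = sub["inclusion"] + sub["skipping"]
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def is_expressed(counts: pd.DataFrame, mode: str = "total",
                 min_reads: int = MIN_READS, condition: str = "baseline",
                 n_replicates: int | None = None) -> pd.DataFrame:
    """Expression flags per event x tissue.

    mode "total": informative reads (allelic + common) >= min_reads in
    every replicate. mode "allelic": the per-replicate threshold must hold
    within each allele separately. Tissues missing a replicate count as
    not expressed.
    """
    if mode not in ("total", "allelic"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "total":
        pooled = pooled_counts(counts, "total", condition)
        pooled["reads"] = pooled["inclusion"] + pooled["skipping"]
        grp = pooled.groupby(["event_id", "tissue"])["reads"]
        flags = grp.agg(lambda r: bool((r >= min_reads).all())).rename("expressed")
        n_rep = grp.size().rename("n")
    else:
        sub = counts[(counts["allele"].isin(("BL6", "SPR"))) & (counts["condition"] == condition)].copy()
        sub["reads"] = sub["inclusion"] + sub["skipping"]
        grp = sub.groupby(["event_id", "tissue"])["reads"]
        flags = grp.agg(lambda r: bool((r >= min_reads).all())).rename("expressed")
        n_rep = grp.size().rename("n")
    out = pd.concat([flags, n_rep], axis=1).reset_index()
    if n_replicates is not None:
        expected = n_replicates * (1 if mode == "total" else 2)
        out.loc[out["n"] != expected, "expressed"] = False
    return out.drop(columns="n")


def replicate_mean_psi(psi: pd.DataFrame) -> pd.DataFrame:
    """Tissue-level PSI: unweighted mean of the replicate PSI values."""
    return (psi.groupby(["event_id", "tissue", "allele_set"], as_index=False)
               ["psi"].mean())


def filter_constitutive(psi: pd.DataFrame, expressed: pd.DataFrame,
                        mode: str = "total",
                        lo: float = 0.1, hi: float = 0.9) -> pd.DataFrame:
    """Flag events that are not really alternatively spliced.

    An event fails when its PSI is > hi in every replicate of every
    expressing tissue, or < lo in all of them. In allelic mode the event
    is only dropped when the same condition also holds within both alleles
    considered separately.

    Returns a frame (event_id, constitutive) covering events with >= 1
    expressing tissue.
    """
    exp = expressed[expressed["expressed"]][["event_id", "tissue"]]

    def _all_extreme(aset: str) -> pd.Series:
        sub = psi[psi["allele_set"] == aset].merge(exp, on=["event_id", "tissue"])
        sub = sub.dropna(subset=["psi"])
        g = sub.groupby("event_id")["psi"]
        return g.agg(lambda v: bool((v > hi).all() or (v < lo).all()))

    if mode == "total":
        flag = _all_extreme("total")
    elif mode == "allelic":
        flag = _all_extreme("allelic") & _all_extreme("BL6") & _all_extreme("SPR")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return flag.rename("constitutive").reset_index()


def consistency_filter(counts: pd.DataFrame,
                       lengths: EffectiveLengths = EffectiveLengths(),
                       condition: str = "baseline",
                       max_delta: float = 0.1, min_fdr: float = 0.5) -> pd.DataFrame:
    """Compare allelic-only against allelic+common PSI per event x tissue.

    Events whose two estimates agree (|dPSI| <= max_delta AND
    beta-binomial FDR > min_fdr) are retained: a disagreement indicates
    that allele-assignable reads are not representative of the event.
    Returns (event_id, tissue, delta, fdr, consistent).
    """
    from statsmodels.stats.multitest import multipletests

    allelic = pooled_counts(counts, "allelic", condition)
    total = pooled_counts(counts, "total", condition)
    wide_a = allelic.pivot_table(index=["event_id", "tissue"], columns="replicate",
                                 values=["inclusion", "skipping"], fill_value=0)
    wide_t = total.pivot_table(index=["event_id", "tissue"], columns="replicate",
                               values=["inclusion", "skipping"], fill_value=0)
    idx = wide_a.index.intersection(wide_t.index)
    wide_a, wide_t = wide_a.loc[idx], wide_t.loc[idx]

    ka = wide_a["inclusion"].to_numpy(float)
    na = ka + wide_a["skipping"].to_numpy(float)
    kt = wide_t["inclusion"].to_numpy(float)
    nt = kt + wide_t["skipping"].to_numpy(float)

    from .divergence import _row_mean
    psi_a = _row_mean(estimate_psi(ka, na - ka, lengths))
    psi_t = _row_mean(estimate_psi(kt, nt - kt, lengths))
    delta = psi_a - psi_t
    p, _ = betabinom_lrt(ka, na, kt, nt)
    fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out = pd.DataFrame({
        "event_id": idx.get_level_values("event_id"),
        "tissue": idx.get_level_values("tissue"),
        "delta": delta,
        "fdr": fdr,
    })
    out["consistent"] = (np.abs(out["delta"]) <= max_delta) & (out["fdr"] > min_fdr)
    return out
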