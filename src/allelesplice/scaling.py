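"""The splicing scaling law and the additive-effect (A) statistic.

A fixed cis-regulatory perturbation acts multiplicatively on the
splicing-efficiency odds, odds(PSI) = PSI / (100 - PSI) on the percent
scale. The additive effect between a starting PSI_s and a final
PSI_s + dPSI is

    A = (PSI_s^2 - 100 PSI_s + dPSI PSI_s - 100 dPSI)
        / (PSI_s (dPSI + PSI_s - 100))
      = odds(PSI_s + dPSI) / odds(PSI_s),

so A = 1 iff dPSI = 0, and a given A (log-odds shift log A) produces the
largest |dPSI| at intermediate starting PSI — the scaling law.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ranksums

BOUNDARY_TOL = 1e-6  # percent-scale distance to 0/100 treated as boundary

PSI_BINS = np.linspace(0.0, 1.0, 11)  # ten bins of starting PSI


def odds(psi_percent):
    """Splicing-efficiency odds on the 0-100 scale."""
    psi_percent = np.asarray(psi_percent, dtype=float)
    return psi_percent / (100.0 - psi_percent)


def additive_effect(psi_start, delta_psi):
    """A score between starting and final PSI (both on the 0-100 scale).

    Requires interior values: 0 < psi_start < 100 and
    0 < psi_start + delta_psi < 100 (beyond BOUNDARY_TOL), else raises.
    """
    s = np.asarray(psi_start, dtype=float)
    d = np.asarray(delta_psi, dtype=float)
    f = s + d
    if np.any((s <= BOUNDARY_TOL) | (s >= 100.0 - BOUNDARY_TOL)):
        raise ValueError("starting PSI at boundary: odds undefined")
    if np.any((f <= BOUNDARY_TOL) | (f >= 100.0 - BOUNDARY_TOL)):
        raise ValueError("final PSI at boundary: odds undefined")
    out = (s * s - 100.0 * s + d * s - 100.0 * d) / (s * (d + s - 100.0))
    # exact identity at zero effect (numerator and denominator round
    # differently in floating point even though they agree algebraically)
    return np.where(d == 0.0, 1.0, out) if out.ndim else (1.0 if d == 0.0 else float(out))


def allelic_A(psi_allele_1, psi_allele_2):
    """A between the two alleles of an event, per the lower-PSI-first
    convention: the allele with the smaller PSI supplies the starting
    value, so A >= 1 with equality iff the alleles are identical.

    PSI inputs on the 0-1 scale; NaN where either PSI is at the boundary
    or missing.
    """
    p1 = np.asarray(psi_allele_1, dtype=float) * 100.0
    p2 = np.asarray(psi_allele_2, dtype=float) * 100.0
    lo = np.minimum(p1, p2)
    hi = np.maximum(p1, p2)
    ok = (np.isfinite(lo) & np.isfinite(hi)
          & (lo > BOUNDARY_TOL) & (hi < 100.0 - BOUNDARY_TOL))
    out = np.full(np.shape(lo), np.nan)
    if np.any(ok):
        out[ok] = additive_effect(lo[ok], hi[ok] - lo[ok])
    return out


def scaling_bins(calls: pd.DataFrame,
                 variant_density: pd.DataFrame | None = None,
                 reference_allele: str = "BL6",
                 divergent_only: bool = True) -> pd.DataFrame:
    """|dPSI| distributions over ten bins of starting PSI.

    The starting PSI of an event is the mean reference-allele PSI across
    its expressing tissues; |dPSI| per event is the mean |dPSI_allelic|
    over the tissues in which it is divergent (all tested tissues when
    ``divergent_only`` is False, in which case all events enter).
    Returns a per-event frame with bin assignments; empty bins are simply
    absent from it.
    """
    ref_col = {"BL6": "psi_bl6", "SPR": "psi_spr"}[reference_allele]
    rows = []
    for event_id, sub in calls.groupby("event_id"):
        sub = sub.dropna(subset=[ref_col, "delta_psi"])
        if sub.empty:
            continue
        if divergent_only:
            if not sub["divergent"].any():
                continue
            adp = sub.loc[sub["divergent"], "delta_psi"].abs().mean()
        else:
            adp = sub["delta_psi"].abs().mean()
        rows.append((event_id, sub[ref_col].mean(), adp))
    df = pd.DataFrame(rows, columns=["event_id", "psi_start", "abs_delta_psi"])
    if df.empty:
        return df.assign(bin=pd.Series(dtype=int))
    df["bin"] = np.minimum(np.searchsorted(PSI_BINS, df["psi_start"], side="right") - 1,
                           9).astype(int)
    if variant_density is not None:
        df = df.merge(variant_density[["event_id", "variant_density"]],
                      on="event_id", how="left")
    return df


def bin_summary(binned: pd.DataFrame) -> pd.DataFrame:
    """Per-bin medians of |dPSI| (and variant density when present)."""
    agg = {"abs_delta_psi": "median", "event_id": "count"}
    if "variant_density" in binned.columns:
        agg["variant_density"] = "median"
    out = binned.groupby("bin").agg(agg).rename(
        columns={"event_id": "n_events",
                 "abs_delta_psi": "median_abs_delta_psi",
                 "variant_density": "median_variant_density"})
    return out.reset_index()


def scaling_law_test(binned: pd.DataFrame,
                     mid_bins=(4, 5), extreme_bins=(0, 9)) -> tuple:
    """Rank-sum comparison of |dPSI| in the intermediate starting-PSI
    bins against the extreme bins (one-sided: intermediate larger)."""
    mid = binned.loc[binned["bin"].isin(mid_bins), "abs_delta_psi"]
    ext = binned.loc[binned["bin"].isin(extreme_bins), "abs_delta_psi"]
    if len(mid) == 0 or len(ext) == 0:
        return np.nan, np.nan
    res = ranksums(mid, ext, alternative="greater")
    return float(mid.median() - ext.median()), float(res.pvalue)
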