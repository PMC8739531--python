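"""End-to-end orchestration of the analysis stages on one dataset.

Each stage is a thin wrapper over the corresponding module; the driver
scripts, the test suite and the acceptance script all run the pipeline
through this interface so results are computed one way only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ancestry as anc
from . import divergence as dv
from . import downstream as ds
from . import patterns as pt
from . import psi as ps
from . import resample as rs
from . import scaling as sc
from .io import tpm_lookup
from .simulate import PERTURB_TISSUE, SyntheticDataset


@dataclass
class PipelineResult:
    psi: pd.DataFrame
    expressed_total: pd.DataFrame
    expressed_allelic: pd.DataFrame
    calls: pd.DataFrame
    groups: pd.DataFrame
    gene_sds: pd.DataFrame
    switch: pd.DataFrame
    scenarios: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_divergence(dataset: SyntheticDataset, alpha: float = dv.ALPHA,
                   min_delta: float = dv.MIN_DELTA,
                   scenario_cutoff: float = 0.1,
                   apply_consistency: bool = False) -> PipelineResult:
    """Quantify PSI, call per-tissue allelic divergence, and classify
    cross-tissue patterns on the baseline condition."""
    counts = dataset.counts
    lengths = dataset.config.lengths
    psi = ps.psi_table(counts, lengths)
    expressed_total = ps.is_expressed(counts, mode="total",
                                      n_replicates=dataset.config.replicates)
    expressed_allelic = ps.is_expressed(counts, mode="allelic",
                                        n_replicates=dataset.config.replicates)

    expressed = expressed_allelic
    if apply_consistency:
        cons = ps.consistency_filter(counts, lengths)
        ok = cons[cons["consistent"]][["event_id", "tissue"]]
        expressed = expressed.merge(ok, on=["event_id", "tissue"], how="left",
                                    indicator=True)
        expressed["expressed"] &= expressed.pop("_merge").eq("both")

    calls = dv.call_divergence(counts, expressed=expressed, lengths=lengths,
                               alpha=alpha, min_delta=min_delta)
    groups = dv.divergence_groups(calls)
    gene_sds = dv.sds(calls, dataset.truth_events)

    total_psi = psi[psi["allele_set"] == "total"]
    exp_ok = expressed_total[expressed_total["expressed"]][["event_id", "tissue"]]
    tissue_psi = ps.replicate_mean_psi(total_psi).merge(exp_ok, on=["event_id", "tissue"])
    switch = pt.switch_score(tissue_psi)
    scenarios = pt.classify_scenarios(calls, cutoff=scenario_cutoff)
    return PipelineResult(psi=psi, expressed_total=expressed_total,
                          expressed_allelic=expressed_allelic, calls=calls,
                          groups=groups, gene_sds=gene_sds, switch=switch,
                          scenarios=scenarios)


def run_buffering(dataset: SyntheticDataset, result: PipelineResult) -> dict:
    """Expression-buffering analyses: |dPSI| vs TPM correlations and the
    paired expression comparison of Some-Divergent events."""
    tpm = tpm_lookup(dataset.genes)
    per_event, p_rho = dv.buffering_correlation(result.calls, tpm, dataset.truth_events)
    pairs, p_paired = dv.paired_expression_comparison(result.calls, result.groups,
                                                      tpm, dataset.truth_events)
    return {"rho_per_event": per_event, "rho_signed_rank_p": p_rho,
            "paired": pairs, "paired_signed_rank_p": p_paired}


def run_scaling(dataset: SyntheticDataset, result: PipelineResult,
                features: pd.DataFrame | None = None) -> dict:
    """Scaling-law bins and the per-event allelic A scores."""
    binned = sc.scaling_bins(result.calls, variant_density=features)
    med_diff, p = sc.scaling_law_test(binned)
    a_scores = result.calls.assign(
        A=sc.allelic_A(result.calls["psi_bl6"], result.calls["psi_spr"]))
    return {"binned": binned, "bin_summary": sc.bin_summary(binned),
            "median_diff": med_diff, "ranksum_p": p, "a_scores": a_scores}


def run_perturbation(dataset: SyntheticDataset, result: PipelineResult,
                     alpha: float = dv.ALPHA, min_delta: float = dv.MIN_DELTA) -> dict:
    """DMSO vs pladB allelic divergence comparison of the cell line."""
    counts = dataset.counts
    lengths = dataset.config.lengths
    out = {}
    calls = {}
    for cond in ("DMSO", "pladB"):
        exp = ps.is_expressed(counts, mode="allelic", condition=cond,
                              n_replicates=dataset.config.replicates)
        calls[cond] = dv.call_divergence(counts, expressed=exp, lengths=lengths,
                                         condition=cond, alpha=alpha,
                                         min_delta=min_delta)
    tissue_calls = result.calls[result.calls["tissue"] != PERTURB_TISSUE]
    per_event, summary = ds.perturbation_compare(calls["DMSO"], calls["pladB"],
                                                 tissue_calls, min_delta=min_delta)
    out.update({"calls_control": calls["DMSO"], "calls_treatment": calls["pladB"],
                "per_event": per_event, "summary": summary})
    return out


def run_resampling(dataset: SyntheticDataset, result: PipelineResult,
                   n_target: int = rs.N_TARGET, reps: int = 20,
                   seed: int = 0) -> dict:
    """Down-sampling consistency and the replicate-noise statistics."""
    counts = dataset.counts
    lengths = dataset.config.lengths
    allelic = counts[(counts["allele"].isin(("BL6", "SPR")))
                     & (counts["condition"] == "baseline")]
    cons = rs.downsample_consistency(allelic, result.calls, n_target=n_target,
                                     reps=reps, lengths=lengths, seed=seed)

    # replicate |dPSI| vs depth on total-read PSI (replicate pair per cell)
    pooled = ps.pooled_counts(counts, "total")
    wide = pooled.pivot_table(index=["event_id", "tissue"], columns="replicate",
                              values=["inclusion", "skipping"], fill_value=0)
    i1 = wide["inclusion"][1].to_numpy(); s1 = wide["skipping"][1].to_numpy()
    i2 = wide["inclusion"][2].to_numpy(); s2 = wide["skipping"][2].to_numpy()
    adj = rs.adjusted_delta_psi(i1, s1, i2, s2, reps=reps, lengths=lengths, seed=seed)
    p1 = ps.estimate_psi(i1, s1, lengths)
    p2 = ps.estimate_psi(i2, s2, lengths)
    import numpy as np
    raw = np.abs(p1 - p2)
    tot = i1 + s1 + i2 + s2
    ok = np.isfinite(raw) & (tot > 0)
    noise = rs.noise_vs_expression(raw[ok], tot[ok])
    return {"downsample": cons, "adjusted_delta": adj, "raw_delta": raw,
            "total_reads": tot, "noise_fit": noise}


def run_ancestry(dataset: SyntheticDataset, result: PipelineResult) -> dict:
    """Out-group ancestry calls and their agreement with the generator.

    Ancestry is only meaningful for events with allelic divergence, so
    calls are restricted to events divergent in at least one tissue.
    """
    divergent_ids = result.calls.loc[result.calls["divergent"], "event_id"].unique()
    div_calls = result.calls[result.calls["event_id"].isin(divergent_ids)]
    calls = anc.ancestry_calls(div_calls, dataset.outgroup)
    merged = calls.merge(dataset.truth_events[["event_id", "ancestral_allele"]],
                         on="event_id")
    unamb = merged[merged["ancestry"].isin(("BL6-conserved", "SPR-conserved"))]
    correct = (unamb["ancestry"].str.removesuffix("-conserved")
               == unamb["ancestral_allele"])
    recovery = float(correct.mean()) if len(unamb) else float("nan")
    return {"calls": calls, "recovery": recovery, "n_unambiguous": int(len(unamb))}
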