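"""Divergence calls, FDR, groups, SDS and buffering statistics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from allelesplice import divergence as dv


def _counts(rows):
    return pd.DataFrame(rows, columns=[
        "event_id", "tissue", "replicate", "condition", "allele",
        "inclusion", "skipping"])


def bh_stepup(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestDeltaPsi:
    @pytest.mark.parametrize("bl6,spr,expected", [
        ((0.8, 0.8), (0.6, 0.6), 0.2),
        ((0.5, 0.5), (0.5, 0.5), 0.0),
        ((0.3, 0.5), (0.5, 0.5), -0.1),
    ])
    def test_replicate_mean_difference(self, bl6, spr, expected):
        rows = []
        for r, (pb, ps) in enumerate(zip(bl6, spr), start=1):
            # equal effective lengths make PSI the plain count fraction
            rows.append(("e1", "cortex", r, "baseline", "BL6",
                         round(pb * 1000), round((1 - pb) * 1000)))
            rows.append(("e1", "cortex", r, "baseline", "SPR",
                         round(ps * 1000), round((1 - ps) * 1000)))
        from allelesplice.events import EffectiveLengths
        calls = dv.call_divergence(_counts(rows), lengths=EffectiveLengths(1, 1))
        assert calls.loc[0, "delta_psi"] == pytest.approx(expected, abs=1e-9)


class TestFdr:
    def test_bh_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            expected = bh_stepup(p)
            got = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_divergent_flag_combines_fdr_and_effect(self):
        calls = pd.DataFrame({
            "delta_psi": [0.15, 0.05, 0.15],
            "fdr": [0.01, 1e-4, 0.2],
        })
        flag = (calls["fdr"] < 0.05) & (calls["delta_psi"].abs() >= 0.1)
        assert list(flag) == [True, False, False]

    def test_boundary_min_delta_inclusive(self):
        calls = pd.DataFrame({"delta_psi": [0.1], "fdr": [0.01]})
        flag = (calls["fdr"] < 0.05) & (calls["delta_psi"].abs() >= 0.1)
        assert flag.iloc[0]


class TestGroups:
    def _calls(self, divs):
        return pd.DataFrame({
            "event_id": ["e1"] * len(divs),
            "tissue": [f"t{i}" for i in range(len(divs))],
            "divergent": divs,
        })

    @pytest.mark.parametrize("divs,expected", [
        ([True, True, True], "All-Divergent"),
        ([True, False, False], "Some-Divergent"),
        ([False, False, False], "Non-Divergent"),
    ])
    def test_group_rules(self, divs, expected):
        out = dv.divergence_groups(self._calls(divs))
        assert out.loc[0, "group"] == expected

    def test_single_tissue_excluded(self):
        out = dv.divergence_groups(self._calls([True]))
        assert out.empty


class TestSds:
    def _run(self, per_event):
        calls = []
        genes = []
        for i, (d, e) in enumerate(per_event):
            for t in range(e):
                calls.append((f"ev{i}", f"t{t}", t < d))
            genes.append((f"ev{i}", "g1"))
        calls = pd.DataFrame(calls, columns=["event_id", "tissue", "divergent"])
        genes = pd.DataFrame(genes, columns=["event_id", "gene_id"])
        return dv.sds(calls, genes)

    @pytest.mark.parametrize("per_event,score,group", [
        ([(0, 4)], 0.0, "Non-Divergent"),
        ([(2, 4)], 50.0, "High Divergence"),
        ([(1, 2), (0, 3)], 25.0, "Low Divergence"),
    ])
    def test_examples(self, per_event, score, group):
        out = self._run(per_event)
        assert out.loc[0, "sds"] == pytest.approx(score)
        assert out.loc[0, "group"] == group

    def test_range_and_zero_iff_no_divergence(self, std_result, std_dataset):
        out = dv.sds(std_result.calls, std_dataset.truth_events)
        assert out["sds"].between(0, 100).all()
        per_gene_div = (std_result.calls
                        .merge(std_dataset.truth_events[["event_id", "gene_id"]],
                               on="event_id")
                        .groupby("gene_id")["divergent"].any())
        merged = out.set_index("gene_id").join(per_gene_div, how="left")
        zero = merged["sds"] == 0
        # SDS = 0 exactly for genes with no divergent event anywhere
        # (restricted to the qualifying events counted by the score)
        assert (zero == ~merged["divergent"]).mean() > 0.95


class TestBuffering:
    def test_perfect_antimonotone_rho(self):
        calls = pd.DataFrame({
            "event_id": ["e1"] * 3, "tissue": ["t1", "t2", "t3"],
            "delta_psi": [0.3, 0.2, 0.1], "divergent": [True, False, False]})
        tpm = pd.DataFrame({"gene_id": ["g1"] * 3, "tissue": ["t1", "t2", "t3"],
                            "tpm": [1.0, 10.0, 100.0]})
        genes = pd.DataFrame({"event_id": ["e1"], "gene_id": ["g1"]})
        per_event, _ = dv.buffering_correlation(calls, tpm, genes)
        assert per_event.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_delta_gives_absent_rho(self):
        calls = pd.DataFrame({
            "event_id": ["e1"] * 3, "tissue": ["t1", "t2", "t3"],
            "delta_psi": [0.2, 0.2, 0.2], "divergent": [True, False, False]})
        tpm = pd.DataFrame({"gene_id": ["g1"] * 3, "tissue": ["t1", "t2", "t3"],
                            "tpm": [1.0, 10.0, 100.0]})
        genes = pd.DataFrame({"event_id": ["e1"], "gene_id": ["g1"]})
        per_event, _ = dv.buffering_correlation(calls, tpm, genes)
        assert np.isnan(per_event.loc[0, "rho"])

    def test_paired_expression_pairs(self):
        calls = pd.DataFrame({
            "event_id": ["e1"] * 2, "tissue": ["t1", "t2"],
            "delta_psi": [0.3, 0.0], "divergent": [True, False]})
        groups = pd.DataFrame({"event_id": ["e1"], "group": ["Some-Divergent"]})
        tpm = pd.DataFrame({"gene_id": ["g1"] * 2, "tissue": ["t1", "t2"],
                            "tpm": [5.0, 50.0]})
        genes = pd.DataFrame({"event_id": ["e1"], "gene_id": ["g1"]})
        pairs, _ = dv.paired_expression_comparison(calls, groups, tpm, genes)
        assert pairs.loc[0, "tpm_divergent"] == pytest.approx(5.0)
        assert pairs.loc[0, "tpm_nondivergent"] == pytest.approx(50.0)
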