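"""PSI/PDI estimation and the expression / constitutive / consistency filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allelesplice.events import EffectiveLengths
from allelesplice.psi import (
    compute_pdi,
    consistency_filter,
    estimate_psi,
    filter_constitutive,
    is_expressed,
    psi_table,
)


def _counts(rows):
    return pd.DataFrame(rows, columns=[
        "event_id", "tissue", "replicate", "condition", "allele",
        "inclusion", "skipping"])


class TestEstimatePsi:
    @pytest.mark.parametrize("I,S,L_I,L_S,expected", [
        (0, 10, 2.0, 1.0, 0.0),
        (10, 0, 2.0, 1.0, 1.0),
        (30, 10, 2.0, 1.0, 15 / 25),
        (30, 10, 1.0, 1.0, 0.75),
    ])
    def test_examples(self, I, S, L_I, L_S, expected):
        psi = estimate_psi(I, S, EffectiveLengths(L_I, L_S))
        assert psi == pytest.approx(expected)

    def test_zero_reads_is_absent_not_zero(self):
        assert np.isnan(estimate_psi(0, 0))

    @given(I=st.integers(0, 10_000), S=st.integers(0, 10_000))
    def test_equal_lengths_reduce_to_fraction(self, I, S):
        if I + S == 0:
            return
        psi = estimate_psi(I, S, EffectiveLengths(1.0, 1.0))
        assert psi == pytest.approx(I / (I + S))

    @given(S=st.integers(1, 500), I=st.integers(0, 500))
    def test_monotone_in_inclusion(self, S, I):
        lengths = EffectiveLengths()
        assert estimate_psi(I + 1, S, lengths) > estimate_psi(I, S, lengths)


class TestPdi:
    @pytest.mark.parametrize("psi,expected", [(0.5, 0.5), (0.2, 0.8), (1.0, 1.0)])
    def test_examples(self, psi, expected):
        assert compute_pdi(psi) == pytest.approx(expected)

    @given(psi=st.floats(0, 1))
    def test_symmetry_and_range(self, psi):
        pdi = compute_pdi(psi)
        assert pdi == pytest.approx(compute_pdi(1 - psi))
        assert 0.5 <= pdi <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_pdi(1.2)


class TestExpressionFilter:
    def test_total_mode_uses_common_reads_and_min_20(self):
        rows = []
        for rep, (i_allelic, i_common) in enumerate([(10, 15), (10, 9)], start=1):
            rows.append(("e1", "cortex", rep, "baseline", "BL6", i_allelic, 0))
            rows.append(("e1", "cortex", rep, "baseline", "common", i_common, 0))
        flags = is_expressed(_counts(rows), mode="total")
        # replicate totals 25 and 19: one below 20 -> not expressed
        assert not flags["expressed"].iloc[0]

    def test_boundary_20_is_expressed(self):
        rows = [("e1", "cortex", r, "baseline", "BL6", 20, 0) for r in (1, 2)]
        flags = is_expressed(_counts(rows), mode="total")
        assert flags["expressed"].iloc[0]

    def test_allelic_mode_requires_each_allele(self):
        rows = []
        for r in (1, 2):
            rows.append(("e1", "cortex", r, "baseline", "BL6", 30, 30))
            rows.append(("e1", "cortex", r, "baseline", "SPR", 5, 10))
        flags = is_expressed(_counts(rows), mode="allelic")
        assert not flags["expressed"].iloc[0]
        rows = []
        for r in (1, 2):
            rows.append(("e2", "cortex", r, "baseline", "BL6", 30, 30))
            rows.append(("e2", "cortex", r, "baseline", "SPR", 15, 10))
        flags = is_expressed(_counts(rows), mode="allelic")
        assert flags["expressed"].iloc[0]

    def test_missing_replicate_not_expressed(self):
        rows = [("e1", "cortex", 1, "baseline", "BL6", 50, 50)]
        flags = is_expressed(_counts(rows), mode="total", n_replicates=2)
        assert not flags["expressed"].iloc[0]


class TestConstitutiveFilter:
    def _frames(self, psis_by_allele_set):
        psi_rows, exp_rows = [], []
        tissues = set()
        for aset, cells in psis_by_allele_set.items():
            for (tissue, rep), value in cells.items():
                psi_rows.append(("e1", tissue, rep, aset, value))
                tissues.add(tissue)
        psi = pd.DataFrame(psi_rows, columns=[
            "event_id", "tissue", "replicate", "allele_set", "psi"])
        expressed = pd.DataFrame(
            [("e1", t, True) for t in sorted(tissues)],
            columns=["event_id", "tissue", "expressed"])
        return psi, expressed

    def test_all_high_dropped(self):
        psi, exp = self._frames({"total": {
            ("cortex", 1): 0.95, ("cortex", 2): 0.97,
            ("heart", 1): 0.96, ("heart", 2): 0.99}})
        out = filter_constitutive(psi, exp, mode="total")
        assert out.loc[0, "constitutive"]

    def test_mixed_kept(self):
        psi, exp = self._frames({"total": {
            ("cortex", 1): 0.95, ("cortex", 2): 0.95,
            ("heart", 1): 0.6, ("heart", 2): 0.6}})
        out = filter_constitutive(psi, exp, mode="total")
        assert not out.loc[0, "constitutive"]

    def test_allelic_mode_needs_both_alleles_extreme(self):
        cells_high = {("cortex", 1): 0.95, ("cortex", 2): 0.97}
        psi, exp = self._frames({
            "allelic": cells_high, "total": cells_high, "BL6": cells_high,
            "SPR": {("cortex", 1): 0.85, ("cortex", 2): 0.97}})
        out = filter_constitutive(psi, exp, mode="allelic")
        assert not out.loc[0, "constitutive"]  # SPR is not all-extreme


class TestConsistencyFilter:
    def test_consistent_vs_biased_common_reads(self):
        rows = []
        for r in (1, 2):
            # e1: common reads agree with allelic reads
            rows += [("e1", "cortex", r, "baseline", "BL6", 50, 50),
                     ("e1", "cortex", r, "baseline", "SPR", 50, 50),
                     ("e1", "cortex", r, "baseline", "common", 200, 200)]
            # e2: common reads tell a very different story
            rows += [("e2", "cortex", r, "baseline", "BL6", 50, 50),
                     ("e2", "cortex", r, "baseline", "SPR", 50, 50),
                     ("e2", "cortex", r, "baseline", "common", 1200, 20)]
        out = consistency_filter(_counts(rows)).set_index("event_id")
        assert out.loc["e1", "consistent"]
        assert not out.loc["e2", "consistent"]

    def test_both_conditions_required(self):
        # delta below 0.1 but significant fdr still drops the event; the
        # decision combines |delta| <= 0.1 AND fdr > 0.5
        out = pd.DataFrame({"delta": [0.05, 0.2, 0.05], "fdr": [0.8, 0.9, 0.3]})
        keep = (out["delta"].abs() <= 0.1) & (out["fdr"] > 0.5)
        assert list(keep) == [True, False, False]


class TestPsiTable:
    def test_psi_close_to_truth_at_high_depth(self):
        # null generator at depth 1e4: estimate within 0.02 of truth for
        # nearly all event x sample cells
        from allelesplice.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_events=300, cis_fraction=0.0, rho0=1e-6,
                               buffering_gamma=0.0, depth_per_tpm=200.0,
                               log_tpm_sd=0.0, tissue_tpm_sd=0.0,
                               depth_noise_sd=0.0)
        ds = simulate_dataset(cfg, seed=2)
        psi = psi_table(ds.counts, allele_sets=("BL6",))
        truth = ds.truth_tissue.set_index(["event_id", "tissue"])["psi_bl6"]
        merged = psi.join(truth, on=["event_id", "tissue"]).dropna(subset=["psi"])
        err = (merged["psi"] - merged["psi_bl6"]).abs()
        assert (err < 0.02).mean() >= 0.99
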