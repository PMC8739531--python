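"""Switch scores, the four-scenario classifier and pattern summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allelesplice import patterns as pt


def brute_force_scenario(db, ds, cutoff):
    """Independent enumeration of the scenario rules."""
    over_b = abs(db) > cutoff
    over_s = abs(ds) > cutoff
    if over_b and over_s and np.sign(db) != np.sign(ds):
        return 1
    if over_b and over_s:
        return 2
    if over_b != over_s:
        return 3
    return 4


class TestSwitchScore:
    @pytest.mark.parametrize("psis,score,group", [
        ([0.2, 0.8], 0.6, "Switch-Like"),
        ([0.4, 0.4, 0.4], 0.0, "Non-Differential"),
        ([0.50, 0.62], 0.12, "Low"),
        ([0.5, 0.75], 0.25, "Moderate-Low"),
        ([0.1, 0.45], 0.35, "Moderate-High"),
        ([0.0, 0.5], 0.5, "Switch-Like"),  # boundary: >= 0.5
    ])
    def test_examples_and_boundaries(self, psis, score, group):
        df = pd.DataFrame({"event_id": "e1", "tissue": [f"t{i}" for i in range(len(psis))],
                           "psi": psis})
        out = pt.switch_score(df)
        assert out.loc[0, "switch_score"] == pytest.approx(score)
        assert out.loc[0, "group"] == group

    def test_single_tissue_absent(self):
        df = pd.DataFrame({"event_id": ["e1"], "tissue": ["t1"], "psi": [0.5]})
        assert pt.switch_score(df).empty

    @given(psis=st.lists(st.floats(0, 1), min_size=2, max_size=7))
    def test_equals_max_minus_min_and_permutation_invariant(self, psis):
        df = pd.DataFrame({"event_id": "e1",
                           "tissue": [f"t{i}" for i in range(len(psis))],
                           "psi": psis})
        out = pt.switch_score(df)
        assert out.loc[0, "switch_score"] == pytest.approx(max(psis) - min(psis))
        shuffled = df.iloc[::-1].reset_index(drop=True)
        out2 = pt.switch_score(shuffled)
        assert out2.loc[0, "switch_score"] == out.loc[0, "switch_score"]


class TestScenarioClassifier:
    @pytest.mark.parametrize("db,ds,cutoff,expected", [
        (0.30, -0.20, 0.1, 1),
        (0.30, 0.25, 0.1, 2),
        (0.30, 0.05, 0.1, 3),
        (0.05, -0.05, 0.1, 4),
        (0.1, 0.1, 0.1, 4),  # strict >: at the cutoff counts as not over
    ])
    def test_rule_examples(self, db, ds, cutoff, expected):
        assert pt.classify_scenario_pair(db, ds, cutoff) == expected

    def test_exact_agreement_with_brute_force_grid(self):
        grid = np.round(np.arange(-0.5, 0.5001, 0.01), 10)
        for cutoff in (0.1, 0.15, 0.2):
            for db in grid:
                for ds in grid:
                    assert (pt.classify_scenario_pair(db, ds, cutoff)
                            == brute_force_scenario(db, ds, cutoff))

    def test_monotone_in_cutoff(self):
        # raising the cutoff never moves an event out of scenario 4
        rng = np.random.default_rng(0)
        for _ in range(2000):
            db, ds = rng.uniform(-0.5, 0.5, 2)
            s_low = pt.classify_scenario_pair(db, ds, 0.1)
            s_high = pt.classify_scenario_pair(db, ds, 0.2)
            if s_low == 4:
                assert s_high == 4

    def test_pair_selection_maximizes_ddpsi(self):
        calls = pd.DataFrame({
            "event_id": "e1",
            "tissue": ["a", "b", "c"],
            "psi_bl6": [0.9, 0.5, 0.5],
            "psi_spr": [0.5, 0.5, 0.5],
            "delta_psi": [0.4, 0.0, 0.0],
            "divergent": [True, False, False],
        })
        out = pt.classify_scenarios(calls, cutoff=0.1)
        # ddPSI is 0.4 for (a,b) and (a,c), 0 for (b,c); lexicographic tie-break
        assert (out.loc[0, "tissue_1"], out.loc[0, "tissue_2"]) == ("a", "b")
        assert out.loc[0, "ddpsi"] == pytest.approx(0.4)
        assert out.loc[0, "scenario"] == 3  # only BL6 changes between tissues

    def test_requires_divergence_and_two_tissues(self):
        calls = pd.DataFrame({
            "event_id": ["e1", "e1"], "tissue": ["a", "b"],
            "psi_bl6": [0.9, 0.5], "psi_spr": [0.5, 0.5],
            "delta_psi": [0.4, 0.0], "divergent": [False, False]})
        assert pt.classify_scenarios(calls).empty


class TestSummaries:
    def test_scenario_magnitude_medians(self):
        sc = pd.DataFrame({
            "event_id": ["a", "b"], "scenario": [2, 3],
            "dpsi_t_bl6": [0.45, 0.17], "dpsi_t_spr": [0.40, 0.01]})
        medians, p = pt.scenario_magnitudes(sc)
        assert medians[2] == pytest.approx(0.45)
        assert medians[3] == pytest.approx(0.17)

    def test_microexon_odds_ratio(self):
        cats = pd.DataFrame({"event_id": [f"e{i}" for i in range(120)],
                             "category": ["S2"] * 20 + ["other"] * 100})
        events = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(120)],
            "microexon": [True] * 10 + [False] * 10 + [True] * 10 + [False] * 90})
        out = pt.microexon_enrichment(cats, events).set_index("category")
        assert out.loc["S2", "odds_ratio"] == pytest.approx(9.0)

    def test_microexon_identical_proportions(self):
        cats = pd.DataFrame({"event_id": [f"e{i}" for i in range(40)],
                             "category": ["A"] * 20 + ["B"] * 20})
        events = pd.DataFrame({"event_id": [f"e{i}" for i in range(40)],
                               "microexon": ([True] * 5 + [False] * 15) * 2})
        out = pt.microexon_enrichment(cats, events).set_index("category")
        assert out.loc["A", "odds_ratio"] == pytest.approx(1.0)

    def test_pairwise_pattern_proportions(self):
        rows = []
        for i, (sel, oth) in enumerate([(True, False), (False, True),
                                        (True, True), (False, False)]):
            rows.append((f"e{i}", "brain", sel))
            rows.append((f"e{i}", "liver", oth))
        calls = pd.DataFrame(rows, columns=["event_id", "tissue", "divergent"])
        out = pt.pairwise_divergence_pattern("brain", calls)
        assert out["selected-only"] == pytest.approx(0.25)
        assert out["neither"] == pytest.approx(0.25)
        assert out.sum() == pytest.approx(1.0)

    def test_pairwise_pattern_all_neither(self):
        rows = [("e1", "brain", False), ("e1", "liver", False)]
        calls = pd.DataFrame(rows, columns=["event_id", "tissue", "divergent"])
        out = pt.pairwise_divergence_pattern("brain", calls)
        assert out["neither"] == 1.0

    def test_allele_switch_concordance_cells(self):
        switch = pd.DataFrame({"event_id": ["e1"], "allele": ["BL6"],
                               "group": ["Switch-Like"]})
        groups = pd.DataFrame({"event_id": ["e1"], "group": ["Non-Divergent"]})
        tab = pt.allele_switch_concordance(switch, groups)
        assert tab.loc["Switch-Like", "Non-Divergent"] == 1

    def test_scenario2_events_have_larger_spans(self, std_result):
        medians, p = pt.scenario_magnitudes(std_result.scenarios)
        if 2 in medians.index and 3 in medians.index:
            assert medians[2] > medians[3]
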