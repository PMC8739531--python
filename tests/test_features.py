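"""Variant density, splice-site windows, PWM scoring, conservation."""

import numpy as np
import pandas as pd
import pytest

from allelesplice import features as ft
from allelesplice.events import Interval, SpliceEvent, Variant
from allelesplice.io import ConservationTrack


def make_event(strand="+", alt=(1000, 1100), up=(100, 200), down=(1900, 2000),
               event_id="e1"):
    return SpliceEvent(event_id, "g1", "chr1", strand,
                       Interval(*up), Interval(*alt), Interval(*down))


class TestVariantDensity:
    def test_five_snvs_in_500nt_region(self):
        ev = make_event()  # 100 nt exon, introns 800 nt each: full 200 nt flanks
        variants = [Variant("chr1", p, "A", "G") for p in (850, 950, 1050, 1150, 1250)]
        assert ft.variant_density(ev, variants) == pytest.approx(5 / 500)

    def test_no_variants_zero(self):
        assert ft.variant_density(make_event(), []) == 0.0

    def test_indel_counted_once(self):
        ev = make_event()
        variants = [Variant("chr1", 1050, "A" * 10, "A")]  # 10 nt deletion
        assert ft.variant_density(ev, variants) == pytest.approx(1 / 500)

    def test_outside_region_not_counted(self):
        ev = make_event()
        variants = [Variant("chr1", 500, "A", "G")]  # beyond the 200 nt flank
        assert ft.variant_density(ev, variants) == 0.0

    def test_flank_clipped_at_neighbor_exon(self):
        ev = make_event(up=(700, 900), down=(1150, 1300))  # introns 100 and 50 nt
        # region: 100 + 100 + 50 nt
        variants = [Variant("chr1", 910, "A", "G")]
        assert ft.variant_density(ev, variants) == pytest.approx(1 / 250)

    def test_strand_flip_invariant(self):
        variants = [Variant("chr1", p, "A", "G") for p in (850, 1050)]
        assert (ft.variant_density(make_event("+"), variants)
                == ft.variant_density(make_event("-"), variants))


class TestSpliceSiteWindows:
    def test_plus_strand_hand_mapped(self):
        win = ft.splice_site_windows(make_event("+"))
        assert (win["donor"].start, win["donor"].end) == (1097, 1106)
        assert (win["acceptor"].start, win["acceptor"].end) == (986, 1001)

    def test_minus_strand_mirror(self):
        win = ft.splice_site_windows(make_event("-"))
        assert (win["donor"].start, win["donor"].end) == (994, 1003)
        assert (win["acceptor"].start, win["acceptor"].end) == (1099, 1114)

    def test_window_lengths_nine_and_fifteen(self):
        for strand in "+-":
            win = ft.splice_site_windows(make_event(strand))
            assert len(win["donor"]) == 9
            assert len(win["acceptor"]) == 15

    def test_windows_clip_at_neighbor_exons(self):
        ev = make_event("+", alt=(1000, 1100), up=(100, 998), down=(1103, 1200))
        win = ft.splice_site_windows(ev)
        assert win["donor"].end == 1103
        assert win["acceptor"].start == 998

    def test_tiny_exon_truncated(self):
        ev = make_event("+", alt=(1000, 1002))
        win = ft.splice_site_windows(ev)
        assert win["donor"] == Interval(1000, 1008)  # 2 exonic + 6 intronic

    def test_variant_flag(self):
        ev = make_event("+")
        assert ft.splice_site_variant_flag(ev, [Variant("chr1", 1100, "G", "T")])
        assert not ft.splice_site_variant_flag(ev, [Variant("chr1", 1150, "G", "T")])
        # deletion spanning the window edge overlaps
        assert ft.splice_site_variant_flag(ev, [Variant("chr1", 1104, "GAAA", "G")])


class TestPwmScorer:
    def test_identical_sequences_zero_delta(self):
        scorer = ft.PwmScorer.train(["CAGGTAAGT"] * 5, ["TTTTTTTTTTTTAGG"] * 5)
        assert ft.splice_strength_delta("CAGGTAAGT", "TTTTTTTTTTTTAGG",
                                        "CAGGTAAGT", "TTTTTTTTTTTTAGG",
                                        scorer) == 0.0

    def test_gt_disruption_scores_positive_delta(self):
        donors = ["CAGGTAAGT", "AAGGTAAGT", "CCGGTAAGT", "CAGGTACGT"]
        acceptors = ["TTTTTTTTTTTTAGG"] * 4
        scorer = ft.PwmScorer.train(donors, acceptors)
        delta = ft.splice_strength_delta(
            "CAGGTAAGT", acceptors[0], "CAGTTAAGT", acceptors[0], scorer)
        assert delta > 0

    def test_length_mismatch_rejected(self):
        scorer = ft.PwmScorer.train(["CAGGTAAGT"], ["TTTTTTTTTTTTAGG"])
        with pytest.raises(ValueError):
            scorer.score_donor("CAGGT")


class TestAnnotationOverlays:
    def test_coding_overlap(self):
        ev = make_event()
        assert ft.coding_overlap(ev, [Interval(900, 1200)])
        assert not ft.coding_overlap(ev, [Interval(100, 200)])

    def test_conservation_summary_uniform(self):
        track = ConservationTrack(pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [5000], "score": [0.95]}))
        assert ft.conservation_summary(make_event(), track) == pytest.approx(0.95)

    def test_conservation_summary_sparse_absent(self):
        track = ConservationTrack(pd.DataFrame(
            {"chrom": ["chr1"], "start": [1000], "end": [1020], "score": [0.9]}))
        assert np.isnan(ft.conservation_summary(make_event(), track))


class TestConservationProfile:
    def _track_step(self):
        # 1.0 on the exon, 0.0 on introns
        return ConservationTrack(pd.DataFrame({
            "chrom": ["chr1"] * 3,
            "start": [0, 1000, 1100],
            "end": [1000, 1100, 5000],
            "score": [0.0, 1.0, 0.0]}))

    def test_step_profile(self):
        ev = make_event()
        prof = ft.conservation_profile([ev], self._track_step(), {"e1": "grp"})
        vals = prof["mean_score"].to_numpy()
        assert len(vals) == 460
        np.testing.assert_allclose(vals[:200], 0.0)        # acceptor intron
        np.testing.assert_allclose(vals[200:260], 1.0)     # exon ends
        np.testing.assert_allclose(vals[260:], 0.0)        # donor intron

    def test_minus_strand_reverses(self):
        track = ConservationTrack(pd.DataFrame({
            "chrom": ["chr1"], "start": [780], "end": [820], "score": [1.0]}))
        plus = ft.conservation_profile([make_event("+")], track, {"e1": "g"})
        minus = ft.conservation_profile([make_event("-")], track, {"e1": "g"})
        p = np.nan_to_num(plus["mean_score"].to_numpy())
        m = np.nan_to_num(minus["mean_score"].to_numpy())
        np.testing.assert_allclose(p, m[::-1])

    def test_short_exon_excluded(self):
        ev = make_event(alt=(1000, 1059))  # 59 nt < 60
        prof = ft.conservation_profile([ev], self._track_step(), {"e1": "grp"})
        assert prof.empty

    def test_short_intron_excluded(self):
        ev = make_event(up=(850, 950))  # upstream intron 50 nt
        prof = ft.conservation_profile([ev], self._track_step(), {"e1": "grp"})
        assert prof.empty


class TestEventFeatures:
    def test_table_on_synthetic_dataset(self, small_dataset):
        feats = ft.event_features(small_dataset.events, small_dataset.variants,
                                  track=small_dataset.conservation)
        assert len(feats) == len(small_dataset.events)
        assert (feats["variant_density"] >= 0).all()
        truth = small_dataset.truth_events
        merged = feats.merge(truth, on="event_id", suffixes=("", "_truth"))
        assert (merged["microexon"] == merged["microexon_truth"]).all()

    def test_variant_density_tracks_cis_effect(self, std_dataset):
        feats = ft.event_features(std_dataset.events, std_dataset.variants)
        merged = feats.merge(std_dataset.truth_events, on="event_id", suffixes=("", "_t"))
        has_cis = merged["cis_effect"].abs() > 0
        assert (merged.loc[has_cis, "variant_density"].mean()
                > merged.loc[~has_cis, "variant_density"].mean())
        # splice-site variants are enriched among cis-affected events
        assert (merged.loc[has_cis, "has_splice_site_variant"].mean()
                > merged.loc[~has_cis, "has_splice_site_variant"].mean())
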