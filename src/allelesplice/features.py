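"""Sequence features of skipped-exon events: variant density, splice-site
windows and variant flags, pluggable splice-site strength scoring, CDS
overlap, and conservation summaries / positional meta-profiles.

Splice-site windows follow the canonical definitions: the donor (5'
splice site) window covers the last 3 exonic and first 6 intronic
nucleotides (9 nt, positions -3..+6), the acceptor (3' splice site)
window the last 14 intronic and first exonic nucleotide (15 nt,
positions -14..+1). Windows are computed strand-aware and clipped at the
neighbouring constitutive exons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import Interval, SpliceEvent, Variant
from .io import ConservationTrack

log = logging.getLogger(__name__)

FLANK = 200          # nt of intron on each side of the alternative exon
DONOR_EXONIC = 3     # donor window: last 3 exonic nt ...
DONOR_INTRONIC = 6   # ... plus first 6 intronic nt
ACCEPTOR_INTRONIC = 14
ACCEPTOR_EXONIC = 1
PROFILE_EXON = 30    # meta-profile: 30 nt at each exon end + FLANK introns


def flank_regions(event: SpliceEvent, flank: int = FLANK) -> list[Interval]:
    """Alt exon plus up to ``flank`` intronic nt per side, clipped at the
    neighbouring exons."""
    up = Interval(max(event.upstream_exon.end, event.alt_exon.start - flank),
                  event.alt_exon.start) if event.alt_exon.start > event.upstream_exon.end else None
    down = (Interval(event.alt_exon.end,
                     min(event.downstream_exon.start, event.alt_exon.end + flank))
            if event.downstream_exon.start > event.alt_exon.end else None)
    regions = [r for r in (up, event.alt_exon, down) if r is not None]
    return regions


def variant_density(event: SpliceEvent, variants: list[Variant],
                    flank: int = FLANK) -> float:
    """Variants per nt over alt exon + intronic flanks; any overlap with
    the region counts a variant once, indels irrespective of length."""
    regions = flank_regions(event, flank)
    length = sum(len(r) for r in regions)
    if length == 0:
        raise ValueError(f"{event.event_id}: zero-length feature region")
    n = sum(
        1 for v in variants
        if v.chrom == event.chrom and any(v.span.overlaps(r) for r in regions)
    )
    return n / length


def splice_site_windows(event: SpliceEvent) -> dict:
    """Donor and acceptor windows of the alternative exon as genomic
    intervals (strand-aware; exonic portions truncated for tiny exons,
    intronic portions clipped at the neighbouring exons)."""
    exon = event.alt_exon
    ex_d = min(DONOR_EXONIC, len(exon))
    ex_a = min(ACCEPTOR_EXONIC, len(exon))
    if ex_d < DONOR_EXONIC:
        log.warning("%s: alt exon shorter than donor-window exonic portion; truncated",
                    event.event_id)
    if event.strand == "+":
        donor = Interval(exon.end - ex_d,
                         min(exon.end + DONOR_INTRONIC, event.downstream_exon.start))
        acceptor = Interval(max(exon.start - ACCEPTOR_INTRONIC, event.upstream_exon.end),
                            exon.start + ex_a)
    else:
        donor = Interval(max(exon.start - DONOR_INTRONIC, event.upstream_exon.end),
                         exon.start + ex_d)
        acceptor = Interval(exon.end - ex_a,
                            min(exon.end + ACCEPTOR_INTRONIC, event.downstream_exon.start))
    return {"donor": donor, "acceptor": acceptor}


def splice_site_variant_flag(event: SpliceEvent, variants: list[Variant]) -> bool:
    """True iff any variant overlaps the donor or acceptor window."""
    win = splice_site_windows(event)
    return any(
        v.chrom == event.chrom
        and (v.span.overlaps(win["donor"]) or v.span.overlaps(win["acceptor"]))
        for v in variants
    )


# ---------------------------------------------------------------------------
# splice-site strength scoring (pluggable)


@dataclass
class PwmScorer:
    """Position-weight-matrix splice-site scorer.

    Log2-odds of per-position base frequencies (with a pseudocount)
    against a uniform background, estimated separately for donor and
    acceptor windows from a training set of window sequences. Scores from
    different scorers are not comparable.
    """

    donor_pwm: np.ndarray      # (window length, 4)
    acceptor_pwm: np.ndarray

    _BASES = {"A": 0, "C": 1, "G": 2, "T": 3}

    @classmethod
    def train(cls, donor_seqs: list[str], acceptor_seqs: list[str],
              pseudocount: float = 0.5) -> "PwmScorer":
        return cls(cls._pwm(donor_seqs, pseudocount), cls._pwm(acceptor_seqs, pseudocount))

    @classmethod
    def _pwm(cls, seqs: list[str], pseudocount: float) -> np.ndarray:
        if not seqs:
            raise ValueError("no training sequences")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("training sequences of unequal length")
        counts = np.full((L, 4), pseudocount)
        for s in seqs:
            for i, base in enumerate(s.upper()):
                if base in cls._BASES:
                    counts[i, cls._BASES[base]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        return np.log2(freqs / 0.25)

    def _score(self, seq: str, pwm: np.ndarray) -> float:
        if len(seq) != pwm.shape[0]:
            raise ValueError(f"sequence length {len(seq)} != window length {pwm.shape[0]}")
        return float(sum(pwm[i, self._BASES[b]] for i, b in enumerate(seq.upper())
                         if b in self._BASES))

    def score_donor(self, seq: str) -> float:
        return self._score(seq, self.donor_pwm)

    def score_acceptor(self, seq: str) -> float:
        return self._score(seq, self.acceptor_pwm)


def splice_strength_delta(donor_bl6: str, acceptor_bl6: str,
                          donor_spr: str, acceptor_spr: str,
                          scorer: PwmScorer) -> float:
    """Summed absolute allelic difference of donor + acceptor strength."""
    d5 = abs(scorer.score_donor(donor_bl6) - scorer.score_donor(donor_spr))
    d3 = abs(scorer.score_acceptor(acceptor_bl6) - scorer.score_acceptor(acceptor_spr))
    return d5 + d3


# ---------------------------------------------------------------------------
# annotation overlays


def coding_overlap(event: SpliceEvent, cds_intervals: list[Interval]) -> bool:
    """True iff the alternative exon overlaps any CDS interval."""
    return any(event.alt_exon.overlaps(c) for c in cds_intervals)


def conservation_summary(event: SpliceEvent, track: ConservationTrack,
                         min_coverage: float = 0.5) -> float:
    """Mean conservation over the alternative exon; NaN when fewer than
    ``min_coverage`` of its bases are scored."""
    return track.mean(event.chrom, event.alt_exon.start, event.alt_exon.end,
                      min_coverage=min_coverage)


def conservation_profile(events: list[SpliceEvent], track: ConservationTrack,
                         groups: dict, min_exon: int = 60,
                         min_intron: int = FLANK) -> pd.DataFrame:
    """Positional conservation meta-profile per event group.

    Uses only events with alt exon >= min_exon nt and both flanking
    introns >= min_intron nt. The 460-position profile runs 5'->3' of the
    transcript: 200 nt acceptor-side intron, 30 nt exon start, 30 nt exon
    end, 200 nt donor-side intron. Returns a long frame (group, position,
    mean_score, n_events); groups with no qualifying event are absent.
    """
    per_group: dict = {}
    for ev in events:
        if ev.exon_length < min_exon:
            continue
        if len(ev.upstream_intron) < min_intron or len(ev.downstream_intron) < min_intron:
            continue
        a, b = ev.alt_exon.start, ev.alt_exon.end
        segs = [(a - FLANK, a), (a, a + PROFILE_EXON), (b - PROFILE_EXON, b), (b, b + FLANK)]
        vals = np.concatenate([track.per_base(ev.chrom, s, e) for s, e in segs])
        if ev.strand == "-":
            vals = vals[::-1]
        grp = groups.get(ev.event_id)
        if grp is None:
            continue
        per_group.setdefault(grp, []).append(vals)
    rows = []
    for grp, mats in per_group.items():
        mat = np.vstack(mats)
        finite = np.isfinite(mat)
        n_fin = finite.sum(axis=0)
        mean = np.where(n_fin > 0,
                        np.where(finite, mat, 0.0).sum(axis=0) / np.maximum(n_fin, 1),
                        np.nan)
        for pos, m in enumerate(mean):
            rows.append((grp, pos, m, mat.shape[0]))
    return pd.DataFrame(rows, columns=["group", "position", "mean_score", "n_events"])


class VariantIndex:
    """Sorted per-chromosome variant spans for fast overlap counting."""

    def __init__(self, variants: list[Variant]):
        self._by_chrom: dict = {}
        grouped: dict = {}
        for v in variants:
            grouped.setdefault(v.chrom, []).append((v.pos, v.pos + max(1, len(v.ref))))
        for chrom, spans in grouped.items():
            spans.sort()
            starts = np.array([s for s, _ in spans])
            ends = np.array([e for _, e in spans])
            self._by_chrom[chrom] = (starts, ends, int((ends - starts).max()))

    def count(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._by_chrom:
            return 0
        starts, ends, max_span = self._by_chrom[chrom]
        lo = np.searchsorted(starts, start - max_span, side="left")
        hi = np.searchsorted(starts, end, side="left")
        return int((ends[lo:hi] > start).sum())

    def any(self, chrom: str, start: int, end: int) -> bool:
        return self.count(chrom, start, end) > 0


def event_features(events: list[SpliceEvent], variants: list[Variant],
                   track: ConservationTrack | None = None,
                   cds_by_gene: dict | None = None) -> pd.DataFrame:
    """Per-event feature table: variant density, splice-site variant flag,
    coding overlap, micro-exon flag, exon mean conservation."""
    index = VariantIndex(variants)
    rows = []
    for ev in events:
        regions = flank_regions(ev)
        # exon and clipped flanks are contiguous: one union interval
        start = min(r.start for r in regions)
        end = max(r.end for r in regions)
        length = sum(len(r) for r in regions)
        dens = index.count(ev.chrom, start, end) / length
        win = splice_site_windows(ev)
        ssv = (index.any(ev.chrom, win["donor"].start, win["donor"].end)
               or index.any(ev.chrom, win["acceptor"].start, win["acceptor"].end))
        coding = (coding_overlap(ev, cds_by_gene.get(ev.gene_id, []))
                  if cds_by_gene is not None else False)
        cons = (conservation_summary(ev, track) if track is not None else np.nan)
        rows.append((ev.event_id, dens, ssv, coding, ev.is_microexon, cons))
    return pd.DataFrame(rows, columns=[
        "event_id", "variant_density", "has_splice_site_variant",
        "coding", "microexon", "exon_mean_phastcons"])
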