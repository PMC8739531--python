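"""Domain types for skipped-exon (SE) events and their annotations.

All genomic coordinates in this package are 0-based, half-open, on the
forward strand of the reference. Strand-dependent arithmetic (splice-site
windows, conservation profiles) is handled by strand-aware helpers so that
no other module needs to branch on strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

MICROEXON_MAX_LENGTH = 30  # nt; alternative exons at or below this are micro-exons

ALLELES = ("BL6", "SPR", "common")
CONDITIONS = ("baseline", "DMSO", "pladB")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class SpliceEvent:
    """A skipped-exon event: upstream, alternative and downstream exon.

    The three exons must be non-overlapping and ordered along the
    chromosome (genomic order, regardless of strand). ``exon_length`` is
    the alternative-exon length; events with exon_length <= 30 nt are
    flagged as micro-exons.
    """

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    upstream_exon: Interval
    alt_exon: Interval
    downstream_exon: Interval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.event_id}: strand must be '+' or '-', got {self.strand!r}")
        exons = (self.upstream_exon, self.alt_exon, self.downstream_exon)
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.event_id}: exons must be ordered and non-overlapping "
                    f"along the chromosome"
                )

    @property
    def exon_length(self) -> int:
        return len(self.alt_exon)

    @property
    def is_microexon(self) -> bool:
        return self.exon_length <= MICROEXON_MAX_LENGTH

    @property
    def upstream_intron(self) -> Interval:
        return Interval(self.upstream_exon.end, self.alt_exon.start)

    @property
    def downstream_intron(self) -> Interval:
        return Interval(self.alt_exon.end, self.downstream_exon.start)


@dataclass(frozen=True)
class EffectiveLengths:
    """Effective lengths of the inclusion and skipping isoform.

    At junction-count resolution the inclusion isoform is supported by two
    junctions and the skipping isoform by one, hence the defaults
    L_I = 2, L_S = 1.
    """

    L_I: float = 2.0
    L_S: float = 1.0

    def __post_init__(self) -> None:
        if self.L_I <= 0 or self.L_S <= 0:
            raise ValueError("effective lengths must be positive")


@dataclass(frozen=True)
class Variant:
    """A sequence variant between the two parental genomes (0-based pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def span(self) -> Interval:
        """Reference bases touched by the variant (>= 1 base)."""
        return Interval(self.pos, self.pos + max(1, len(self.ref)))


@dataclass
class GeneRecord:
    """Per-gene annotations: expression, selective constraint, CDS."""

    gene_id: str
    tpm: dict = field(default_factory=dict)  # tissue -> TPM >= 0
    dn_ds: float | None = None
    cds_intervals: list = field(default_factory=list)  # list[Interval]

    def __post_init__(self) -> None:
        bad = {t: v for t, v in self.tpm.items() if v < 0}
        if bad:
            raise ValueError(f"{self.gene_id}: negative TPM {bad}")


def validate_events(events: Iterable[SpliceEvent]) -> None:
    """Raise on duplicate event ids."""
    seen: set[str] = set()
    for ev in events:
        if ev.event_id in seen:
            raise ValueError(f"duplicate event_id {ev.event_id}")
        seen.add(ev.event_id)
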