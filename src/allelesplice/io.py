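"""Readers and writers for the pipeline's tabular formats.

Events, counts, genes and out-group observations travel as TSV; variants
as VCF (read through pysam); per-base conservation as bedGraph. All output
tables are TSV with a header line and reals serialized at 6 decimals, so
every table round-trips and diffs cleanly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .events import ALLELES, CONDITIONS, Interval, SpliceEvent, Variant, validate_events

EVENT_COLUMNS = [
    "event_id", "gene_id", "chrom", "strand",
    "up_start", "up_end", "alt_start", "alt_end", "down_start", "down_end",
]
COUNT_COLUMNS = ["event_id", "tissue", "replicate", "condition", "allele", "inclusion", "skipping"]
OUTGROUP_COLUMNS = ["species", "tissue", "event_id", "psi"]

FLOAT_FORMAT = "%.6f"


def write_tsv(df: pd.DataFrame, path: str) -> None:
    """Write a results table: TSV, header line, 6-decimal reals."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# events


def events_to_frame(events: list[SpliceEvent]) -> pd.DataFrame:
    rows = [
        (e.event_id, e.gene_id, e.chrom, e.strand,
         e.upstream_exon.start, e.upstream_exon.end,
         e.alt_exon.start, e.alt_exon.end,
         e.downstream_exon.start, e.downstream_exon.end)
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[SpliceEvent]:
    events = [
        SpliceEvent(
            event_id=str(r.event_id), gene_id=str(r.gene_id), chrom=str(r.chrom),
            strand=str(r.strand),
            upstream_exon=Interval(int(r.up_start), int(r.up_end)),
            alt_exon=Interval(int(r.alt_start), int(r.alt_end)),
            downstream_exon=Interval(int(r.down_start), int(r.down_end)),
        )
        for r in df.itertuples(index=False)
    ]
    validate_events(events)
    return events


def read_event_table(path: str, dialect: str = "tsv") -> list[SpliceEvent]:
    """Read SE events from TSV.

    dialect "tsv": coordinates already 0-based half-open.
    dialect "gtf": coordinates 1-based inclusive (GTF convention); starts
    are shifted down by one on import.

    Raises ValueError naming the offending line for malformed rows and on
    duplicate event ids.
    """
    if dialect not in ("tsv", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if dialect == "gtf":
        for col in ("up_start", "alt_start", "down_start"):
            df[col] = df[col] - 1
    events: list[SpliceEvent] = []
    for i, r in enumerate(df.itertuples(index=False)):
        try:
            events.append(SpliceEvent(
                event_id=str(r.event_id), gene_id=str(r.gene_id), chrom=str(r.chrom),
                strand=str(r.strand),
                upstream_exon=Interval(int(r.up_start), int(r.up_end)),
                alt_exon=Interval(int(r.alt_start), int(r.alt_end)),
                downstream_exon=Interval(int(r.down_start), int(r.down_end)),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    validate_events(events)
    return events


def write_event_bed(events: list[SpliceEvent], path: str) -> None:
    """Export alternative exons as BED6 (0-based half-open, like the events)."""
    df = pd.DataFrame(
        [(e.chrom, e.alt_exon.start, e.alt_exon.end, e.event_id, 0, e.strand) for e in events]
    )
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# allelic junction counts


def read_counts(path: str) -> pd.DataFrame:
    """Read the allelic junction-count table.

    Columns: event_id, tissue, replicate, condition, allele, inclusion,
    skipping. Counts must be non-negative integers; allele must be one of
    BL6/SPR/common; condition one of baseline/DMSO/pladB.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_counts(df)


def validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    bad_allele = set(df["allele"].unique()) - set(ALLELES)
    if bad_allele:
        raise ValueError(f"unknown allele labels {sorted(bad_allele)}")
    bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown conditions {sorted(bad_cond)}")
    for col in ("inclusion", "skipping"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            raise ValueError(f"negative {col} count")
        if not np.array_equal(vals, vals.astype(np.int64)):
            raise ValueError(f"non-integer {col} count")
        df[col] = vals.astype(np.int64)
    df["replicate"] = df["replicate"].astype(int)
    return df


# ---------------------------------------------------------------------------
# variants (VCF)


def read_variants(path: str) -> list[Variant]:
    """Read variants from a VCF; 1-based POS becomes 0-based, multi-allelic
    records are split into one Variant per ALT."""
    out: list[Variant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                raise ValueError(f"malformed VCF record at {rec.chrom}:{rec.pos} (no ALT)")
            for alt in rec.alts:
                out.append(Variant(chrom=rec.chrom, pos=rec.pos - 1, ref=rec.ref, alt=alt))
    return out


def write_variants_vcf(variants: list[Variant], path: str) -> None:
    """Write a minimal sites-only VCF (positions converted back to 1-based)."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    chroms = sorted({v.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def variants_to_frame(variants: list[Variant]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.chrom, v.pos, v.ref, v.alt, v.vtype) for v in variants],
        columns=["chrom", "pos", "ref", "alt", "vtype"],
    )


# ---------------------------------------------------------------------------
# conservation (bedGraph)


@dataclass
class ConservationTrack:
    """Per-base conservation scores over a set of genomic intervals.

    Bases not covered by any interval are missing (NaN on lookup), never
    zero. Scores must lie in [0, 1].
    """

    intervals: pd.DataFrame  # columns chrom, start, end, score; non-overlapping

    def __post_init__(self) -> None:
        s = self.intervals["score"]
        if ((s < 0) | (s > 1)).any():
            raise ValueError("conservation scores must be in [0, 1]")
        self._by_chrom = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            sub = sub.sort_values("start")
            self._by_chrom[chrom] = (
                sub["start"].to_numpy(), sub["end"].to_numpy(), sub["score"].to_numpy()
            )

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for each base of [start, end); NaN where uncovered."""
        out = np.full(end - start, np.nan)
        if chrom not in self._by_chrom:
            return out
        starts, ends, scores = self._by_chrom[chrom]
        pos = np.arange(start, end)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = scores[idx[ok]]
        return out

    def mean(self, chrom: str, start: int, end: int, min_coverage: float = 0.5) -> float:
        """Mean score over the interval; NaN if < min_coverage of bases scored."""
        vals = self.per_base(chrom, start, end)
        covered = np.isfinite(vals).mean()
        if covered < min_coverage:
            return float("nan")
        return float(np.nanmean(vals))


def read_conservation(path: str) -> ConservationTrack:
    """Read a bedGraph (chrom, start, end, score; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "score"])
    if df[["start", "end", "score"]].isna().any().any():
        raise ValueError(f"{path}: malformed bedGraph record")
    return ConservationTrack(df)


def write_conservation(track: ConservationTrack, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    track.intervals.to_csv(path, sep="\t", index=False, header=False,
                           float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# gene table


def read_genes(path: str) -> pd.DataFrame:
    """Gene table: gene_id, dn_ds, cds (semicolon 'start-end' list or empty),
    plus one ``tpm_<tissue>`` column per tissue."""
    df = pd.read_csv(path, sep="\t")
    tpm_cols = [c for c in df.columns if c.startswith("tpm_")]
    if not tpm_cols:
        raise ValueError(f"{path}: no tpm_<tissue> columns")
    if (df[tpm_cols] < 0).any().any():
        raise ValueError("negative TPM")
    df["cds"] = df["cds"].fillna("")
    return df


def parse_cds(cds: str) -> list[Interval]:
    if not cds:
        return []
    out = []
    for part in cds.split(";"):
        a, b = part.split("-")
        out.append(Interval(int(a), int(b)))
    return out


def tpm_lookup(genes: pd.DataFrame) -> pd.DataFrame:
    """Long-format TPM: gene_id, tissue, tpm."""
    tpm_cols = [c for c in genes.columns if c.startswith("tpm_")]
    long = genes.melt(id_vars="gene_id", value_vars=tpm_cols,
                      var_name="tissue", value_name="tpm")
    long["tissue"] = long["tissue"].str.removeprefix("tpm_")
    return long


# ---------------------------------------------------------------------------
# out-group observations


def read_outgroup(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(OUTGROUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"out-group table missing columns {sorted(missing)}")
    if ((df["psi"] < 0) | (df["psi"] > 1)).any():
        raise ValueError("out-group PSI outside [0, 1]")
    return df
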