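"""Synthetic F1-hybrid allelic splicing datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, without simulating reads or alignment:

* Each skipped-exon event has a per-tissue inclusion logit; the SPR
  allele of cis-affected events is shifted additively on the logit scale
  (the mechanism behind the scaling law: a fixed log-odds shift moves PSI
  most at intermediate inclusion). The unshifted pattern belongs to the
  ancestral allele, whose logits the out-group species share.
* Junction counts are beta-binomial: the read-level inclusion fraction is
  the PSI warped by the effective-length weights, depth per allele is
  log-linear in the gene's TPM with lognormal noise, and the
  overdispersion rho shrinks with TPM (trans buffering: abundant splicing
  machinery makes splicing more precise).
* Variant density in the exon + flanks scales with the cis-effect
  magnitude, and cis-affected events preferentially carry a splice-site
  variant, realized as an allelic difference in the donor/acceptor window
  sequences.
* A perturbation pair (DMSO control vs pladienolide B) re-draws one cell
  line's counts with inflated dispersion and cis-effect penetrance.

Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as asio
from .betabinom import sample_betabinom
from .events import EffectiveLengths, Interval, SpliceEvent, Variant

TISSUES = ("cortex", "heart", "kidney", "liver", "lung", "spleen", "ESC")
PERTURB_TISSUE = "fibroblast"
OUTGROUP_SPECIES = ("caroli", "pahari")
OUTGROUP_TISSUES = ("brain", "heart", "kidney", "liver")  # cortex maps to brain

_DONOR_LEN = 9
_ACCEPTOR_LEN = 15


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults define the standard study conditions."""

    n_events: int = 2000
    tissues: tuple = TISSUES
    replicates: int = 2
    microexon_fraction: float = 0.15
    # cis effects (log-odds shift of the derived allele)
    cis_fraction: float = 0.3
    cis_min: float = 0.5
    cis_max: float = 2.5
    # inclusion logits
    base_logit_lo: float = float(logit(0.05))
    base_logit_hi: float = float(logit(0.95))
    tissue_sd: float = 0.8
    # overdispersion and its TPM link (trans buffering)
    rho0: float = 0.02
    buffering_gamma: float = 1.0  # rho ~ 1/TPM: trans buffering of splicing noise
    rho_min: float = 1e-4
    rho_max: float = 0.3
    # trans buffering of cis effects: penetrance shrinks with expression
    cis_buffering_gamma: float = 0.5
    cis_atten_lo: float = 0.25
    cis_atten_hi: float = 2.0
    # fraction of cis-affected events whose variant only acts in a random
    # subset of tissues (cis x trans interaction; the derived allele then
    # carries a genuinely tissue-dependent pattern)
    cis_tissue_specific_fraction: float = 0.3
    cis_tissue_on_prob: float = 0.5
    # lognormal per-tissue penetrance noise on every cis effect (the
    # derived allele's pattern carries tissue noise the ancestral lacks)
    cis_tissue_sd: float = 1.0
    # expression / depth model
    log_tpm_mean: float = float(np.log(50.0))
    log_tpm_sd: float = 1.0
    tissue_tpm_sd: float = 0.7
    depth_per_tpm: float = 2.0
    depth_exp: float = 1.0
    depth_noise_sd: float = 0.3
    common_read_factor: float = 3.0
    # sequence features
    base_variant_density: float = 0.008
    variant_density_per_cis: float = 0.004
    splice_site_variant_per_cis: float = 0.3
    indel_fraction: float = 0.15
    # annotations
    events_per_gene: float = 1.5
    coding_fraction: float = 0.8
    ortholog_fraction: float = 0.7
    outgroup_noise_sd: float = 0.02
    # perturbation
    perturb_dispersion_mult: float = 2.0
    perturb_cis_mult: float = 2.0
    lengths: EffectiveLengths = field(default_factory=EffectiveLengths)

    def validate(self) -> None:
        if not 0 < self.rho0 < 1:
            raise ValueError("rho0 must be in (0, 1)")
        if not (0 <= self.cis_fraction <= 1 and 0 <= self.microexon_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.perturb_dispersion_mult < 1 or self.perturb_cis_mult < 1:
            raise ValueError("perturbation multipliers must be >= 1")


@dataclass
class SyntheticDataset:
    events: list
    counts: pd.DataFrame
    variants: list
    conservation: "asio.ConservationTrack"
    genes: pd.DataFrame
    outgroup: pd.DataFrame
    site_seqs: pd.DataFrame     # event_id, allele, donor_seq, acceptor_seq
    truth_events: pd.DataFrame  # event_id, gene_id, cis_effect, ancestral_allele, ...
    truth_tissue: pd.DataFrame  # event_id, tissue, base_logit, rho, true psi per allele
    config: SimulationConfig


def _psi_to_read_fraction(psi, lengths: EffectiveLengths):
    """Expected inclusion-read fraction for a given isoform fraction."""
    return psi * lengths.L_I / (psi * lengths.L_I + (1.0 - psi) * lengths.L_S)


def _random_seq(rng, length, bases="ACGT", p=None):
    return "".join(rng.choice(list(bases), size=length, p=p))


def _simulate_geometry(rng, cfg) -> list:
    """Lay events along one synthetic chromosome."""
    events = []
    pos = 1000
    n_genes = max(1, int(np.ceil(cfg.n_events / cfg.events_per_gene)))
    gene_of = np.sort(rng.integers(0, n_genes, size=cfg.n_events))
    micro = rng.random(cfg.n_events) < cfg.microexon_fraction
    for i in range(cfg.n_events):
        up_len = 150
        intron1 = int(rng.integers(250, 800))
        alt_len = int(rng.integers(3, 31)) if micro[i] else int(rng.integers(60, 250))
        intron2 = int(rng.integers(250, 800))
        down_len = 150
        strand = "+" if rng.random() < 0.5 else "-"
        up = Interval(pos, pos + up_len)
        alt = Interval(up.end + intron1, up.end + intron1 + alt_len)
        down = Interval(alt.end + intron2, alt.end + intron2 + down_len)
        events.append(SpliceEvent(
            event_id=f"ev{i:05d}", gene_id=f"gene{gene_of[i]:05d}", chrom="chr1",
            strand=strand, upstream_exon=up, alt_exon=alt, downstream_exon=down))
        pos = down.end + 500
    return events


def simulate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete synthetic dataset plus ground truth."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    E = cfg.n_events
    T = len(cfg.tissues)
    events = _simulate_geometry(rng, cfg)
    gene_ids = sorted({e.gene_id for e in events})
    G = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    ev_gene = np.array([gene_index[e.gene_id] for e in events])

    # --- expression (TPM) per gene x tissue (incl. the perturbed cell line)
    all_tissues = list(cfg.tissues) + [PERTURB_TISSUE]
    log_tpm = (rng.normal(cfg.log_tpm_mean, cfg.log_tpm_sd, size=G)[:, None]
               + rng.normal(0.0, cfg.tissue_tpm_sd, size=(G, len(all_tissues))))
    tpm = np.exp(log_tpm)

    # --- true splicing parameters
    base_mean = rng.uniform(cfg.base_logit_lo, cfg.base_logit_hi, size=E)
    tissue_off = rng.normal(0.0, cfg.tissue_sd, size=(E, T + 1))  # + fibroblast
    base_logit = base_mean[:, None] + tissue_off
    has_cis = rng.random(E) < cfg.cis_fraction
    cis = np.where(has_cis,
                   rng.uniform(cfg.cis_min, cfg.cis_max, size=E)
                   * rng.choice([-1.0, 1.0], size=E), 0.0)
    ancestral = rng.choice(["BL6", "SPR"], size=E)

    ev_tpm = tpm[ev_gene, :]  # (E, T+1)
    rho = np.clip(cfg.rho0 * (np.exp(cfg.log_tpm_mean) / ev_tpm) ** cfg.buffering_gamma,
                  cfg.rho_min, cfg.rho_max)

    # allele logits: ancestral allele carries the base pattern, the derived
    # allele the cis shift, attenuated where the gene is highly expressed
    # (trans buffering of cis effects)
    atten = np.clip((np.exp(cfg.log_tpm_mean) / ev_tpm) ** cfg.cis_buffering_gamma,
                    cfg.cis_atten_lo, cfg.cis_atten_hi)
    # a fraction of cis effects act only in a random subset of tissues
    tissue_specific = has_cis & (rng.random(E) < cfg.cis_tissue_specific_fraction)
    on = np.where(tissue_specific[:, None],
                  rng.random((E, T + 1)) < cfg.cis_tissue_on_prob, True)
    jitter = np.exp(rng.normal(0.0, cfg.cis_tissue_sd, size=(E, T + 1)))
    shift_bl6 = np.where(ancestral == "SPR", cis, 0.0)[:, None] * atten * on * jitter
    shift_spr = np.where(ancestral == "BL6", cis, 0.0)[:, None] * atten * on * jitter
    psi_bl6 = expit(base_logit + shift_bl6)
    psi_spr = expit(base_logit + shift_spr)

    # --- depth and counts (baseline condition, the named tissues)
    depth_mean = cfg.depth_per_tpm * ev_tpm[:, :T] ** cfg.depth_exp
    count_rows = []
    for r in range(1, cfg.replicates + 1):
        noise = np.exp(rng.normal(0.0, cfg.depth_noise_sd, size=(E, T)))
        n_allele = rng.poisson(depth_mean * noise)
        n_common = rng.poisson(depth_mean * noise * cfg.common_read_factor)
        for allele, psi_a in (("BL6", psi_bl6[:, :T]), ("SPR", psi_spr[:, :T])):
            mu = _psi_to_read_fraction(psi_a, cfg.lengths)
            n = n_allele if allele == "BL6" else rng.poisson(depth_mean * noise)
            inc = sample_betabinom(rng, n, mu, rho[:, :T])
            count_rows.append(_counts_frame(events, cfg.tissues, r, "baseline",
                                            allele, inc, n - inc))
        mu_c = _psi_to_read_fraction(0.5 * (psi_bl6[:, :T] + psi_spr[:, :T]), cfg.lengths)
        inc_c = sample_betabinom(rng, n_common, mu_c, rho[:, :T])
        count_rows.append(_counts_frame(events, cfg.tissues, r, "baseline",
                                        "common", inc_c, n_common - inc_c))

    # --- perturbation condition (fibroblast cell line): DMSO re-drawn from
    # baseline truth, pladB with inflated dispersion and cis penetrance
    fib = T  # column index of the fibroblast tissue
    pert = perturb_condition(
        events, cfg, rng,
        base_logit=base_logit[:, fib], shift_bl6=shift_bl6[:, fib], shift_spr=shift_spr[:, fib],
        rho=rho[:, fib], depth_mean=cfg.depth_per_tpm * ev_tpm[:, fib] ** cfg.depth_exp,
        multiplier_dispersion=cfg.perturb_dispersion_mult,
        multiplier_cis=cfg.perturb_cis_mult)
    count_rows.append(pert)
    counts = pd.concat(count_rows, ignore_index=True)

    variants, site_seqs = _simulate_variants(rng, events, cis, cfg)
    conservation = _simulate_conservation(rng, events)
    genes = _genes_frame(events, gene_ids, tpm, all_tissues, rng, cfg)
    outgroup = _simulate_outgroup(rng, events, base_logit, cfg)

    truth_events = pd.DataFrame({
        "event_id": [e.event_id for e in events],
        "gene_id": [e.gene_id for e in events],
        "cis_effect": cis,
        "ancestral_allele": ancestral,
        "microexon": [e.is_microexon for e in events],
    })
    tt = []
    for j, t in enumerate(all_tissues):
        tt.append(pd.DataFrame({
            "event_id": truth_events["event_id"],
            "tissue": t,
            "base_logit": base_logit[:, j],
            "rho": rho[:, j],
            "psi_bl6": psi_bl6[:, j],
            "psi_spr": psi_spr[:, j],
            "tpm": ev_tpm[:, j],
        }))
    truth_tissue = pd.concat(tt, ignore_index=True)

    return SyntheticDataset(events=events, counts=counts, variants=variants,
                            conservation=conservation, genes=genes,
                            outgroup=outgroup, site_seqs=site_seqs,
                            truth_events=truth_events, truth_tissue=truth_tissue,
                            config=cfg)


def perturb_condition(events, cfg, rng, base_logit, shift_bl6, shift_spr, rho,
                      depth_mean, multiplier_dispersion: float,
                      multiplier_cis: float) -> pd.DataFrame:
    """Counts for the DMSO / pladB pair of the perturbed cell line.

    pladB counts use rho * multiplier_dispersion and cis effects scaled by
    multiplier_cis (direction preserved); DMSO counts are an independent
    re-draw from the baseline truth.
    """
    if multiplier_dispersion < 1 or multiplier_cis < 1:
        raise ValueError("perturbation multipliers must be >= 1")
    E = len(events)
    rows = []
    for condition, mult_c, mult_d in (("DMSO", 1.0, 1.0),
                                      ("pladB", multiplier_cis, multiplier_dispersion)):
        psi_b = expit(base_logit + mult_c * shift_bl6)
        psi_s = expit(base_logit + mult_c * shift_spr)
        rho_c = np.clip(rho * mult_d, 0.0, 0.99)
        for r in range(1, cfg.replicates + 1):
            noise = np.exp(rng.normal(0.0, cfg.depth_noise_sd, size=E))
            for allele, psi_a in (("BL6", psi_b), ("SPR", psi_s)):
                n = rng.poisson(depth_mean * noise)
                mu = _psi_to_read_fraction(psi_a, cfg.lengths)
                inc = sample_betabinom(rng, n, mu, rho_c)
                rows.append(_counts_frame(events, (PERTURB_TISSUE,), r, condition,
                                          allele, inc[:, None], (n - inc)[:, None]))
            n_c = rng.poisson(depth_mean * noise * cfg.common_read_factor)
            mu_c = _psi_to_read_fraction(0.5 * (psi_b + psi_s), cfg.lengths)
            inc_c = sample_betabinom(rng, n_c, mu_c, rho_c)
            rows.append(_counts_frame(events, (PERTURB_TISSUE,), r, condition,
                                      "common", inc_c[:, None], (n_c - inc_c)[:, None]))
    return pd.concat(rows, ignore_index=True)


def _counts_frame(events, tissues, replicate, condition, allele, inc, skp):
    E, T = inc.shape
    return pd.DataFrame({
        "event_id": np.repeat([e.event_id for e in events], T),
        "tissue": np.tile(list(tissues), E),
        "replicate": replicate,
        "condition": condition,
        "allele": allele,
        "inclusion": inc.ravel(),
        "skipping": skp.ravel(),
    })


def _simulate_variants(rng, events, cis, cfg):
    """Variants (density linked to |cis|) and allelic splice-site window
    sequences (a splice-site variant is realized as a one-base allelic
    difference in the donor or acceptor window)."""
    from .features import flank_regions, splice_site_windows

    variants: list[Variant] = []
    seq_rows = []
    acc_p = np.array([0.05, 0.35, 0.05, 0.55])  # pyrimidine-rich acceptor tract
    for i, ev in enumerate(events):
        regions = flank_regions(ev)
        length = sum(len(r) for r in regions)
        dens = cfg.base_variant_density + cfg.variant_density_per_cis * abs(cis[i])
        n_var = rng.poisson(dens * length)
        offsets = rng.integers(0, length, size=n_var)
        for off in np.sort(offsets):
            pos = _offset_to_pos(regions, int(off))
            if rng.random() < cfg.indel_fraction:
                ref = _random_seq(rng, int(rng.integers(2, 7)))
                alt = ref[0]
            else:
                ref = _random_seq(rng, 1)
                alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(Variant(chrom=ev.chrom, pos=pos, ref=ref, alt=alt))

        # window sequences: canonical-ish GT / AG cores
        donor = _random_seq(rng, 3) + "GT" + _random_seq(rng, 4)
        acceptor = _random_seq(rng, 12, p=acc_p) + "AG" + _random_seq(rng, 1)
        donor_spr, acceptor_spr = donor, acceptor
        p_ss = min(1.0, cfg.splice_site_variant_per_cis * abs(cis[i]))
        if rng.random() < p_ss:
            win = splice_site_windows(ev)
            if rng.random() < 0.5:
                j = int(rng.integers(0, _DONOR_LEN))
                donor_spr = donor[:j] + rng.choice([b for b in "ACGT" if b != donor[j]]) \
                    + donor[j + 1:]
                w = win["donor"]
            else:
                j = int(rng.integers(0, _ACCEPTOR_LEN))
                acceptor_spr = acceptor[:j] + rng.choice(
                    [b for b in "ACGT" if b != acceptor[j]]) + acceptor[j + 1:]
                w = win["acceptor"]
            pos = int(rng.integers(w.start, w.end))
            ref = _random_seq(rng, 1)
            variants.append(Variant(chrom=ev.chrom, pos=pos, ref=ref,
                                    alt=rng.choice([b for b in "ACGT" if b != ref])))
        seq_rows.append((ev.event_id, "BL6", donor, acceptor))
        seq_rows.append((ev.event_id, "SPR", donor_spr, acceptor_spr))
    # de-duplicate positions (VCF-style one record per locus)
    seen = set()
    uniq = []
    for v in variants:
        if (v.chrom, v.pos) not in seen:
            uniq.append(v)
            seen.add((v.chrom, v.pos))
    site_seqs = pd.DataFrame(seq_rows,
                             columns=["event_id", "allele", "donor_seq", "acceptor_seq"])
    return uniq, site_seqs


def _offset_to_pos(regions, off: int) -> int:
    for r in regions:
        if off < len(r):
            return r.start + off
        off -= len(r)
    raise IndexError("offset beyond region")


def _simulate_conservation(rng, events) -> "asio.ConservationTrack":
    rows = []
    for ev in events:
        exon_score = rng.uniform(0.5, 1.0)
        flank_score = np.clip(exon_score - rng.uniform(0.1, 0.5), 0.0, 1.0)
        a, b = ev.alt_exon.start, ev.alt_exon.end
        rows.append((ev.chrom, max(ev.upstream_exon.end, a - 200), a, flank_score))
        rows.append((ev.chrom, a, b, exon_score))
        rows.append((ev.chrom, b, min(ev.downstream_exon.start, b + 200), flank_score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return asio.ConservationTrack(df)


def _genes_frame(events, gene_ids, tpm, all_tissues, rng, cfg) -> pd.DataFrame:
    coding = rng.random(len(gene_ids)) < cfg.coding_fraction
    dn_ds = rng.gamma(2.0, 0.08, size=len(gene_ids))
    gidx = {g: i for i, g in enumerate(gene_ids)}
    cds: dict = {g: [] for g in gene_ids}
    for ev in events:
        if coding[gidx[ev.gene_id]]:
            cds[ev.gene_id].append(f"{ev.upstream_exon.start}-{ev.downstream_exon.end}")
    df = pd.DataFrame({"gene_id": gene_ids,
                       "dn_ds": dn_ds,
                       "cds": [";".join(cds[g]) for g in gene_ids]})
    for j, t in enumerate(all_tissues):
        df[f"tpm_{t}"] = tpm[:, j]
    return df


def _simulate_outgroup(rng, events, base_logit, cfg) -> pd.DataFrame:
    """Out-group PSI observations: the ancestral tissue pattern plus noise.

    Out-group tissues are brain (= cortex), heart, kidney and liver; only
    a fraction of events has a detectable ortholog.
    """
    tissue_idx = {t: i for i, t in enumerate(TISSUES)}
    rows = []
    for i, ev in enumerate(events):
        if rng.random() > cfg.ortholog_fraction:
            continue
        for og_tissue in OUTGROUP_TISSUES:
            host = "cortex" if og_tissue == "brain" else og_tissue
            true_psi = expit(base_logit[i, tissue_idx[host]])
            for sp in OUTGROUP_SPECIES:
                obs = np.clip(true_psi + rng.normal(0.0, cfg.outgroup_noise_sd), 0.0, 1.0)
                rows.append((sp, og_tissue, ev.event_id, obs))
    return pd.DataFrame(rows, columns=["species", "tissue", "event_id", "psi"])


def write_dataset(ds: SyntheticDataset, outdir: str) -> None:
    """Write every table of the dataset as text files under outdir."""
    import dataclasses
    import json

    os.makedirs(outdir, exist_ok=True)
    asio.write_tsv(asio.events_to_frame(ds.events), os.path.join(outdir, "events.tsv"))
    asio.write_tsv(ds.counts, os.path.join(outdir, "counts.tsv"))
    asio.write_variants_vcf(ds.variants, os.path.join(outdir, "variants.vcf"))
    asio.write_conservation(ds.conservation, os.path.join(outdir, "conservation.bedgraph"))
    asio.write_tsv(ds.genes, os.path.join(outdir, "genes.tsv"))
    asio.write_tsv(ds.outgroup, os.path.join(outdir, "outgroup.tsv"))
    asio.write_tsv(ds.site_seqs, os.path.join(outdir, "site_seqs.tsv"))
    asio.write_tsv(ds.truth_events, os.path.join(outdir, "truth_events.tsv"))
    asio.write_tsv(ds.truth_tissue, os.path.join(outdir, "truth_tissue.tsv"))
    cfg = dataclasses.asdict(ds.config)
    cfg["tissues"] = list(cfg["tissues"])
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)


def load_dataset(indir: str) -> SyntheticDataset:
    """Reconstruct a dataset written by write_dataset."""
    import json

    with open(os.path.join(indir, "config.json")) as fh:
        raw = json.load(fh)
    raw["tissues"] = tuple(raw["tissues"])
    raw["lengths"] = EffectiveLengths(**raw["lengths"])
    cfg = SimulationConfig(**raw)
    return SyntheticDataset(
        events=asio.read_event_table(os.path.join(indir, "events.tsv")),
        counts=asio.read_counts(os.path.join(indir, "counts.tsv")),
        variants=asio.read_variants(os.path.join(indir, "variants.vcf")),
        conservation=asio.read_conservation(os.path.join(indir, "conservation.bedgraph")),
        genes=asio.read_genes(os.path.join(indir, "genes.tsv")),
        outgroup=asio.read_outgroup(os.path.join(indir, "outgroup.tsv")),
        site_seqs=asio.read_tsv(os.path.join(indir, "site_seqs.tsv")),
        truth_events=asio.read_tsv(os.path.join(indir, "truth_events.tsv")),
        truth_tissue=asio.read_tsv(os.path.join(indir, "truth_tissue.tsv")),
        config=cfg,
    )
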