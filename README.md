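# allelesplice

Allele-specific alternative-splicing divergence analysis for F1-hybrid
RNA-seq designs.

## The problem

In an F1 hybrid of two mouse species (C57BL/6J × SPRET/EiJ, "BL6" and
"SPR"), both alleles of every gene are spliced inside the same nuclei, so
any reproducible difference between the alleles' isoform ratios must be
caused in *cis* — by sequence variants on the transcript itself — rather
than by the shared *trans* environment. This package implements the full
analysis chain for skipped-exon (SE) events in such a design, for
computational biologists studying the evolution and robustness of
splicing:

* **PSI quantification** from allelic junction counts. For inclusion
  reads I and skipping reads S with isoform effective lengths L_I, L_S,

      PSI = (I/L_I) / (I/L_I + S/L_S),

  with L_I = 2, L_S = 1 at junction resolution. PDI = |PSI − 0.5| + 0.5.
* **Divergence testing** per event × tissue: BL6 vs SPR replicate counts
  under a beta-binomial model k ~ BB(n, μ, ρ), with the dispersion ρ
  estimated as a Pearson quasi-dispersion moderated across the event
  cohort (empirical Bayes), a likelihood-ratio test against χ²₁, and
  Benjamini–Hochberg FDR within tissue. An event is divergent when
  FDR < 0.05 and |ΔPSI_allelic| ≥ 0.1.
* **Cross-tissue patterns**: All-/Some-/Non-Divergent groups, the
  gene-level splicing divergence score SDS = (Σᵢ dᵢ/eᵢ)/n × 100, switch
  scores (max pairwise tissue |ΔPSI|) with five tissue-regulatory groups,
  and the four-scenario classifier of tissue-dependent allelic divergence
  on the tissue pair maximizing ΔΔPSI.
* **The scaling law**: the additive effect
  A = odds(PSI_s + ΔPSI)/odds(PSI_s) with odds(x) = x/(100 − x), the
  fold change in splicing-efficiency odds between alleles; a fixed
  log-odds perturbation moves PSI most at intermediate inclusion.
* **Sequence features**: variant density over the alternative exon ±200 nt
  flanks, splice-site windows (donor −3..+6, acceptor −14..+1), a
  pluggable PWM splice-site strength scorer, CDS overlap, and PhastCons
  summaries and positional meta-profiles.
* **Noise controls**: hypergeometric down-sampling to 20 reads,
  mocked-replicate adjusted |ΔPSI|, and replicate noise vs read depth.
* **Out-group polarization**: orthologous-exon matching (same size,
  >90% identity, preserved order) against *M. caroli* and *M. pahari*
  PSI to call each allele ancestral (conserved) or derived.
* **Perturbation**: DMSO vs pladienolide-B comparison of allelic
  divergence in a cell line with a weakened spliceosome.

A synthetic-data generator (`allelesplice.simulate`) produces complete
datasets — counts, variants, conservation, gene table, out-group PSI, a
perturbation pair — with known ground truth, so every stage is testable
without any sequencing data.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data; each writes its tables under `results/` and prints a one-line
summary:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_quantify_psi.py
python analysis/03_call_divergence.py
python analysis/04_tissue_patterns.py
python analysis/05_scaling_law.py
python analysis/06_sequence_features.py
python analysis/07_resampling.py
python analysis/08_ancestry.py
python analysis/09_perturbation.py
```

With seed 1 this prints, among others:

```
wrote 2000 events (609 with cis effects, 319 micro-exons), 108000 count rows, ...
11987 event x tissue tests, 1683 divergent; groups: {'Non-Divergent': 1252,
  'Some-Divergent': 641, 'All-Divergent': 30}; gene SDS groups:
  {'Non-Divergent': 501, 'Low Divergence': 440, 'High Divergence': 87}
scenarios: {3: 392, 1: 145, 2: 123, 4: 11}; median tissue change scenario 2 vs 3:
  0.537 vs 0.336 (one-sided rank-sum p = 5.73e-14)
680 divergent events binned; median |dPSI| intermediate minus extreme bins = 0.157
  (rank-sum p = 4.47e-05); median A = 1.420
476 ancestry calls ...; truth recovery 91.3% on 335 unambiguous events
1653 events in both conditions: both 194, treatment-only 111, control-only 42, ...
```

Reading these: about 14% of event × tissue tests are allelically
divergent; most divergent events are divergent in only some tissues
(buffering); the scenario-2 events (both alleles switch together) change
almost twice as much between tissues as scenario-3 events; the realized
|ΔPSI| of divergent events peaks at intermediate starting PSI (the
scaling law); the out-group comparison recovers the generator's
ancestral allele for >90% of unambiguously called events; and inflating
dispersion and cis penetrance (the pladB condition) creates 2.6× more
newly divergent events than it removes.

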