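# Methods

## Design

The package analyzes skipped-exon (SE) splicing in an F1 hybrid
(C57BL/6J × SPRET/EiJ) profiled across seven tissues/cell types with two
biological replicates, plus a fibroblast line treated with pladienolide B
(spliceosome inhibitor) or DMSO. Reads unambiguously assignable to one
parental genome are "allelic"; reads equally compatible with both are
"common". All computation operates on junction counts per
event × tissue × replicate × allele × condition; read alignment and
allele assignment are upstream of this package.

Coordinates are 0-based half-open on the forward strand throughout;
strand-dependent window arithmetic lives in strand-aware helpers. Output
tables are TSV with a header and 6-decimal reals, so every table
round-trips exactly and diffs cleanly.

## PSI, PDI and filters

PSI = (I/L_I)/(I/L_I + S/L_S) with default effective lengths L_I = 2,
L_S = 1 (two inclusion junctions versus one skipping junction at
junction-count resolution); PSI is undefined, never zero, without
informative reads. Tissue-level PSI is the unweighted mean of replicate
PSIs. PDI = |PSI − 0.5| + 0.5.

An event is *expressed* in a tissue when every replicate has ≥ 20
informative reads — pooled over alleles and common reads for total-mode
analyses, within each allele separately for allelic analyses. Events
whose PSI exceeds 0.9 (or falls below 0.1) in every replicate of every
expressing tissue are *constitutive* and dropped; in allelic analyses
only if the same holds within both alleles separately. The
*consistency filter* compares allelic-only with allelic+common PSI per
event × tissue and retains cells with |ΔPSI| ≤ 0.1 and beta-binomial FDR
> 0.5, guarding against unrepresentative allele-assignable reads.

## The divergence test

Counts are modeled as k_r ~ BetaBinomial(n_r, μ, ρ) on the read scale
(μ is PSI warped through the effective-length weights — a monotone map,
so testing μ equality is testing PSI equality). H1 gives each allele its
own μ; H0 shares one μ; 2·(ℓ₁ − ℓ₀) is referred to χ² with 1 df.

With two replicates per allele a per-event maximum-likelihood ρ is
degenerate: profiling it separately under each hypothesis lets
overdispersion absorb the between-allele difference (complete allelic
separation then yields p ≈ 0.02), and fixing the H1-profiled ρ makes the
test strongly anti-conservative (empirical type-I error ≈ 0.16 at
α = 0.05). We therefore estimate dispersion the way count-based
differential-expression tools do: a per-event Pearson (quasi-likelihood)
dispersion under free means, squeezed toward the cohort consensus by an
empirical-Bayes step — the prior degrees of freedom found by matching
the spread of bias-corrected log dispersions to the theoretical scaled-F
spread (trigamma matching), the prior location the bias-corrected
geometric mean. One ρ per event, shared by both hypotheses, bounded to
[10⁻⁶, 0.99]. Events whose replicates agree perfectly keep ρ ≈ 0, so
complete separation still produces an enormous statistic. The mean MLE
at fixed ρ is a 45-step bisection on the score in logit space,
vectorized across events; testing 10,000 events takes well under a
second. Measured operating characteristics: type-I error 0.043–0.050 at
α = 0.05 on null beta-binomial data (depth 100, ρ = 0.01), p = 1 for
identical groups, p < 10⁻¹⁰⁰ for complete separation, invariance under
group order and allele relabeling.

Benjamini–Hochberg correction is applied within each tissue by default
(each tissue is its own comparison family); a global scope is available.
Divergent means FDR < 0.05 **and** |ΔPSI_allelic| ≥ 0.1 (non-strict on
the effect, strict on the FDR). Scenario cutoffs, by contrast, use
strict "greater than" — the two thresholds intentionally differ.

## Cross-tissue statistics

*Divergence groups* need ≥ 2 expressing tissues: All-Divergent
(every expressing tissue), Non-Divergent (none), Some-Divergent
(otherwise). *SDS* for a gene with n qualifying events is
(Σᵢ dᵢ/eᵢ)/n × 100 (dᵢ divergent, eᵢ expressing tissues of event i);
groups: SDS = 0 / 0 < SDS < 50 / SDS ≥ 50. *Switch score* is the max
pairwise |PSI| difference between expressing tissues (equivalently
max − min); groups at <0.1 / [0.1,0.2) / [0.2,0.3) / [0.3,0.5) / ≥0.5,
with Switch-Like at ≥ 0.5. The *scenario classifier* takes the tissue
pair maximizing ΔΔPSI = |ΔPSI_allelic(T1) − ΔPSI_allelic(T2)| (ties
broken by lexicographic tissue order for determinism) and compares each
allele's ΔPSI_T = PSI(T1) − PSI(T2) with a cutoff in [0.1, 0.2]:
scenario 1 both above with opposite signs, 2 both above same sign,
3 exactly one above, 4 neither.

## The additive effect and the scaling law

A(PSI_s, ΔPSI) on the percent scale equals
odds(PSI_s + ΔPSI)/odds(PSI_s); between alleles the lower PSI is the
start, so A ≥ 1 with equality iff the alleles agree. Values within 10⁻⁶
of the 0/100 boundary are excluded, not clamped, so A never silently
explodes; A(·, 0) returns exactly 1. The scaling-law analysis bins
divergent events by the BL6-allele mean PSI into ten bins and compares
per-bin median |ΔPSI| (the intermediate bins [0.4, 0.6) against the
extreme bins, one-sided rank-sum).

## Sequence features

Variant density = variants overlapping the alternative exon plus up to
200 nt of each flanking intron (clipped at the neighbouring exons; the
density denominator uses the clipped length) divided by region length;
an indel counts once irrespective of length, and "overlap" means any
shared base. Splice-site windows: donor = last 3 exonic + first 6
intronic nt (9 nt), acceptor = last 14 intronic + 1 exonic nt (15 nt),
strand-aware, truncated for tiny exons and clipped at neighbouring
exons. Splice-site strength is pluggable; the default scorer is a
log₂-odds PWM (pseudocount 0.5, uniform background) trained on the
supplied window sequences — deltas are comparable only within one
scorer. Conservation summaries are exon means requiring ≥ 50% scored
bases; the positional meta-profile (events with exon ≥ 60 nt and introns
≥ 200 nt) concatenates 200 intron + 30 exon nt on the acceptor side and
30 exon + 200 intron nt on the donor side, 460 positions oriented 5'→3'
of the transcript.

## Resampling controls

All resampling treats reads as physical objects and samples without
replacement. Down-sampling draws 20 of the I + S labeled reads
(hypergeometric; cells with fewer reads are excluded). Consistency with
the full data uses |ΔPSI_down| ≥ 0.1 against the full-data divergence
flag, averaged over repetitions with a 2.5/97.5-percentile CI. The
headline Pearson r compares full ΔPSI with the repetition-averaged
down-sampled ΔPSI (the down-sampled expectation, matching the
repetition-averaging of the published procedure); per-repetition r is
reported alongside — it is bounded by the irreducible 20-read noise and
therefore mostly reflects the cohort's ΔPSI spread. The adjusted
replicate |ΔPSI| subtracts the mean mock |ΔPSI| obtained by pooling both
replicates' labeled reads and re-splitting them into the original
replicate sizes (default 100 mocks), using the same effective-length PSI
estimator as the main pipeline; it may be negative and is unbiased to
within ±0.01 on binomial null data.

## Out-group ancestry

Orthologous events require, for all three exons in order, a same-size
out-group exon with ungapped identity > 0.90 (sizes equal by
construction, so gapless identity is well defined). Per tissue, an
out-group PSI within mean(allele PSIs) ± 0.05 (closed interval) is
intermediate; otherwise the closer allele labels it (exact ties resolve
to intermediate — conservative). Two out-group species must agree;
disagreement or double-intermediate is ambiguous. The overall call uses
the tissue pair with the largest ΔΔPSI among the four out-group tissues
(cortex is matched to out-group whole brain; the tissue map is a config
table): same conserved allele in both → that allele is ancestral;
opposite → excluded; one ambiguous → decided by the tissue with the
larger allelic divergence, unless that tissue is the ambiguous one.
Ancestry is only computed for events divergent in ≥ 1 tissue — for
non-divergent events both alleles match the out-group and the label is a
coin flip.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume;
its defaults are the standard study conditions (2,000 events, 7 tissues,
2 replicates, plus the fibroblast DMSO/pladB pair).

* **Splicing truth.** Each event draws a mean inclusion logit uniform on
  [logit 0.05, logit 0.95] and per-tissue offsets N(0, 0.8). 30% of
  events carry a cis effect: a log-odds shift of magnitude U(0.5, 2.5)
  with random sign applied to the derived allele (the ancestral allele,
  drawn at random, keeps the base pattern and is what the out-group
  species share, up to N(0, 0.02) observation noise; 70% of events have
  a detectable ortholog). Additive logit effects are the minimal
  mechanism consistent with the odds-ratio algebra of the additive
  effect and produce the scaling law automatically.
* **Cis × trans interaction.** Cis-effect penetrance is attenuated in
  highly expressed tissues ((TPM_ref/TPM)^0.5, clipped to [0.25, 2]) —
  trans buffering of cis effects; 30% of cis effects additionally act in
  only a random half of the tissues, and every cis effect carries
  per-tissue lognormal penetrance noise (sd 1.0, the same order as the
  effect). Purely uniform additive effects cannot reproduce the observed
  asymmetry between tissue-stable and tissue-variable alleles: the
  logistic squashes the shifted allele's between-tissue variation
  whenever the shift points outward, so without a cis × trans component
  the derived allele would be the *less* variable one.
* **Counts.** Depth per allele per replicate is Poisson with mean
  2 × TPM × lognormal(0, 0.3); gene TPM is lognormal (median 50, gene sd
  1.0, tissue sd 0.7). Common reads are 3× the allelic depth with the
  two alleles' average PSI. Inclusion counts are beta-binomial with the
  read-level mean warped by the effective lengths and dispersion
  ρ = 0.02 × (TPM_ref/TPM), clipped to [10⁻⁴, 0.3] — splicing noise
  shrinks with expression (trans buffering of noise). Together with the
  depth–TPM link this gives the buffering analyses recoverable
  structure.
* **Variants and sequences.** Variant count over exon + flanks is
  Poisson with density 0.008 + 0.004·|cis| per nt (15% indels);
  cis-affected events get a splice-site variant with probability
  0.3·|cis|, realized as a one-base allelic difference in the donor or
  acceptor window sequence (windows carry canonical GT/AG cores and a
  pyrimidine-rich acceptor tract). Conservation is piecewise constant
  per event (exon U(0.5, 1.0), flanks lower). Genes hold ~1.5 events;
  80% are coding (CDS spanning the event), with gamma-distributed dN/dS.
* **Perturbation.** The pladB condition re-draws the fibroblast counts
  with ρ × 2 and cis effects × 2 (directions preserved); DMSO is an
  independent re-draw from the baseline truth. Multipliers below 1 are
  rejected.

Identical seed and config give byte-identical files. What the generator
does **not** emulate: read-level artifacts (mapping bias, reference
bias, positional coverage), correlated variants, isoform classes other
than SE, and real genomic sequence context. Tests passing on this
generator therefore validate the statistical machinery and the
decision rules, not robustness to alignment artifacts.

## Numerical choices

Dispersion bounds [10⁻⁶, 0.99]; logit-mean bisection over [−15, 15],
45 iterations; PWM pseudocount 0.5; conservation coverage threshold 50%;
boundary tolerance 10⁻⁶ (percent scale) for the additive effect;
scenario tie-breaks lexicographic; Fisher odds ratios are sample
cross-product ratios with Haldane +0.5 only when exactly one cell is
zero (flagged); rank-sum comparisons in `group_compare` use the exact
null distribution for small untied samples and the continuity-corrected
normal approximation otherwise. Empty or degenerate inputs yield absent
(NaN) values, never silent zeros.

## Problem sizes

The default analyses run 2,000 events × 7 tissues × 2 replicates; the
test-calibration simulation uses 10,000 null events and the full-scale
pipeline check 10,000 events (about 40 s in total on one core). These
sizes give stable Monte-Carlo estimates for every cohort statistic while
keeping the whole suite fast.

## Known limitations

The divergence test assumes a common dispersion for both alleles of an
event; allele-specific dispersion is not modeled. The consistency filter
compares overlapping read sets (allelic ⊂ total), which makes its test
conservative. The PWM strength scorer is a stand-in interface — scores
are not comparable to any external splice-site server. Ortholog matching
requires exactly equal exon sizes, so orthologs with small indels are
missed by design. The scenario classifier's tissue pair is chosen on
measured ΔΔPSI and inherits its noise at low depth.
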