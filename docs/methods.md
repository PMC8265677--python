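# Methods

## Problem and model

`sixma` analyses N6-methyladenine (6mA) in an AT-rich, highly polyploid
genome (the *Tetrahymena thermophila* macronucleus, ~45 copies per
chromosome) across two physiological conditions — vegetative growth (Veg)
and 24 h starvation (S24). The unit of analysis is the strand-resolved
adenine call produced by single-molecule kinetic base-modification
detection: `(chrom, pos, strand, coverage, Qv, frac)`, where `frac` is the
estimated fraction of DNA molecules methylated at the site. Because the
genome is polyploid, `frac` behaves as a nearly continuous methylation
level in [0, 1]; it is binned L1–L5 in 20% steps, with L5 closed at 100%.

### Coordinates and duplex geometry

All internal coordinates are 0-based half-open; 1-based conventions exist
only at file boundaries (GFF3, qPCR site names). A 5'-ApT-3' dinucleotide
presents an ApT on both strands by base pairing, so its two adenines —
Watson at `p`, Crick at `p+1` — form the unit of symmetry analysis. A
"Crick-strand adenine at coordinate p" means the Watson base at `p` is T;
this lets both strands share genomic coordinates. N bases never form ApT
duplexes and are excluded from adenine denominators.

### Filtering and classification

Coverage is first normalized by one global scalar so the mean over called
sites equals 100x (the mean is taken over calls, the only objects carrying
coverage), then the confidence filter keeps calls with Qv > 30 and
normalized coverage > 25x, both strict. Normalization precedes filtering;
the two are order-dependent and this order is the package's stated choice.

Each surviving call is assigned exactly one class:

* **symmetric** — both adenines of its duplex are in the filtered set
  (counted as two methylated adenines, one per strand);
* **asymmetric** (hemimethylated) — the partner adenine is absent;
* **non-ApT** — the strand-local 3' neighbour is not T.

Symmetry is evaluated *after* filtering: a partner removed by the
confidence filter leaves the survivor asymmetric. This is an
interpretation — sub-threshold methylation is indistinguishable from
absence — and it propagates to the transition analysis, where
"unmethylated" likewise means "absent from the filtered set".

Composition percentages are rounded to one decimal, half away from zero,
matching printed-table style. Density denominators count strand-resolved
adenines (Watson A + Crick A, i.e. A+T of the Watson sequence) because
calls are strand-resolved; a Watson-A-only switch is provided.

### Transitions

Sites are matched across conditions per strand-resolved adenine. The
transition matrix is 4x4 over {symmetric, asymmetric, non-ApT,
unmethylated}; the unmethylated-in-both cell is structurally zero (such
adenines never enter the universe). Published transition fractions mix
denominators (condition-A vs condition-B marginals), so
`transition_fractions` demands an explicit per-row denominator instead of
guessing. The duplex-level view (for GATC conversion/retain site
selection) is derived from the adenine-level table.

### 6mA amount and expression coupling

The 6mA amount of a region is the sum of `frac` over its sites — a site
count weighted by level. Metagene profiles scale gene bodies (> 1 kb) to
unit length with unit flanks, bin 0.05; TSS profiles accumulate per base
over [-1000, +2000). Both are amount-weighted and normalized to sum to 1.
The coupling statistic is the Pearson correlation between the raw amount
change (S24 − Veg, over the strand-aware [TSS, TSS+1 kb) window) and the
log2 fold change, over a stated gene set. Gene sets: DEGs (padj < 0.05,
|log2FC| > 2, strict), starvation-induced (counts Veg < 300 and
S24 > 1,500), repressed (the reverse gates), and highly regulated — the
top decile of |log2FC|, by default among expressed (FPKM-flagged) genes;
this reading of "top 10% genes with different expression levels" is a
package choice and is configurable.

### Nucleosome statistics

Dyads are fragment midpoints, gated to 120–180 bp. The composite profile
accumulates dyads strand-oriented around TSSs over [-500, +1500), smooths
with a centered 31-bp moving average (reflected edges), and normalizes
area to 1. The **positioning degree** of the +k nucleosome is
`(P_k − T_k)/(P_k + T_k)`: the +k peak is the maximum in
[200(k−1), 200(k−1)+250) downstream of the TSS, troughs are minima between
adjacent peaks (and between the TSS and +1, and the last peak and the
window end), and P/T are mean densities within ±20 bp of each extremum.
This contrast statistic is the package's explicit, testable definition —
the literature procedure it stands in for is not specified precisely
enough to reimplement — so absolute published degree values are not
reproduction targets; the statistic is scale-invariant, 0 on flat
profiles and 1 when troughs reach zero.

Periodicity is the lag of the first local maximum (beyond 50 bp) of the
circular autocorrelation of the profile. Two numerical choices matter:
the circular (FFT) estimator avoids the overlap taper that biases the
linear estimator's maximum toward smaller lags, and a significance floor
(normalized autocorrelation > 0.1 at the candidate lag) is required so
that chance wiggles of an aperiodic profile raise an "aperiodic" error
instead of returning noise.

6mA–dyad phasing maps each site between consecutive dyads `d_i < d_{i+1}`
(gap ≤ 400 bp) to `(pos − d_i)/(d_{i+1} − d_i)`; linker-concentrated 6mA
shows a mode near 0.5.

### Restriction qPCR

DpnI cuts methylated GATC, DpnII unmethylated GATC. With
ΔCt = Ct_digest − Ct_undigested, the readout is
ΔΔCt = ΔCt_DpnI − ΔCt_DpnII (the undigested control cancels
algebraically, asserted as a property test) and
ΔΔΔCt = ΔΔCt_Veg − ΔΔCt_S24. Conversion sites (symmetric → unmethylated)
give ΔΔΔCt > 0; retain sites ≈ 0. "Close to zero" is |ΔΔΔCt| < 1 cycle by
default (no published threshold exists); no PCR-efficiency correction is
applied.

## Synthetic data generator

The generator emits every format the pipeline reads (FASTA, GFF3,
modifications GFF, BED, TSV, CSV) plus truth tables, under one global
seed with named substreams (adding a consumer never perturbs existing
draws).

* **Genome**: i.i.d. bases at AT content 0.75 (AT-rich macronucleus);
  genes > 1 kb tiled on alternating strands.
* **Methylation placement**: per-duplex condition-A state from
  (p_sym = 0.0088, p_asym = 0.0077), per non-ApT adenine rate 0.00105.
  These defaults were derived once from the target vegetative composition:
  with AT content a = 0.75, ApT duplexes occur at (a/2)² = 0.1406/bp and
  non-ApT strand-resolved adenines at ≈ 0.47/bp; solving for a 61.1/26.7/
  12.2 class split at ~0.5% overall 6mA/A density gives the rates above.
  Tests needing more sites enlarge the genome or raise the rates
  explicitly rather than changing the defaults.
* **Transition kernel**: the spec-level 4-state kernel is factorized into
  a 3x3 duplex kernel over {symmetric, asymmetric, unmethylated} plus an
  independent non-ApT retention probability (0.33 ≈ the observed S24/Veg
  non-ApT count ratio), because a non-ApT state is geometrically
  impossible for an ApT duplex. Default rows encode the observed
  directionality (symmetric loss to asymmetric/unmethylated, minimal
  re-methylation).
* **Levels**: class-conditional Beta mixtures — symmetric concentrated
  high, asymmetric bimodal, shifting toward high levels in the starved
  condition (emulating the doubling of highly methylated asymmetric
  sites). A copy-number mode (levels quantized as Binomial(45, level)/45)
  mirrors polyploid copy counting; the continuous default is faster.
* **Coverage/Qv**: negative binomial around mean 103x (the study's
  average coverage) with shape 10; Qv ~ N(42, 8) clipped at 1, so the
  Qv > 30 / cov > 25 filter has realistic bite.
* **Nucleosomes**: true dyads at TSS + 100 + 200k (k = 0..5) in the gene
  direction; fragment midpoints N(dyad, jitter 20), lengths N(147, 15),
  10% uniform background. The linker-enrichment factor up-weights 6mA
  placement > 73 bp from every dyad.
* **Expression**: log2FC = beta·z + N(0, 1) with z the standardized true
  amount change and beta chosen for a population correlation of 0.3 (the
  "weak yet significant" coupling regime); counts are negative binomial
  around a log-normal baseline consistent with the fold change; padj from
  a sign-randomization null with Benjamini–Hochberg adjustment.
* **Ct values**: undigested baseline 18 cycles, +5 cycles for a cut
  template, noise sd 0.3.

What the generator does **not** emulate: sequence composition beyond
i.i.d. bases (no codon structure, no motifs beyond ApT geometry), kinetic
detection noise in `frac`, correlated coverage along the genome, MNase
sequence bias, or replicate structure in expression. Passing tests
therefore demonstrate correctness of the arithmetic and recoverability of
planted structure, not robustness to those real-data artifacts.

## Truth conventions in tests

Class-label recovery is asserted on the emitted call sets *before*
filtering: the generator draws realistic coverage/Qv, and a filtered-out
partner legitimately flips a symmetric site to asymmetric, so exact
recovery is only defined pre-filter. Post-filter behavior is tested
against brute-force recounts instead. Kernel recovery is asserted at the
duplex level within 3-sigma binomial bounds.

## Problem sizes

The shipped checks run on desk-scale data chosen once: ~0.3–0.75 Mb
genomes (≈ 10⁵ ApT duplexes for kernel recovery, with placement rates
raised to 0.25/0.20 for statistical power), 2,000 genes for the
correlation point estimate and 100 replicates of 500 genes for sign
recovery, ~8,000 dyads for periodicity. Genome-scale absolute quantities
(hundreds of thousands of called sites, genome-wide densities) require
the original sequencing data and are out of scope; the printed count
tables are used as direct inputs to the composition and transition
arithmetic instead.

## Known limitations

* "Unmethylated" conflates absence with sub-threshold methylation.
* The positioning degree is a declared stand-in definition (above).
* The generator's duplex states are independent across duplexes; no
  spatial autocorrelation of methylation.
* Symmetric duplex strand levels are drawn independently rather than
  correlated within a duplex.
* The rDNA-like chromosome exclusion is a plain name list in the pipeline
  config (`exclude_chromosomes`); no sequence-based detection.
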