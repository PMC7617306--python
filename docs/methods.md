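# Methods

This note documents the models, defaults and numerical choices behind
`clonefate`, and what the synthetic-data validation does and does not
demonstrate.

## The experimental model

A barcoded founder population of B-ALL cells is split into two arms —
tumour alone and tumour + NK cells — each grown in three replicate wells
and sampled at two timepoints (TP1 ≈ day 4, TP2 ≈ day 14, matching an
initial challenge and a re-challenge schedule at an effector-to-target
ratio of 1:1). Barcode amplicons are sequenced per well in technical
duplicate at a target coverage of 50–100 reads per barcode, as 64-bp
single-end reads. Four additional sequencing runs of the viral plasmid
library define the barcode whitelist.

The analysis assumes: one barcode per clone (guaranteed experimentally by
a <5% transduction rate), exact barcode identity across time (no
within-barcode error correction is attempted), and wells as the unit of
biological replication (technical replicates are summed before any
statistics).

## Clone-level statistics

**Size factors.** Median-of-ratios: the pseudo-reference is the
per-barcode geometric mean over all well samples, using only barcodes with
a nonzero count everywhere; each sample's factor is the median ratio of
its counts to the pseudo-reference. When no barcode is everywhere-nonzero
the code falls back to total-count ratios with a warning. A consequence
worth knowing: barcodes that drop to zero anywhere (e.g. fully eliminated
clones) leave the pseudo-reference, so the factors centre on the
*persisting* clones. This is what makes "static" a meaningful category in
an experiment where the majority of clones is being removed; if
elimination were only partial (no zeros), the median could land inside the
eliminated block and normalisation would absorb the effect instead.

**Normalisation.** Values used for variability, classification and display
are the shifted log transform x = log₂(count/factor + 1); zeros map to 0.
The differential-abundance test uses linear normalised counts
(count/factor) because its variance model lives on the count scale.

**Variability.** v = log₂((max(x)+1)/(min(x)+1)) across the three wells of
one condition and timepoint, computed on the shifted-log values. On this
scale a perfectly consistent clone at ordinary counting noise has v ≈ 0.1,
safely under the 0.5 gate, while a clone present in one well and absent in
the others scores v ≥ 1. (Computed on *linear* normalised counts the same
thresholds would misbehave: at overdispersion 0.05 and ~75 reads/barcode a
genuinely static clone has max/min well ratios around 1.5, i.e. v ≈ 0.6,
and the static gate would reject most truly static clones.)

**Differential abundance.** Per barcode, a two-group Wald test under a
gamma-Poisson model:

* log₂FC = log₂((m_nk + ½)/(m_alone + ½)), m being group means of
  normalised counts;
* Var(x̄_g) = (m_g·mean(1/s_j) + α·m_g²)/n_g, mapped to the log scale by
  the delta method;
* α is estimated per barcode by method of moments (pooled within-group
  variance excess over the Poisson part) and squeezed toward the ensemble
  estimate pooled over all barcodes, with prior weight 50 against the
  4 residual degrees of freedom of a 3-vs-3 design
  (`shrinkage_prior_df=50`; 0 disables moderation);
* two-sided p from the normal reference, Benjamini–Hochberg adjusted
  (via `statsmodels`).

The moderation is load-bearing. With three wells per arm the raw
per-barcode variance estimate has ~4 df, and treating the resulting Wald
statistic as normal rejects a true null ~11% of the time at α = 0.05. With
the dispersion squeezed toward the ensemble value the empirical type-I
error in a 2,000-barcode null simulation is ~0.053, inside the binomial
95% CI of the nominal level, which the acceptance suite verifies. A small
residual inflation (~+0.003) is intrinsic to the statistic at n = 3 (the
means themselves are estimated and NB counts are skewed) and does not
shrink further with stronger moderation. Barcodes with zero counts in both
arms are reported as lfc 0, p 1, and flagged.

**Classification.** The five rules run in fixed order with first-match
precedence; thresholds (padj < 0.05, |log₂FC| ≥ 1, v ≤ 0.5 alone,
v < 1 / v ≥ 1 in NK) are the analysis defaults and all configurable. The
"high in only one well" criterion of the secondary-resistant rule is
formalised as: well i is high iff log₂((xᵢ+1)/(min(x)+1)) ≥ 1, i.e. at
least one doubling above the shifted minimum — the same scale and bar as
the v ≥ 1 gate, parameter-free, with the bar exposed as `high_well_bar`.
Classification is computed per timepoint; headline summaries use TP2.

## The synthetic generator

`GeneratorConfig` defaults encode the study design: 3,000 founder clones,
21-nt barcodes, log-normal founder abundances (σ = 0.5), two conditions ×
two timepoints × 3 wells × 2 technical replicates, 4 library samples,
depth 75 reads/barcode per library, NB dispersion 0.05, read length 64,
and a 15% defective-read fraction split evenly over five defect classes
(short insert, long insert, uncalled base, missing head, missing tail).

Fate weights default to the observed per-category means of the co-culture
experiments — eliminated 58.5%, primary resistant 14.3%, static 23.9%,
secondary resistant 3.3%, other 0% — so that the default simulation *is*
the recovery experiment. Effect sizes (log₂, applied in the NK arm):

* eliminated −10: near-complete clearance (≈ 0.1% residual abundance,
  i.e. >99.9% killing over two weeks). Besides being the realistic regime
  for NK-sensitive clones, this puts eliminated clones at zero counts in
  the NK wells, which (a) removes them from the size-factor
  pseudo-reference — see above — and (b) empties both non-expanded wells
  of secondary-resistant clones, making their one-high-well signature
  clean. With mild elimination (e.g. −3) the recovery experiment is not
  merely harder, it is structurally impossible under median-of-ratios
  normalisation, because eliminated clones are the majority category.
* primary resistant +3 (reproducible 8-fold enrichment);
* secondary resistant +2 in exactly one randomly chosen well, the
  eliminated effect in the others. The expansion is deliberately moderate:
  because NK-arm frequencies renormalise, a one-well 8-fold expansion
  would push the clone's *mean* observed log₂FC above +1 and rule i would
  capture it before rule iv.
* static and other 0.

Selection pressure scales with time: effects apply at half strength at TP1
and full strength at TP2, and the secondary expansion exists only at TP2 —
acquired resistance is a late event; at TP1 those clones behave like
eliminated ones.

Counts per technical replicate are NB(mean = frequency × n_clones ×
depth, dispersion), with dispersion 0 giving Poisson, and a log₂FC of −∞
acting as a kill flag (exact zeros). Reads are head + barcode + tail
padded to 64 nt with random bases at uniform high quality; defective reads
are injected so their expected share of the file equals
`malformed_fraction`. Generation is fully deterministic given the seed
(independent RNG streams per stage), and the seed is recorded in the first
read header of each FASTQ.

**What the generator does not emulate:** sequencing substitution errors
inside the barcode, PCR chimeras and amplification jackpots, barcode
sharing between clones, cross-sample index hopping, GC/length biases, or
any absolute cell-count dynamics (frequencies are compositional by
construction). Passing the recovery tests therefore shows that the
pipeline's inference is correct *under its own noise model* — it does not
certify performance on real libraries, where anchor-proximal sequencing
errors and barcode collisions would first have to pass or fail the exact
extraction filters.

## Validation surfaces

* Deterministic oracles: analytic Shannon values, power-of-two variability
  fixtures, a brute-force Benjamini–Hochberg implementation, a regex full
  scan for extraction decisions, and an exact conditional-binomial Poisson
  test in the dispersion→0 limit.
* Calibration: the 2,000-barcode null for type-I error.
* End-to-end recovery: at the default (study) conditions the full
  read-level pipeline returns fate proportions within ±3 percentage points
  of the generating weights (±2 for secondary resistant), a ~15% discard
  rate, and ≥95% per-clone fate agreement for eliminated / primary /
  static clones. Secondary-resistant recovery is structurally lower
  (~86%): a clone whose two non-eliminated wells straddle zero (one zero,
  one small positive) shows two "high" wells and lands in "other". Raising
  `high_well_bar` removes this at the cost of sensitivity to genuinely
  shared expansions.

Problem sizes used in the shipped tests (3,000 clones for recovery, ~10⁵
reads for QC calibration, 150–600 clones elsewhere) were chosen as the
smallest instances at which the binomial/Monte-Carlo error of each checked
quantity is comfortably below its assertion tolerance.

## Known limitations

* Exact anchor matching: a single sequencing error in an anchor discards
  the read; with real error rates the effective depth is lower than
  nominal. Mismatch-tolerant matching is deliberately out of scope.
* No dispersion trend over the mean, no lfc shrinkage: at 3 wells per arm
  a trended fit would be weakly identified; the ensemble moderation is the
  simplest estimator that calibrates.
* The decision tree inherits the compositionality of relative abundances:
  a strong expansion of one clone depresses every other clone's observed
  fold change. The renormalisation-aware effect-size defaults account for
  this in simulation, but on real data "static" always means "static
  relative to the persisting population".
* `other` is a residual class: clones with inconsistent behaviour in the
  alone arm (v_alone > 0.5) or ambiguous NK-arm patterns end there and are
  reported, never silently dropped. A four-category renormalised summary
  (`fate_proportions(renormalize_four=True)`) is provided alongside the
  five-category one.
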