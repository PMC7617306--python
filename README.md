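# clonefate

Clone-fate analysis of cellular DNA-barcode sequencing from tumour / NK-cell
co-culture experiments.

## The problem

Cancer immunoediting sculpts tumour cell populations: some clones are killed
by immune effectors, some resist intrinsically, and some acquire resistance
during the encounter. Heritable DNA barcoding makes this quantifiable — each
founder cell is tagged once (low-MOI lentiviral transduction, <5% of cells)
with a random 21-nt barcode, and bulk amplicon sequencing of the barcode
locus turns clone abundances into read counts. Culturing barcoded B-ALL
(B-cell acute lymphoblastic leukaemia) cells for two weeks with or without
NK cells, in replicate wells, then lets count statistics assign each clone a
fate.

`clonefate` implements the complete analysis for such experiments, from raw
FASTQ to per-clone fate calls, plus a fully ground-truthed synthetic
experiment generator, so that every stage of the pipeline is testable
against a known answer at desk scale. It is aimed at researchers running
barcode lineage-tracing co-cultures (or similar selection experiments) and
at anyone who wants a reproducible, self-validating reference implementation
of this class of analysis.

## Method

**Extraction.** The barcode of each read is the insert between two fixed
anchors (head `GAACACTCGAGATCAG`, tail `TGTGGTATGATGT`), located by exact
pattern matching. Reads are discarded when an anchor is missing, the insert
is not exactly 21 bases, or it contains an uncalled base (`N`).

**Reference and filtering.** Barcodes with a summed count ≥ 100 across the
viral-library samples form the reference whitelist. Sample counts are
restricted to it, technical replicates are merged by summing, and a clone
enters the analysis only if detected (≥ 1 read) in every tumour-alone well
at the reference timepoint with a summed count ≥ 9.

**Statistics.** Per-sample clonal complexity is Shannon diversity
H = −Σ pᵢ ln pᵢ. Counts are depth-normalised with median-of-ratios size
factors sⱼ and transformed as x = log₂(K/s + 1) (shifted log). Per clone
and condition, the between-well variability is

    v = log2( (max(x) + 1) / (min(x) + 1) ).

Differential abundance (NK vs alone, per timepoint) uses a negative-binomial
Wald test: log₂FC from the +0.5-pseudo-count ratio of group means of
normalised counts, with the NB variance m + α·m² and a per-clone
method-of-moments dispersion moderated toward the ensemble estimate;
p-values are Benjamini–Hochberg corrected.

**Decision tree** (first match wins):

| rule | category | condition |
|---|---|---|
| i | primary resistant | padj < 0.05 and log₂FC ≥ +1 |
| ii | eliminated | padj < 0.05 and log₂FC ≤ −1 |
| iii | static | v ≤ 0.5 (alone) and v < 1 (NK) |
| iv | secondary resistant | v ≤ 0.5 (alone), v ≥ 1 (NK), high in exactly 1 of 3 wells |
| v | other | none of the above |

Heatmap display order within each category comes from Ward-linkage
hierarchical clustering of the normalised profiles.

## Worked example

```python
from clonefate import (GeneratorConfig, generate_library,
                       simulate_coculture, CloneFateModel)

cfg = GeneratorConfig(n_clones=400, seed=8)     # defaults = study design
library, truth = generate_library(cfg)
counts = simulate_coculture(truth, cfg)
results = CloneFateModel(counts).fit()
print(results.summary())
```

prints (abridged):

```
Clone fate analysis
=======================================================
retained barcodes: 400
thresholds: padj_cut=0.05, lfc_cut=1.0, v_alone_cut=0.5, v_nk_cut=1.0, high_well_bar=1.0

-- TP2 -----------------------------------------------
          eliminated:    233  ( 58.2%)
   primary_resistant:     61  ( 15.2%)
              static:     90  ( 22.5%)
 secondary_resistant:     14  (  3.5%)
               other:      2  (  0.5%)
      diversity drop:  22.5%  (1 - H_nk/H_alone)

per-sample Shannon diversity (ln):
            A_alone_TP2_w1: H=5.860  detected=400
               A_nk_TP2_w1: H=4.518  detected=169
...
```

The TP2 block is the headline result: of 400 simulated clones, 58.2% were
called eliminated, 15.2% primary resistant, 22.5% static and 3.5%
secondary resistant — recovering this run's generating fate distribution —
and NK co-culture reduced Shannon diversity by 22.5% relative to the
tumour-alone arm. `results.fate_table("TP2")` gives the per-clone calls
with their supporting statistics, `results.overlap(other)` compares fate
sets between experiments (Jaccard per category), and
`results.plot_heatmap()` draws the category-blocked heatmap.

The same analysis runs from the shell on real data:

```bash
clonefate report --sample-sheet samples.tsv \
    --library-fastq lib1.fastq --library-fastq lib2.fastq \
    --library-fastq lib3.fastq --library-fastq lib4.fastq \
    --out results/
clonefate selftest --n-clones 600 --workdir selftest/   # ground-truthed check
```

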