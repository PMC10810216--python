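# cistrokit

Toolkit for comparing the chromatin-binding landscapes (cistromes) and
transcriptomes of two steroid receptors — prototypically the androgen
receptor (AR) and the glucocorticoid receptor (GR) in antiandrogen-treated
prostate cancer cells. When AR signaling is blocked with enzalutamide, GR is
de-repressed and takes over part of AR's regulatory program; the questions
this package quantifies are *where* the incoming factor binds (already-open
"pre-accessible" chromatin vs closed "de novo" sites), *how much* of the
first factor's cistrome it replaces, which sequence motif drives its
binding, and which genes respond.

It is written for computational biologists who want the downstream analysis
— peak calling, differential binding/expression, accessibility
classification, overlap quantification, motif enrichment, peak-to-gene
distance statistics — as a tested, reusable library with a synthetic-data
generator that plants known ground truth, so every stage can be validated
end to end without touching raw sequencing data.

## What it computes

* **Peak calling** (`peakcalling`): fixed-width windows on tag maxima,
  retained when they pass *all* of: > 25 tags, > 4-fold over the
  depth-normalized control and over a ±5 kb local background, and a
  BH-adjusted Poisson enrichment q < 0.01.
* **Differential binding / expression** (`nbstats`): for feature counts
  K<sub>ij</sub> ~ NB(s<sub>j</sub>μ<sub>gi</sub>, α<sub>i</sub>) with
  median-of-ratios size factors s<sub>j</sub>, a per-group NB fit with
  trend-shrunk dispersion and a Wald test of
  β = log(μ<sub>B</sub>/μ<sub>A</sub>). Binding classes UN/UP/DN use
  FDR < 0.1 and fold change > 2; expression classes use FDR < 0.05 and
  |log₂FC| ≥ 0.5 on genes with TPM > 0.5 in at least one sample.
* **Accessibility classification** (`cistrome`): a binding site is
  *pre-accessible* when its basal accessibility signal exceeds 1 on the
  log₂ scale of tags normalized to 10 M mapped reads (+1 pseudocount),
  *de novo* otherwise.
* **Replacement** (`cistrome`): fraction of AR sites directly overlapped
  (≥ 1 bp) by GR sites, with the full Venn decomposition.
* **Peak-to-gene distances** (`cistrome`): nearest peak-center to TSS
  distance per gene, cumulative distributions over 0–100 kb in 10 kb bins,
  and a two-sample Kolmogorov–Smirnov test of regulated vs expressed genes.
* **De novo motif enrichment** (`motifs`): exhaustive k-mer search in
  200 bp peak windows vs 50 000 sampled background regions, matches scored
  on both strands with up to 2 mismatches, exact binomial tail p-values,
  plus PWM scanning and refinement.
* **Synthetic data** (`synthetic`): NB tag counts at planted sites over
  Poisson background, configurable shared-site and pre-accessible
  fractions, condition-dependent fold changes, planted motifs, and gene
  expression linked to planted sites — with the ground-truth labels
  returned alongside.

## Worked example

```python
from cistrokit.synthetic import SyntheticConfig, simulate_dataset, simulate_tags
from cistrokit.tagsignal import TagLibrary
from cistrokit.peakcalling import call_peaks
from cistrokit.cistrome import (
    classify_accessibility, percent_preaccessible, replacement_fraction,
)

cfg = SyntheticConfig(seed=42, n_chrom=2, chrom_length=500_000,
                      n_sites=400, n_genes=400)
truth = simulate_dataset(cfg)

gr_enz = TagLibrary.pool(simulate_tags(truth, "enz", "chip_gr"))
ar_base = TagLibrary.pool(simulate_tags(truth, "baseline", "chip_ar"))
control = TagLibrary.pool(simulate_tags(truth, "baseline", "control"))
atac = TagLibrary.pool(simulate_tags(truth, "baseline", "atac"))

gr_peaks, _ = call_peaks(gr_enz, control)
ar_peaks, _ = call_peaks(ar_base, control)
print(f"GR peaks (ENZ): {len(gr_peaks)}   AR peaks (baseline): {len(ar_peaks)}")

calls = classify_accessibility(gr_peaks, atac)
print(f"GR binding at pre-accessible chromatin: {percent_preaccessible(calls):.1f}%")

rep = replacement_fraction(ar_peaks, gr_peaks)
print(f"AR sites replaced by GR: {rep.n_ar_replaced}/{rep.n_ar} "
      f"({100 * rep.fraction_replaced:.1f}%)")
```

prints

```
GR peaks (ENZ): 316   AR peaks (baseline): 200
GR binding at pre-accessible chromatin: 90.2%
AR sites replaced by GR: 116/200 (58.0%)
```

The generator planted 90% of sites in open chromatin and made 58% of AR
sites GR-shared; the pipeline recovers both from the simulated tags alone.
The GR cistrome under enzalutamide (316 peaks) is wider than the baseline
AR cistrome because GR-only sites are planted too.

There is also a CLI for file-based work — `cistrokit run-all` drives the
whole synthetic pipeline from a YAML config, and `cistrokit callpeaks /
diffbind / access / replace / genes / motifs / expr` run single stages on
BED/TSV inputs. See `cistrokit --help`.

## Layout

```
src/cistrokit/
  intervals.py     genomic intervals, BED I/O, overlap/merge
  tagsignal.py     tag libraries, depth normalization, binned profiles
  nbstats.py       size factors, NB dispersion + Wald test, BH, KS, ANOVA
  peakcalling.py   enrichment peak caller, per-peak count matrices
  cistrome.py      accessibility, replacement, distance CDFs
  motifs.py        PWM scanning, background sampling, k-mer enrichment
  expression.py    TPM, expressed filter, DE classes, Venn, 2^-ddCt
  synthetic.py     ground-truth data generator
  pipeline.py      stage orchestration and summary.json
  cli.py           click command-line interface
docs/methods.md    model and design notes
```
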