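# Methods

## Coordinate and signal conventions

All intervals are 0-based half-open (BED convention); any 1-based display is
formatting only. The center of a peak is `floor((start+end)/2)`; derived
windows are even-width, so centering never creates asymmetric ties.
Chromosome names are compared as exact strings — no `chr` aliasing — and
`chromosome_mismatch_warning` surfaces names present in only one of two
inputs rather than silently dropping them.

A *tag* is one mapped read reduced to a single genomic position. Working at
point-tag rather than fragment level preserves all downstream arithmetic
(window counts, depth normalization, binned densities) while keeping the
exchange format a two-column TSV. An optional fixed extension for fragment
smoothing was considered and left out: none of the implemented statistics
depends on fragment shape.

Signal quantities are normalized to a reference depth of 10 million mapped
tags. Binned profiles divide additionally by bin width, giving tags per bp
per site per 10 M tags; "local tag density" is exactly this per-bp unit, not
a second background correction. Site-level box-plot quantities are
`log2(normalized count + pseudocount)` with pseudocount 1.0. The pseudocount
is exposed everywhere because it interacts with the accessibility threshold
(below): `log2(0 + 1) = 0` puts empty sites one unit below the cut.

Per-site counting uses the peak interval itself (peak-width counting). A
fixed-width alternative (count over `center_window(site, w)`) is available
by transforming the peak set first; for the 200 bp fixed-width peaks the
caller emits, the two coincide.

## Peak calling

Candidate windows of fixed width (default 200 bp) are centered on tag
positions; candidates are kept greedily, highest count first with leftmost
tie-breaking, suppressing any candidate whose center lies within one peak
width of an accepted one — so retained windows never overlap and the
procedure is deterministic. Each retained candidate must then pass all of:

* raw tag count > 25 (raw, not depth-normalized: the floor gates evidence
  quantity, and scaling it with depth would defeat that);
* count > 4 × the depth-normalized control count in the same window;
* count > 4 × the expected count from a ±5 kb local background (candidate
  window excluded);
* BH-adjusted Poisson upper-tail q < 0.01, where the Poisson expectation is
  the largest of the control, local, and genome-wide estimates.

Expected counts are floored at 0.5 tags so fold enrichment stays defined on
empty background. The genome-wide rate is estimated from the tag extent of
the treatment library itself. When no control is supplied the control
filter is skipped with a warning. The control fold uses depth-normalized
control counts (the alternative — raw control counts — makes the filter
depend on the control's sequencing depth, which is clearly unintended).

## Count statistics

The two-group testing core is deliberately compact rather than a clone of
any particular differential-analysis package; its contract is calibrated
error rates and power on simulated counts, which the test suite checks
directly.

* **Size factors**: median-of-ratios over features positive in all samples;
  library-size ratios as a warned fallback. Known property: when a large
  one-sided fraction of features truly changes (e.g. 30% of sites gaining
  4-fold), the median absorbs a little of the composition shift and null
  log2FCs acquire a small opposite-sign bias (~0.1); the handful of
  BH-permitted false calls then lands on that side. This is inherent to
  ratio normalization and is documented rather than patched.
* **Dispersion** (NB variance μ + αμ²): per-feature method of moments on
  normalized counts within each condition, pooled across conditions, then
  shrunk toward a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ with weight
  `df/(df + prior_df)` (residual df; `prior_df` 20) and floored at the
  trend. With 2–3 replicates the moment estimate is mostly noise, so the
  trend dominates; the floor clips the downward noise that would otherwise
  inflate Wald statistics. Null simulations (2000 features, α = 0.05, 2v2
  and 3v3) put the fraction of p < 0.05 at 0.04–0.055 with this scheme;
  an equal-weight unfloored mixture gave 0.063–0.074.
* **Wald test**: per-group NB maximum likelihood for the mean with size
  factors as offsets and the shrunk dispersion fixed (Newton iterations on
  the log scale), z = β̂/SE from the per-group Fisher information of the
  log-mean, normal reference, two-sided. The reported log2FC is
  `log2((μ̂_B + c)/(μ̂_A + c))` with pseudocount c = 1 normalized count,
  which keeps the statistic finite for group-wise zeros; all-zero features
  report p = 1, log2FC = 0.
* **Classification**: UP iff q < FDR-cut and the fold change exceeds the
  cut upward, DN symmetric, UN otherwise. Binding uses FDR < 0.1 with
  linear FC > 2; expression uses FDR < 0.05 with |log2FC| ≥ 0.5. The
  fold-change cut applies to the raw normalized-mean ratio, not a shrunken
  estimate.
* **KS test**: D is the exact supremum difference of empirical CDFs; p is
  asymptotic (Kolmogorov distribution at effective size n₁n₂/(n₁+n₂)),
  with scipy's exact method behind `mode="exact"` for small samples. At
  n = 20 per group the asymptotic p sits within 0.02 of a 10⁵-permutation
  estimate.
* **ANOVA**: standard one-way F plus pairwise two-sample t-tests with
  Bonferroni multiplication by the number of pairs, capped at 1. All-equal
  constant groups are reported as F = 0, p = 1.

## Accessibility and replacement

A site is **pre-accessible** when its basal (untreated) accessibility
signal exceeds 1.0 in log2 normalized tags; sites exactly at the boundary
are called pre-accessible (the thresholds are defined with strict
inequalities on both sides, so the boundary needed a documented rule; both
the cut and the pseudocount are parameters). **Replacement** is the
fraction of the first factor's sites overlapped by ≥ 1 bp of the second
factor's sites — no minimum-overlap threshold is imposed by default because
"direct overlap" carries none; `min_bp` is exposed, and the replaced
fraction is non-increasing in it. The symmetric fraction and the three Venn
counts are reported alongside.

**Peak-to-gene distances** are strand-independent linear distances from
TSS to nearest same-chromosome peak center. Genes whose chromosome carries
no peak get +∞: they stay in the CDF denominator by default (so the curve
can plateau below 1) and are always excluded from KS input. The CDF spans
0–100 kb in 10 kb bins.

## Motif analysis

Background regions are uniform draws from the supplied genome, rejecting
windows that overlap an exclusion set (the peaks themselves) or contain
non-ACGT characters; no GC or dinucleotide matching is attempted — on the
uniform synthetic genome there is no composition to match, and on real
genomes this is a known difference from composition-matched backgrounds.

De novo enrichment enumerates k-mers (k ≤ 12) occurring exactly in at least
`min_seed_seqs` target sequences (reverse-complement duplicates merged). A
sequence hits a candidate when any window on either strand is within a
Hamming-distance radius; each candidate is scored at every radius
0..max_mismatch (default 2) and keeps its best exact-binomial p. Scoring at
the best radius is essential: at a fixed radius of 2, any string sharing
k−2 bases with a true motif matches all of its instances through the free
mismatches — palindromic shifted variants (whose background rate is halved)
otherwise outrank the motif itself. Because candidates are seeded on their
exact target counts, the binomial tail is computed with the seed sequences
excluded — P(Binom(n−s, p₀) ≥ hits−s) — otherwise every seeded k-mer looks
enriched at radius 0 even on null data. The reported p additionally carries
a Bonferroni factor of max_mismatch+1 for the minimum over radii.
Background rates are floored at 1/(2·n_bg). Ranked candidates within
Hamming distance ≤ 1 of a better survivor are collapsed; each result
records the number of candidates scored so the top p can be
Bonferroni-adjusted across candidates. On null data (targets and
backgrounds from the same distribution) the candidate-adjusted top p
crosses 0.05 in ~4% of runs (300-run estimate).

PWM scanning scores Σ log2(p_base/bg_base) at every offset on both strands;
N scores −∞. PWM refinement aligns each sequence's best match to the
consensus (either strand) and builds a position-frequency matrix with +0.25
pseudocount per base.

## Expression

TPM divides counts by transcript length in kb and rescales each sample to
10⁶; no effective-length correction is applied. Genes outside a keep-list
of biotypes (default `protein_coding`) are dropped before normalization.
The expressed universe is genes with TPM strictly > 0.5 in at least one
sample across all treatments, applied globally (not per contrast) before
testing. Relative qPCR quantification is `2^−ΔΔCt` with
ΔCt = Ct(target) − Ct(control) and ΔΔCt = ΔCt(treatment) − ΔCt(vehicle).

## Synthetic data generator

The generator emulates the statistical structure of a two-factor,
two-condition receptor study: an "AR" factor active at baseline and
attenuated under antiandrogen; a "GR" factor whose cistrome partly overlaps
AR's and partly expands under treatment ("ENZ-UP" sites, 4-fold by
default); basal accessibility high at pre-accessible sites and residual at
de novo sites; motif instances planted in GR site windows; and regulated
genes whose TSSs sit within a link radius of GR sites.

Defaults (the conditions the test suite runs at): 2 chromosomes × 2 Mb,
2000 sites of 200 bp with ≥ 1 kb spacing, 50% AR sites, 58% of them
GR-shared, 90% pre-accessible, 30% of GR sites ENZ-UP at 4-fold, site mean
60 tags/replicate (strong signal separation for ground-truth recovery), NB
dispersion 0.05, background 2×10⁻⁴ tags/bp, 3 replicates, 5×10⁵ tags per
ChIP library and 10⁷ per accessibility library, motif consensus `AGAACAGA`
(a receptor-half-site-like 8-mer) sampled at 0.9 per-position fidelity into
60% of GR sites; 2000 genes with lognormal base means (median 200,
σ = 0.8), 10% regulated at |log2FC| = 1 within 20 kb of a GR site. Site
category assignments use exact counts (randomized positions), so configured
fractions are hit to rounding rather than binomial noise.

Accessibility libraries get their own depth because the classification
threshold lives on the 10 M-normalized scale: at ChIP-scale depth a single
stray background tag normalizes to ~20 tags and flips a de novo site's
label, which no realistic accessibility experiment would do. With 10⁷-tag
libraries the de novo residual mean (0.2 tags/site/replicate) keeps those
sites just under the log2 = 1 boundary while letting occasional 1–2-tag
sites probe it. Site means and the background rate scale linearly with
library depth relative to these nominals, so deeper libraries yield
proportionally more raw tags with depth-normalized values unchanged.

Every stage draws from `default_rng(SeedSequence([seed, crc32(label)]))`,
making each output byte-reproducible from (config, seed) and independent of
stage execution order.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mappability and repeat structure, GC and
cross-linking bias, fragment-length effects, correlated replicate batches,
copy-number variation, isoform structure, and motif co-occurrence (one
planted motif; real cistromes carry composite elements). The simulated
genome is i.i.d. uniform ACGT, so background motif statistics are cleaner
than in any real genome.

## Pipeline scale and determinism

The default full-pipeline run (simulate → call peaks for both factors →
differential binding → accessibility → replacement → expression → distance
CDF/KS → de novo motifs against 50 000 background windows) takes ~30 s on
one CPU; problem sizes were chosen so the complete validation suite runs in
a few minutes while leaving every estimate's Monte-Carlo error well inside
the asserted tolerances. Identical (config, seed) runs produce
byte-identical outputs; the summary JSON echoes every parameter.

Under the default dense site layout (one site per ~2 kb) every TSS is close
to some peak, so the regulated-vs-expressed distance contrast is
structurally absent and the pipeline's own KS p-value is expectedly weak;
the distance machinery is validated on a sparse configuration (20 sites on
10 Mb) where the planted linkage produces strong stochastic dominance. The
pipeline reports its KS result as computed either way.

## Known limitations

* The NB test targets two-group designs only: no covariates, batch terms,
  outlier replacement, or independent filtering.
* The motif search is k-mer-exhaustive with a single PFM refinement pass,
  not an EM/ZOOPS optimizer; it reports strings, not optimized PWMs, and
  provides a multi-k loop but no model-selection heuristic across k.
* Replacement is overlap-based; it does not model binding strength at
  shared sites.
* The peak caller assumes single-position tags and fixed-width peaks; broad
  domains and super-enhancer stitching are out of scope.
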