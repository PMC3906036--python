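# Methods

`ffpearray` implements a processing stack for 3'-biased short-oligo
expression arrays applied to formalin-fixed, paraffin-embedded (FFPE)
tissue: probe re-annotation into alternative chip descriptions,
MAS5-style / RMA / frozen-RMA summarization, degradation diagnostics, and
a frozen-vs-FFPE concordance benchmark that rates each
(normalization, description) pipeline against matched fresh-frozen data.
This note records the models, the defaults and why they were chosen, and
what the synthetic study does and does not establish.

## Probe re-annotation and alternative chip descriptions

Arrays of this class measure each gene through ~11 perfect-match 25-mers
grouped into vendor probesets that reflect the transcript annotation at
design time.  `ffpearray.cdf` re-annotates probes by **exact** (no
mismatch) 25-mer matching against a one-isoform-per-gene transcriptome
(the longest isoform per gene; equal lengths break toward the
lexicographically smallest transcript id, for determinism).  A probe is
kept only if it matches exactly one gene; a probe matching one gene at
several positions keeps the most-3' position, so each probe carries a
single 3' distance `d = L - (start + 25)` (0-based, half-open
coordinates; `d` is measured to the probe's 3'-most aligned base, so a
probe "within 300 bp" lies entirely inside the window).

Two re-annotated descriptions are built:

* **refseq_all** — all uniquely mapping probes of a gene merged into one
  probeset (splitting across vendor probesets is undone); genes with
  fewer than 5 unique probes are dropped.  More probes per probeset means
  more statistical power per expression value.
* **refseq_dist** — at most the 5 probes closest to the 3' end, all
  required within 300 bp of the 3' terminus.  Fragmented FFPE RNA is
  reverse-transcribed from the 3' end, so these probes retain the most
  signal.  Genes with fewer than 5 qualifying probes are dropped by
  default; `min_dist_probes` exposes the choice because keeping sparser
  probesets is equally defensible.

Ties at the selection boundary break toward the smaller probe id.  Probe
tables stored in array orientation are handled by `revcomp_probes=True`;
the default matches probe sequences directly against the transcript sense
strand.

## Normalization engines

All engines operate on a raw probe x sample matrix restricted to one chip
description.

**RMA.**  Per array, the observed intensity is modelled as signal plus
optical background, `o = s + b`, `s ~ Exp(alpha)`, `b ~ N(mu, sigma^2)`;
the background-corrected value is the posterior mean
`E[s|o] = a + sigma * phi(a/sigma) / Phi(a/sigma)`, `a = o - mu -
sigma^2 * alpha`, evaluated in log space so deep-background values stay
positive.  Parameters come from the classic mode-based heuristic (mode of
the density's lower tail for `mu`, doubled spread below the mode for
`sigma`, mean excess above the mode for `alpha`).  The kernel bandwidth
is robust — `0.9 * min(sd, IQR/1.34) * n^(-1/5)` — because an sd-only
rule oversmooths heavily right-skewed intensity distributions and loses
the background peak.  Arrays are then quantile-normalized (tied values
receive the mean of the reference values at their occupied ranks),
log2-transformed, and summarized per probeset by Tukey median polish
(tolerance 0.01 on the largest absolute row/column median, at most 10
sweeps — the conventional caps).  `background_correct=False` skips the
convolution step for data known to carry no optical background, where
the heuristic has no peak to find.

**MAS5-style (PM-only).**  Re-annotated descriptions carry no mismatch
probes, so the ideal-mismatch step is omitted and the 16-zone spatial
background is replaced by a global per-array background (2nd percentile
of all probe intensities, result floored at 2^-20).  Probeset signal is
the one-step Tukey-biweight location (c = 5, epsilon = 1e-4) of the log2
probe values; arrays are scaled so the 2%-trimmed mean of signals equals
500.  Expression is reported in log2.  Because the background is a
percentile of the intensity distribution itself, weakly expressed genes
are intrinsically distorted — this is the algorithm's real behavior, and
the main reason it ranks last in the benchmark.

**Frozen RMA (fRMA).**  Parameters are estimated once from a pool of
reference arrays organized in batches: reference quantiles are the mean
sorted (background-corrected) intensity vector over all reference arrays;
probe effects come from a median polish of the pooled normalized log2
data; the polish residuals are decomposed into a within-batch variance
and a between-batch variance per probe.  A new array is then processed
*alone*: background-corrected, quantile-normalized to the frozen
reference, log2, probe effects subtracted, and summarized per probeset by
a precision-weighted mean (weights `1/(sigma2_residual + sigma2_batch)`)
combined with one-step Huber down-weighting (k = 1.345) of outlying
probes.  One-step rather than fully iterated Huber keeps the estimator
deterministic and cheap while retaining the down-weighting contract; a
random-effects BLUP weighting would be an equally defensible reading, so
anyone comparing against archived parameter files should check which
scheme those used.  If every variance component in a probeset is zero the
weights collapse to uniform; a zero total weight falls back to an
unweighted Huber mean with a warning.  By construction the expression of
a sample never depends on which other samples are processed with it.

## Degradation diagnostics

* **Rank profile** — probe intensities averaged by within-probeset
  position (5'→3') over all vendor probesets sharing the modal probe
  count, one curve per array, with a least-squares slope per array.  FFPE
  arrays show markedly steeper 5'→3' gradients than matched frozen
  arrays.
* **Correlation vs distance** — frozen–FFPE correlation of probe-level
  log2 intensities as a function of the probe's 3' distance (default
  25-bp bins over 0–600 bp).  Default pooling computes r per probe across
  matched pairs and averages within a bin, which is robust to probe
  affinity differences; `probesxpairs` pools all points in a bin into a
  single correlation.  The curve declines with distance and flattens once
  probes sit mostly in background.
* **Decay-scale fit** — under multiplicative decay `exp(-d/lambda)` the
  mean per-probe log2 frozen/FFPE ratio is linear in `d` with slope
  `log2(e)/lambda`.  The estimator background-corrects both arms first
  and uses probes with `d <= 300 bp`, because the optical floor flattens
  the ratio for strongly decayed probes and otherwise biases `lambda`
  upward by 30–50%.

## Concordance benchmark

Frozen-derived expression is the gold standard.  Per pipeline:

* **Sample correlation** — Pearson r per matched pair over all probesets
  (median reported).
* **Probeset correlation** — Pearson r per probeset across pairs, on the
  top 50% of probesets by frozen-arm IQR (unexpressed probesets carry no
  usable signal); retained zero-variance probesets are excluded, not
  reported as NaN.
* **Differential expression** — equal-variance two-sample t per probeset,
  Benjamini–Hochberg adjustment; the default call rule is raw p < 1e-4,
  with BH < 0.01 exposed as an alternative because both rules are in
  common use.
* **Fold-change agreement** — Pearson r (Fisher-z CI) and OLS slope
  (t-based CI) of FFPE fold changes on frozen fold changes, over **all**
  common probesets (DE status is an annotation, not a filter).  The CI
  level defaults to 0.95 with 0.90 available; degenerate |r| = 1 clamps
  the interval to contain the estimate.  Slopes below 1 quantify FFPE
  attenuation.
* **Sensitivity / PPV** — fraction of frozen-DE probesets recovered in
  FFPE, and of FFPE-DE probesets confirmed in frozen; empty denominators
  are reported as missing.
* **Leave-one-out** — sensitivity/PPV recomputed with each matched pair
  removed (DE only is recomputed; normalization is not re-run, matching
  how such robustness checks are done in practice), reported as mean/SD.
* **Pipeline tests** — Wilcoxon signed-rank on per-pair sample
  correlations (paired; exact null for n <= 25; p = 1 by convention for
  identical inputs) and Wilcoxon–Mann–Whitney on probeset correlations
  (the probeset universes differ between descriptions, so pairing is not
  possible).

## The synthetic study

The generator emulates matched frozen/FFPE hybridizations with known
truth.  On the log2 scale, a matching probe `p` of gene `g` in pair `j`
yields

    frozen: 2^(g_gj + a_p + eps)                    + b
    FFPE:   2^(g_gj + a_p + eps) * exp(-d_p/lambda_j) + b

with probe affinity `a_p ~ N(0, 0.7)`, measurement noise `eps` (sd 0.25
frozen, 0.5 FFPE — the FFPE inflation factor of 2 is a free parameter,
not an empirically reported value), and an optional additive optical
background `b` (log-normal around 2^4, sd 0.3 log2), on by default.  The
additive term is what makes the RMA convolution model estimable, gives
MAS5 a real background to subtract, and produces the fold-change
attenuation seen on archival material; setting `additive_background=False`
recovers the pure multiplicative model used by the exactness tests.
Expression is `g_gj = base_g (+/- 1.0 log2 in subgroup B for 15% of
genes, sign random) + N(0, 0.5)`, with `base_g ~ N(7, 2)`; the biological
draw is shared by the two preservation arms of a pair, and subgroup
effects are applied identically in both arms so frozen DE is a valid
gold standard.  Each FFPE sample draws `lambda_j` from
`decay_scale_range`, fixed at 150 bp by default.

The chip design plants the pathologies a dated vendor annotation shows:
per gene, 9 matching probes tiled every 50 bp from the 3' end plus 2
"stale" random probes inside the same vendor probeset (11 probes total);
30% of genes carry a second vendor probeset tiling further 5' (merged by
refseq_all); 20 probes are made ambiguous by planting their 25-mer into
two transcripts (their intensity sums both targets); 50 decoy probes
match nothing and read background only, as do stale probes (log-normal
around the 5th percentile of matching-probe intensities).  Transcript
lengths are uniform on 800–1600 bp so every tile fits.

Reference pools for frozen-parameter estimation are frozen-type arrays
with fresh biological draws and a small per-batch per-probe shift
(sd 0.1 log2) so the between-batch variance component is estimable.

**Study sizes.**  The benchmark study uses 2,000 genes and 10+10 matched
pairs with a 20x5 reference pool; the unit-test fixture uses 120 genes
and 4+4 pairs.  These sizes keep the full 9-pipeline benchmark in the
low minutes on one core while leaving every qualitative contrast
measurable.

**What passing does and does not show.**  The generator reproduces the
mechanisms — exponential 3' decay, probe-level affinity, optical
background, annotation drift — but not cross-hybridization beyond the
planted ambiguous probes, spatial chip artifacts, MM-probe behavior,
amplification chemistry, or realistic expression correlation structure.
Absolute metric values are therefore not comparable to real cohorts
(synthetic probeset correlations are far higher than on clinical
material); only the orderings and recovery properties are meaningful.
With ~100 DE calls per arm at this scale, sensitivity-based orderings
carry binomial noise of about +-0.05, comparable to the true gaps
between the better pipelines, so those two orderings are stable only for
most, not all, random seeds.

## Numerical choices and degenerate inputs

* Background-correction mode estimation thins to 5,000 evenly spaced
  order statistics and evaluates the KDE on a 512-point grid; constant
  vectors raise a degenerate-density error; a pathological mode at the
  minimum falls back to the median split.
* Quantile-normalization ties: mean of the reference values at the
  occupied ranks (exact float equality defines a tie).
* Median polish: sweep order rows-then-columns, effects re-centered into
  the overall term each sweep; the decomposition identity holds exactly
  at every iteration.
* MAS5 floor after background subtraction: 2^-20.
* fRMA weight floor: variances clipped at 1e-12 before inversion; a
  probeset whose variances are all zero uses uniform weights.
* Empty distance-correlation bins report r as missing with occupancy 0.
* Self-comparison of a pipeline reports p = 1 by convention.
* All randomness flows from a single integer seed through per-stage
  substreams; identical configurations produce bit-identical outputs.

## Known limitations

* Binary vendor chip formats (CEL/CDF) are not parsed; text dialects
  carry the same information and adapters can populate the in-memory
  types.
* Probeset selection per gene ("best probeset" filtering of the vendor
  description) is provided only as a trivial max-IQR stand-in, not the
  published selection method.
* The MAS5 engine is a PM-only reading; numbers are not expected to
  match vendor software on PM/MM arrays.
* Mismatch-tolerant alignment and genome (rather than transcriptome)
  mapping are out of scope.
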