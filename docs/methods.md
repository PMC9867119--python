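# Methods

`mirshift` implements an integrative transcriptomic analysis for
pressure-overload heart failure: it asks whether a large-scale rise in
miRNA abundance can account for the asymmetric (down-dominated) change in
mRNA expression, by linking differential miRNA abundance to seed-match
target sites in 3'UTRs and measuring the per-site repression of target
transcripts.  Every stage can be driven by a synthetic-data generator with
planted ground truth, which is how the package validates itself.

## Differential expression

Counts are modelled non-parametrically: normalization plus a two-sample
test per feature.

* **mRNA**: each library is scaled to the mean library size (total-count
  normalization), features are pre-filtered at FPKM > 2
  (FPKM = count x 10^9 / (length x library size)), and groups are compared
  with the equal-variance Student's t-test.  A gene is called changed when
  fold change > 2.0 (strict) and p < 0.05 (raw).
* **miRNA**: libraries are normalized so that the geometric mean of two
  invariant reference miRNAs (miR-126a-3p, miR-19b-3p) is equal across
  samples, features are pre-filtered at mean count > 100, and the cut-off
  is fold change > 1.70, p < 0.05.

Conventions the cut-offs do not pin down, chosen here and configurable:
fold change is the ratio of pseudocounted (0.5) group means taken in
whichever direction makes it >= 1; the abundance filter uses the mean
across samples (a minimum-based filter is available); significance uses
the raw p-value to match the stated cut-offs, with Benjamini-Hochberg
q-values reported as an informational column; Welch's test is available
by flag.  Degenerate inputs are defined rather than left to float
arithmetic: zero pooled variance with equal means gives t = 0, p = 1, and
with unequal means t = +/-inf, p = 0.

## Seed-match target scanning

The seed is miRNA positions 2-8 (1-based, 5' end).  A canonical site on
the UTR sense strand is the reverse complement of the seed (7mer-m8), of
positions 2-7 (6mer), or either followed by an A opposite position 1
(8mer, 7mer-A1).  The scanner enumerates all occurrences of the four
match strings and resolves them with one deterministic rule: sort by
(start, strength), sweep left to right, keep a candidate only if it does
not overlap an accepted site; at equal starts the stronger type wins
(8mer > 7mer-m8 > 7mer-A1 > 6mer).  Coordinates are 0-based half-open
throughout; DNA input (T) is normalized to RNA (U).  By default a gene
counts as "targeted" through 7mer-or-stronger sites only — 6mers are
scanned and reported but excluded from targeted calls, since their signal
is weak and prediction databases disagree on their inclusion; the
`types` argument restores them.

## Cumulative fold-change shift

Genes passing the FPKM filter are stratified by their number of seed
sites for the significantly *up*-regulated miRNAs (default strata 0 / 1 /
2-4 / >=5; the bin edges are a package choice and configurable).  Each
stratum's log2 fold-change distribution is compared with the zero-site
background by a two-sided two-sample Kolmogorov-Smirnov test; the
stratum's median shift is median(stratum) - median(background).  The KS
statistic D is the supremum ECDF distance; the default p-value uses the
asymptotic Kolmogorov distribution at effective size
n_a n_b / (n_a + n_b), which is accurate to O(n^-1/2) — an exact
label-permutation p-value (add-one estimator, tolerance-guarded
comparison at the observed statistic so tied permutation mass is not
dropped by float jitter) is available where that matters.

## Site prioritization

Predicted sites are annotated with Ago2 CLIP peak overlap (>= 1 nt
intersection under half-open semantics by default; a minimum-overlap or
site-within-peak criterion is configurable), the maximum height among
overlapping peaks, and the mean per-base conservation over the site span,
classified Cons when the mean exceeds 0.6 (strict).  Bases missing from
the conservation track score 0, which is conservative toward Noncons.
Candidates are ranked by (Ago2 overlap, peak height, conservation score,
position) — a total, deterministic order.  `enrichment_table` tabulates
validation outcomes by Ago2 x conservation cell with per-Ago2 marginals.

## Functional readouts

**PSI** (percent spliced in) is 100 x inclusion / (inclusion + exclusion),
computed identically for band intensities and counts, NaN when both are
zero; no saturation correction is applied.

**Calcium line scans** are time x position matrices with sampling
interval `dt` (ms).  On the spatially averaged trace: F0 is the mean of
values at or below the 20th percentile (a fixed pre-onset window is
available by flag); transients are local maxima above F0 + 3 SD(baseline)
with >= 200 ms separation and a prominence of at least a quarter of the
global rise — the prominence guard stops noise wiggles riding a slow
decay from being counted as transients, since the amplitude threshold
alone cannot.  Amplitude is (peak - F0)/F0; FDHM is the distance between
the two half-maximum crossings, each located by linear interpolation.
Crossings are located on a 5-frame moving average of the trace: the
moving average leaves linear segments unchanged (piecewise-linear
fixtures stay exact) while suppressing the early-stopping bias that
raw-trace threshold walks acquire under noise; the peak value itself is
taken from the raw trace so amplitudes are not flattened.  Synchrony COV
is the coefficient of variation of per-position half-rise times: for each
position, the time from the global transient onset (5% rise crossing of
the averaged trace) at which that position first reaches half of its own
peak rise; positions with no resolvable rise are excluded with a warning.
This per-position-normalized definition is robust to spatial amplitude
gradients; other windows over "the rising phase" are defensible and would
give slightly different absolute COV values, though the zero-jitter limit
(COV = 0) and the recovered jitter SD do not depend on the choice.  All
three metrics are invariant to rescaling the fluorescence values.

## Synthetic data: what it emulates

The generators reproduce the study design the analysis expects: two
groups (sham / TAC), quadruplicate miRNA libraries, duplicate mRNA
libraries, a predominantly upregulated miRNA compartment with two
invariant reference miRNAs, and per-site repression of targeted genes.

* **miRNA counts**: negative binomial with variance mu + phi mu^2
  (default dispersion phi = 0.05, a conventional bulk small-RNA value;
  the real libraries' dispersion is unknown), log-normal per-miRNA
  baselines around 500 counts, and a planted fraction (default 0.35) of
  non-reference miRNAs whose TAC mean is multiplied by a fold drawn
  log-normally around 2.5, floored at 2.0 so every planted effect exceeds
  the 1.70 calling threshold.  Reference miRNAs are abundant and
  unchanged by construction.
* **UTRs**: i.i.d. uniform A/C/G/U backgrounds (mean length 800 nt,
  15% SD) with 0-5 planted sites per gene, types uniform over the four
  classes.  Background is rejection-sampled and patched so *no*
  unplanned seed match to any supplied miRNA exists, and guard bases
  prevent a planted site from reading as a stronger type (e.g. an A
  immediately after a planted 7mer-m8 would upgrade it to an 8mer); a
  final scan verifies that the planted truth is recovered exactly, so
  site-count truth is exact, not approximate.  Supplied miRNAs must have
  distinct seeds — seed-sharing family members would make site ownership
  ambiguous.
* **mRNA expression**: a gene's true log2 fold change is
  delta_per_site x (number of planted sites for upregulated miRNAs),
  delta_per_site <= 0 (default -0.2 log2 per site).  Per-sample
  abundances are log-normal around the group mean (replicate scatter
  0.25 log2 units) and counts are Poisson at a depth giving ~20 counts
  per FPKM unit, so count noise is realistic but not dominant.
* **Ago2 peaks**: each planted site is covered with probability
  `site_recall` (default 0.7) by a peak strictly containing it; decoy
  peaks (1 per kb) avoid planted sites; heights are log-normal.
* **Conservation**: high scores (0.9) over a designated conserved subset
  of planted sites, low (0.2) elsewhere, Gaussian noise (SD 0.05) clipped
  to [0, 1] — at the 0.6 threshold site-level misclassification is below
  1%.
* **Line scans**: fluorescence = F0 + F0 x amplitude x kernel, kernel a
  difference of exponentials normalized to unit peak (default rise 25 ms,
  decay 150 ms — neonatal-cardiomyocyte order), onsets evenly spaced with
  a quarter-period lead-in of baseline, per-position onset jitter shared
  across transients, Gaussian noise, dt = 1 ms.  The recorded truth FDHM
  is computed from the kernel's half-maximum crossing times by root
  finding, independent of the measurement path.

What the generators do **not** emulate: real 3'UTR base composition and
repeat structure (accidental near-sites, GC bias), miRNA families with
shared seeds, non-canonical and 3'-supplementary pairing, expression-
dependent dispersion trends, batch effects, CLIP library biases, and
motion or photobleaching artifacts in imaging.  Passing the planted-truth
checks therefore demonstrates that the *computational* pipeline is
correct and calibrated, not that the biological effect sizes of any
particular dataset will match.

## Validation design and problem sizes

The acceptance checks run at desk scale, chosen to finish in minutes
while leaving usable statistical resolution: seed scanning is verified
against an exhaustive substring oracle on 1,000 random UTRs x 10 miRNAs;
the KS statistic against a quadratic brute force on 1,000 sample pairs
(and its permutation p against the exact conditional distribution);
interval overlap against an all-pairs oracle on 10,000 configurations.
Null calibration uses 100 simulation seeds; shift recovery uses 30 seeds
of 300 genes (the per-stratum recovery check uses simultaneous
Bonferroni-adjusted 95% intervals so the joint test, not each of three
strata separately, has the nominal confidence); the down-dominance check
uses 20 seeds of 500 genes with delta_per_site = -0.35, an effect size
at which multi-site genes clear the 2-fold calling threshold, mirroring
the regime where repression is strong enough to dominate the
differential-expression table.

## Known limitations

* The t-test at duplicate (n = 2) mRNA libraries has very low power; the
  pipeline reproduces this property of the design faithfully rather than
  substituting a shrinkage estimator.
* The asymptotic KS p-value is anticonservative/biased by O(n^-1/2) for
  small strata; use the permutation option for small n.
* Seed scanning is sequence-only: no pairing thermodynamics, site
  accessibility, or expression weighting.
* The conservation class uses a single threshold on the site mean; no
  phylogenetic model.
* `normalize_by_references` requires strictly positive reference counts
  in every sample and fails loudly otherwise.
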