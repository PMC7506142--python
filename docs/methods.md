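# Methods

## Coordinate model

All intervals are 0-based half-open. Each gene is represented by one
3'UTR — the transcript with the longest total UTR length, ties broken by
the lexicographically smallest transcript id so results are independent
of input order. UTR-local coordinate 0 is the 5'-most UTR base; on the
minus strand that is the highest genomic coordinate, and genomic blocks
are walked in transcript order during conversion. A genomic site that
intersects several blocks of a spliced UTR maps to the single contiguous
local interval covering the union of its per-block intersections — a
conservative choice that never splits a peak. Sites partially outside
the UTR are clipped to it rather than dropped; sites entirely outside
are ignored. 1-based inclusive TSV input is supported behind a dialect
flag, but BED I/O is natively 0-based half-open.

Pooling collapses identical (regulator, gene, interval) records, and by
default also merges overlapping or book-ended intervals of the same
regulator on the same gene, because broad CLIP peaks frequently arise
from several adjacent binding events merged by peak callers. Merging can
be disabled when per-study site counts matter.

## Seed matching

The seed is nucleotides 2–8 (1-based) of the mature microRNA; the mRNA
target motif is its reverse complement in the RNA alphabet. Scanning is
exact 7-mer string matching, reporting every (possibly mutually
overlapping) occurrence. This is a deliberate simplification of
full-scale target prediction — no site-type hierarchy (8mer vs 7mer-A1),
no context scoring, no conservation — chosen because the downstream
analysis only needs site *positions*, and exact matching makes the
generator's ground truth exact. Homologous family members sharing a seed
are treated as independent regulators even where their matches coincide,
since family members need not share expression patterns.

## Accessibility filter

Tracks are per-nucleotide unpaired probabilities, read from RNAplfold
`_lunp`-style files (the single-nucleotide column) or a TSV. A site
passes when the **mean** unpaired probability over its interval is at
least the threshold (default 0.5, boundary inclusive). The mean was
chosen over min/max because it is monotone in the threshold, robust to a
single structured base inside a long peak, and easy to reason about;
both the statistic and the cutoff are configurable. Computing the
probabilities themselves (a partition-function calculation) is out of
scope; the generator draws background accessibility from Beta(8, 2) —
mostly open chromatin-free RNA with occasional structured patches — and
forces planted sites to 0.85–1.0 (or 0.0–0.1 for decoys).

## Overlap scenarios and the randomization null

Two sites overlap when their half-open intervals intersect (≥ 1 shared
nucleotide); a relaxed variant counts gaps smaller than `max_gap`
(e.g. 5 nt) as overlap for sensitivity analysis. Scenario labels are
assigned per (pair, gene) trio — a pair may be overlapping on one gene
and neighboring on another; no pair-level collapse is performed because
the group tests operate on trios. Pairs sharing no gene are flagged
independent at pair level.

The null model re-places every site independently and uniformly on its
own gene's UTR, preserving the site count, each site's length, and the
gene assignment — the spacing between sites is *not* preserved, which
makes the null exactly enumerable in small cases (two length-3 sites on
a 10-nt UTR overlap with probability 34/64). Default 10 rounds; each
round's random stream is derived from (seed, round index) so results are
reproducible and rounds could be run in parallel. Same-regulator
self-overlap after randomization is allowed but never scored; only
cross-regulator overlap counts.

## Expression preprocessing

Features missing in strictly more than 30% of samples are dropped
(exactly 30% survives). Remaining gaps are filled by k-nearest-neighbor
imputation over features: the imputed cell is the mean, over the k = 10
nearest features by nan-aware Euclidean distance (computed on
co-observed samples and rescaled by the co-observation count), of their
values at that sample. The implementation delegates to
scikit-learn's `KNNImputer` applied to the feature-rows orientation,
which realizes exactly this rule; a brute-force oracle verifies it in
the tests. An optional log2(x+1) transform is available for count-like
inputs; the synthetic benchmark generates on a Gaussian scale and does
not use it.

## Interaction model

Per trio, `y = a1·x1 + a2·x2 + a3·x1·x2 + a4` is fitted by ordinary
least squares with an intercept; `a4` is interpreted as
intercept-plus-residual ("regulation by everything else"). The test on
`a3` is two-sided (competition and cooperation both count) using the t
distribution with n − 4 degrees of freedom and standard errors from the
unbiased residual variance. Trios need n ≥ 5 samples. Degenerate
designs (rank < 4, e.g. a constant regulator) are flagged and excluded
downstream with a counter; machine-precision exact fits (residual sum of
squares below 1e−24 of the response's scale) report p = 0 for a nonzero
`a3` with a degeneracy flag rather than dividing by a zero standard
error.

Independent pairs have no shared target, so no natural `y` exists. For
each such pair the package samples genes targeted by exactly one member
of the pair, drawing the per-pair trio count from the empirical count
distribution of the overlapping group (fixed seed), which gives the
three scenario groups comparable sizes in the KS comparison.

BH adjustment is computed within each (condition, regulator-class
combination, scenario) family, step-up with a cap at 1 and NaN
passthrough. The KS comparisons consume raw p-values, not q-values.

## Group comparisons

The one-sided two-sample KS statistic is
`D⁺ = sup_t [ECDF_x(t) − ECDF_y(t)]`: when group x's p-values are
collectively smaller, its ECDF rises first and D⁺ is large. The p-value
is the plain asymptotic tail `exp(−2·D⁺²·n_x·n_y/(n_x+n_y))`, capped at
1, without the finite-sample Hodges correction (group sizes in practice
are large; the tests document the exact relationship to the corrected
form). For tiny groups (n_x + n_y ≤ 20) a seeded permutation p-value is
used instead. Scenario group inputs are sorted before testing so results
are invariant to fit ordering.

Recurrence testing crosses trio significance (q < 0.05) with pair
membership in a 2×2 table per pair per condition and computes the
one-sided hypergeometric (enrichment) p, BH-adjusted across pairs within
each condition; pairs significant in ≥ 2 conditions are reported as
recurrent. The one-sided direction was chosen because the question is
enrichment, not depletion.

## Synthetic data generator

The generator is the package's test bed: it emulates the *statistical
shape* of a CLIP catalog + target-prediction + expression study, not its
biology.

* **Defaults** (the study conditions of the benchmark): 300 genes with
  UTR lengths uniform on [200, 1000] nt; 10 RBPs, 10 microRNAs; 15
  overlapping and 15 neighboring RBP–microRNA pairs, 5 genes each; RBP
  site lengths uniform on [10, 30] nt; 100 samples per condition
  (tumor / normal); regulator expression i.i.d. standard normal; main
  effects |a1|, |a2| ~ U(0.3, 0.8) with random sign, interactions
  |a3| ~ U(0.5, 1.0) for overlapping trios, U(0.2, 0.5) for neighboring,
  exactly 0 for everything else; noise σ = 1. These sizes keep a full
  run around two seconds while leaving the KS comparisons decisive; the
  neighboring range is smaller than the overlapping one to mirror the
  expectation that co-bound but non-overlapping regulators interact more
  weakly.
* **Planting**: each pair-gene receives a microRNA seed site (the motif
  is physically written into the UTR sequence) and an RBP site that
  intersects it by ≥ 1 nt (overlapping) or sits ≥ 10 nt away
  (neighboring — far enough that the 5-nt relaxed overlap variant cannot
  flip the label). Each gene belongs to at most one pair, so scenario
  labels are unambiguous. Unassigned genes carry one site from a single
  regulator, providing the gene pool from which independent-pair trios
  are sampled. Spurious seed-motif occurrences in the random background
  are mutated away, so exact scanning recovers exactly the planted
  microRNA sites.
* **Decoys**: a configurable fraction of planted sites (only those whose
  footprint is private, so neighbors are unaffected) is written below
  the accessibility threshold; the filter must drop exactly these.
* **Missingness**: optional missing-completely-at-random injection with
  recorded positions, off by default, used to exercise the
  preprocessing contract.
* **What it does not emulate**: real UTR length distributions (heavy
  tails), clustered binding within a UTR, correlated regulator
  expression, count noise, tumor/normal effect differences, or confounded
  pair frequencies. Passing the benchmark therefore shows the machinery
  is correct and calibrated — not that the effect sizes seen in real
  cancer cohorts are recoverable.

A reduced configuration (`SimConfig.small()`: 60 genes, 5+5 regulators,
40 samples) is used where many replicates are needed, e.g. the 100-run
null calibration; the single recovery run uses the full default
configuration.

## Known limitations

* Exact 7-mer seed matching under- and over-calls real microRNA sites
  relative to context-aware predictors.
* The accessibility rule (mean single-nucleotide unpaired probability,
  cutoff 0.5) is a declared stand-in; no published cutoff exists for
  this filtering step, and results should be checked for robustness
  across thresholds.
* The randomization null resamples site starts independently; a
  spacing-preserving null would be stricter for clustered sites.
* OLS on expression assumes additive Gaussian noise on the chosen scale;
  heavy-tailed counts should be log-transformed first.
* Scenario labels depend on the chosen (longest) UTR isoform; genes with
  strong alternative polyadenylation may be misclassified.
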