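# transinteract

Detecting interactions between *trans* regulators — RNA-binding proteins
(RBPs) and microRNAs — from the geometry of their binding sites on 3'UTRs
and from expression data.

## The problem

An mRNA's 3'UTR is crowded: CLIP-seq catalogs place millions of RBP
binding sites there, and microRNA seed matches land in the same region.
When two regulators bind the same UTR their sites may *overlap* (share at
least one nucleotide), sit *neighboring* on the same transcript without
overlapping, or the regulators may be *independent* (no shared target at
all). Overlapping sites are the spatial precondition for direct
competition or cooperation. `transinteract` implements the complete
analysis:

1. **Site catalog** — choose each gene's longest 3'UTR, map binding-site
   intervals into UTR-local coordinates, pool sites across studies.
2. **Seed targeting** — extract the microRNA seed (nucleotides 2–8 of the
   mature sequence), derive the mRNA target motif (its reverse
   complement) and scan UTR sequences for exact matches.
3. **Accessibility filter** — keep RBP sites whose mean per-nucleotide
   unpaired probability (RNAplfold `_lunp`-style tracks) reaches a
   threshold, since most of these RBPs bind single-stranded RNA.
4. **Overlap classification** — label every regulator pair on every
   shared gene as overlapping or neighboring, and estimate the chance
   level of overlap by re-placing each site uniformly at random on its
   own UTR (default 10 randomization rounds).
5. **Interaction regression** — per (regulator, regulator, target) trio,
   fit

   ```
   y = a1·x1 + a2·x2 + a3·x1·x2 + a4
   ```

   by OLS, where `x1`, `x2` are the regulators' expression levels and `y`
   the target's; the two-sided t-test on the interaction coefficient `a3`
   flags competitive or cooperative regulation. P-values are
   Benjamini–Hochberg adjusted (q < 0.05).
6. **Group comparison** — one-sided two-sample Kolmogorov–Smirnov test
   (`D⁺ = sup_t [ECDF_x(t) − ECDF_y(t)]`, p ≈ exp(−2·D⁺²·n_x n_y/(n_x+n_y)))
   asking whether the overlapping group's interaction p-values are
   collectively smaller than the neighboring and independent groups',
   plus one-sided Fisher tests for pairs recurrently enriched among
   significant trios across conditions.

A fully-instrumented synthetic-data generator plants known overlapping /
neighboring pairs and known interaction coefficients, so every stage can
be validated against ground truth.

## Worked example

```bash
python examples/full_pipeline.py
```

generates the default synthetic benchmark (300 genes, 10 RBPs, 10
microRNAs, 15 planted overlapping and 15 neighboring pairs, 100 samples
per condition, seed 42) and prints:

```
catalog: 450 sites on 300 genes
trios fitted: 950
planted overlapping pairs recovered: 100%

-- tumor --
condition     group_x     group_y  n_x  n_y   d_plus         p_ks
    tumor overlapping neighboring   75   75 0.773333 3.314705e-20
    tumor overlapping independent   75  800 1.000000 2.751781e-60
    tumor neighboring independent   75  800 0.825000 2.895424e-41
```

Every planted overlapping pair is recovered from the site geometry alone,
and the KS comparisons confirm that interaction p-values are smallest in
the overlapping group, intermediate in the neighboring group, and null in
the independent group — exactly the planted structure. The other
examples (`seed_matching.py`, `overlap_randomization.py`,
`interaction_regression.py`) each exercise one capability in isolation.

A thin CLI mirrors the library for file-based use:

```bash
transinteract simulate --seed 42 -o bundle/
transinteract catalog --annotation bundle/annotation.tsv --sites bundle/sites.bed -o catalog.tsv
transinteract classify --catalog catalog.tsv --annotation bundle/annotation.tsv -o trios.tsv
transinteract randomize --catalog catalog.tsv --annotation bundle/annotation.tsv --rounds 10 --seed 17 -o null.json
```

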