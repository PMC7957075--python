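# Methods

## Units of analysis

All statistics are computed over fixed-width transcriptomic bins (default
200 bp). Binning walks each gene's mature (spliced) transcript 5′→3′ and
lifts every bin back to genomic coordinates; a bin whose footprint touches
more than one exon is a *junction* bin, otherwise *exonic*. A bin therefore
has an exact width in transcript space but may consist of several genomic
fragments; all interval overlap is computed against the fragments, so a site
falling entirely inside an intron never counts. Trailing transcript
remainders shorter than one bin are dropped rather than emitted short —
resolution is fixed, and a variable-width tail would not be comparable to
the other bins. Bins with identical genomic spans (isoform duplicates) are
deduplicated keeping the first gene id in input order.

Reproducible m⁶A regions are individual bins, not merged runs: every
downstream count (N_t, classifier features) is defined per bin, and merging
would conflate region count with region length. A merge step could be added
as presentation-layer convenience but plays no role in any statistic.

## Consensus rule

A study calls a bin iff ≥ `min_replicate_frac` (default 0.6, inclusive: 3 of
5 passes) of its replicates call it; a bin is reproducible iff ≥
`min_studies` (default 3) studies call it. The same-study reading is used:
the replicate rule must be satisfied within each of the counted studies.
The rule is monotone (adding a call never removes a region; raising either
threshold never adds one) and idempotent on its own output; both properties
are asserted in tests. The ≥ comparisons carry an epsilon of 1e-9 so that
exact fractions such as 3/5 are not lost to binary floating point.

## Enrichment test

For RBP *p*: N_t = number of m⁶A regions with ≥ 1 bp overlap by a site of
*p*; control sets are drawn from the **control pool** — all bins of genes
containing ≥ 1 m⁶A region, minus the m⁶A regions themselves — matching the
m⁶A set's exonic/junction counts exactly, without replacement within a set,
independently across the `n_perm` = 1000 sets. R = N_t / E(N_c); the
one-sided empirical p is the inclusive proportion #{N_c ≥ N_t}/n_perm.

Decisions worth recording:

- One shared sequence of control sets serves all RBPs. This is cheaper than
  per-RBP resampling, marginally valid for each RBP, and makes the whole
  result table reproducible from a single seed. It induces (weak) dependence
  between RBPs' p-values, which is irrelevant for BH under positive
  dependence.
- The raw proportion k/n_perm is stored; reports display p = 0 as
  `<1/n_perm` because the resolution of the test ends there. A
  `pseudo=True` option computes (k+1)/(n_perm+1) for users who prefer a
  never-zero estimator.
- Depletion is read descriptively off R < 1; there is no second one-sided
  test. The classifier, being direction-blind, is the instrument that
  surfaces depleted RBPs.
- E(N_c) = 0 with N_t > 0 yields R = +inf with an `infinite` flag; with
  N_t = 0 the ratio is NaN (`undefined`) and p is set to 1.
- Stratum exhaustion (a control stratum smaller than its required count)
  raises an error naming the stratum; silently relaxing the matching would
  reintroduce the position confounder the matching exists to remove.

### Calibration and pool size

The permutation null is exact only insofar as each control set is
exchangeable with the m⁶A set. When the pool is small relative to the
region set the conditional spread of N_c under-represents the sampling
variability of N_t and the test becomes anti-conservative, with rejection
inflation on the order of regions/pool. In real transcriptomes the
non-methylated bins of m⁶A genes outnumber the regions many-fold, so the
synthetic calibration checks use a geometry with pool ≈ 47× the region set
(400 long genes, ~52k bins, 1,000 m⁶A regions). Users applying the test to
small custom universes should be aware of this regime.

## Classifier

Positives are m⁶A regions with ≥ 1 bound RBP; all-zero feature rows cannot
carry information and are excluded from the positive class (controls are not
filtered — unbound controls are legitimate). Each of the
`n_control_sets` = 10 control sets matches the positives' stratum
composition and size. Per set: stratified 80:20 split; 5-fold CV accuracy is
measured inside the training portion (validation), then the forest (500
trees by default, `mtry = floor(sqrt(n_features))`, here the familiar 8 for
~71 features) is refit on the training portion and scored on the untouched
20 % — confusion counts, accuracy, AUROC, ROC curve. Both CV and held-out
accuracies are reported, labelled, since either convention is defensible.
Importance is mean decrease in impurity, normalised to sum 1 per run; runs
are aggregated by arithmetic means, ROC curves averaged vertically on a
fixed 101-point false-positive-rate grid.

Impurity importance was chosen over permutation importance: it is the
standard forest default, cheap, and sufficient for ranking binary features;
its known bias toward high-cardinality features cannot act here because all
features are binary.

## Association analyses

- Co-binding: cosine similarity between binary binding columns (values in
  [0,1]); all-zero columns are flagged NaN rather than given an arbitrary
  similarity. Clustering is average linkage on 1 − cosine; columns are
  name-sorted before linkage so the dendrogram is invariant to input order.
  Linkage and distance are recorded in the run manifest because they are
  conventions, not forced choices.
- Expression: Spearman rank correlation (average ranks on ties) of each
  RBP's tissue profile against an effector's profile; values are used as
  given — no log transform, since ranks are transform-invariant. Group
  comparison is the two-sample one-sided Mann–Whitney rank-sum test (the
  groups are different RBP sets, so a paired statistic would be wrong):
  exact p for ≤ 25 total tie-free observations, normal approximation with
  tie correction otherwise; completely tied inputs return the symmetric
  p = 0.5 instead of a degenerate tail. A `tissue_subset` helper slices the
  panel so that protein- and transcript-level comparisons can use equally
  sized tissue sets.

## Synthetic-data generator

The generator starts at the bin-call level a transcriptome-based peak caller
produces; it simulates no reads or coverage. Defaults describe one study
design: four independent studies with 2–3 replicates each (nine samples) at
200-bp resolution; 15 % of bins truly methylated; per-sample call
probabilities 0.8 (methylated) / 0.05 (background), i.e. a recoverable but
noisy signal consistent with the substantial between-study irreproducibility
of MeRIP-Seq. RBP tracks are Bernoulli per (RBP, bin) at `p_m6a` or `p_bg`,
with each emitted site placed uniformly inside one genomic fragment of its
bin, so planted rates translate exactly into overlap rates and sites stay
within gene spans. The default panel holds two readers (0.50/0.25,
0.40/0.20), one repelled RBP (0.10/0.60) and eight nulls (0.30/0.30).

Expression tables share a single latent tissue profile z ~ N(0,1); an entity
in group g gets `c·z + sqrt(1−c²)·noise_sd·ε` with c the group's latent
correlation, then `exp(·)` for positivity (strictly monotone, so Spearman is
untouched). With `noise_sd = 1` the population correlation of an entity with
the latent profile is exactly c; groups with c = 0 are independent of it.

Truth labels (which bins are methylated, each RBP's planted role, the latent
correlations) travel only in a JSON sidecar, never in the emitted BED/TSV
files, so no pipeline stage can read them.

What the generator does **not** emulate: motif sequence context, coverage-
dependent peak-calling noise, correlated binding between RBPs (beyond what
the planted m⁶A status induces), gene-expression-dependent detectability,
and strand-specific binding. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under an idealised noise
model, not that the biological conclusions of any particular dataset are
correct.

## Problem sizes and numerics

Test and acceptance workloads are scaled for a laptop-class single core: the
calibration geometry uses ~52k bins/1,000 regions/800 null RBPs with 1,000
permutations; classifier checks use ~2,000-sample datasets, 10 control sets
and 200 trees; expression power uses 100 simulations of a 15-vs-56 panel.
Forest and split seeds derive from one user seed via `SeedSequence`, so
every stage is reproducible bit-for-bit; all seeds stay below 2³¹.

## Known limitations

- The enrichment test conditions on the realised control pool; very small
  pools make it anti-conservative (see above), and the package does not
  warn about this automatically.
- Stratum matching covers only the exonic/junction axis; no GC, length or
  expression covariates are matched.
- Overlap is strand-blind and requires ≥ 1 bp; no minimum-fraction rule.
- BH is applied within one run (one species/cell line); combining runs into
  a single family is the caller's responsibility.
- The CLI reads whole BED files into memory; it targets transcriptome-scale
  inputs (10⁴–10⁶ intervals), not genome-wide billion-row tracks.
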