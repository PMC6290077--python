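# Methods

This note records the statistical model behind each component, the defaults
and why they were chosen, and what the synthetic benchmark does and does not
demonstrate.

## Two-colour differential expression

Each dataset is a direct two-colour comparison of a resistant population
against a susceptible reference on a shared probe set.  For probe *g* on
array *i* the data are transformed to

- M_gi = log2(R_gi / G_gi), sign-flipped on dye-swapped arrays so positive
  M always means higher expression in the resistant sample, and
- A_gi = (log2 R_gi + log2 G_gi) / 2.

A is computed from the physical channels and is unaffected by orientation.
Only the direct resistant-vs-susceptible design is supported; loop designs
with contrast matrices are out of scope.

**Within-array normalisation** subtracts a robust loess fit of M on A
(local linear regression, tricube weights).  Defaults: span 0.4, four
robustifying iterations.  These are conventional values for two-colour
arrays; they are exposed as parameters because no single span is right for
every platform.  Arrays with fewer than 50 probes fall back to
median-centering with a warning, since a local fit on so few points is
noise.  The fit itself is delegated to `statsmodels`' lowess; the test
suite checks it against a direct weighted-least-squares implementation.

**Between-array normalisation** (Aquantile) maps each array's A values
rank-wise onto the mean of the sorted A vectors, leaving M untouched, so
intensity distributions agree across arrays without disturbing the
log-ratios.  Ties in A are resolved by stable sort order; with continuous
intensities exact ties are measure-zero, and the defining postcondition
(equal sorted A vectors) holds regardless.

**Inference** uses an empirical-Bayes moderated one-sample t-test on the
normalised M matrix.  Per-probe sample variances s²_g (df d = n−1) are
shrunk toward a prior s₀² with prior degrees of freedom d₀:

    posterior variance = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g = mean(M_g) / sqrt(posterior variance / n),   df = d₀ + d.

d₀ and s₀² are estimated by matching the mean and variance of log s²_g to
the scaled-F model (digamma/trigamma moment equations; the trigamma inverse
is solved by Newton iteration).  When the observed spread of log-variances
does not exceed the chi-square expectation, d₀ is infinite and all probes
share s₀².  Zero variances are floored at 1e−8 before taking logs.
P-values are two-sided; multiple testing uses the Benjamini–Hochberg
step-up adjustment (`q_i = min over p_j ≥ p_i of m·p_j/rank_j`, capped at
1), which is order-preserving and never below the raw p.

Setting the prior df to 0 recovers the ordinary t-test; the suite pins this
limit, the dye-swap involution (swapping every physical channel negates
every mean M and leaves |t|, p and q unchanged), null calibration
(type-I error and p-value uniformity on planted-null simulations) and
power on planted twofold changes.

Background correction is not implemented: input intensities are assumed
background-corrected upstream.

## Probe → transcript consensus

A transcript measured by several probes in one dataset receives a single
value only under the consensus rule: strictly more than 75% of its probes
must share fold-change direction (FC>1 vs FC<1).  Three of four probes is
exactly 75% and fails — the strict reading is pinned by an exhaustive
enumeration test over all direction/significance patterns for 1–6 probes.
If direction consensus fails but every probe is non-significant (q > α),
the transcript is kept as `all_nonsignificant`; otherwise it is flagged
`discordant` and carries no value in that dataset.

Averaging is geometric on fold changes (arithmetic on log2), because
arithmetic averaging of ratios is not symmetric under inverting the strain
orientation; q values are averaged arithmetically, as a summary of
probe-level adjusted significance rather than a recomputed test.
Probes flagged as cross-hybridising participate in aggregation but taint
their transcripts with a warning flag that is carried into the integrated
table, since their signal may mix genes.

## Consensus meta-signature

Over a metadata-selected set of datasets, a transcript is "up" when its
fold change exceeds 1 in every selected dataset and (by default) q ≤ α in
every selected dataset; "down" symmetrically.  A fold change of exactly 1
(possible after averaging) belongs to neither direction and excludes the
transcript.  Transcripts absent or discordant anywhere in the selection are
excluded.  Because the filter is a per-dataset conjunction, shrinking the
selection can only grow the signature, and dropping the significance
requirement can only grow it too — both monotonicities are property-tested.
Whether published selections demanded per-dataset significance is ambiguous
in general, so `require_significance` is an explicit flag.

Splice variants are first-class: signatures are reported at transcript
level and collapsed to gene stems (`-RA`/`-RB` suffixes) only on request.

The candidate-frequency screen (e.g. for transcription-factor lists) counts
the datasets in which a candidate is significant in either direction and
passes it when the count strictly exceeds `min_fraction` of the datasets —
with 31 datasets and 50% the threshold is 16.  Direction-consistent
counting is available behind a flag; either-direction is the default
because regulators can plausibly act in both directions across
populations.

## Correlation networks

For a focal transcript, Pearson correlations are computed against every
other transcript row over pairwise-complete datasets, on log2 fold changes
(ratio-scale correlations would be dominated by the largest fold changes; a
flag restores raw ratios).  Edges require |r| ≥ cutoff — "≥" so that a
published cutoff value includes itself; a strict-mode flag uses ">" — and
at least `min_overlap` complete pairs (default 10 of 31; fewer than 3 pairs
never forms an edge, and constant vectors are skipped).  Splice variants of
the focal gene are ordinary partners.  Correlation rows are transcripts,
not collapsed genes, so a focal gene's own variants can (and should) appear
in its network.

## Enrichment

Over-representation of a gene set in a query list uses the hypergeometric
upper tail P(X ≥ q) with population m + n, set size m and draws k; the
implementation delegates to the log-space survival function of
`scipy.stats.hypergeom` and is verified against exhaustive draw enumeration
for all populations up to 12.  The universe is always explicit input
(typically all transcripts in the integrated table): genome-wide universe
sizes are annotation-build-dependent and silently baking one in would make
p-values irreproducible.  BH adjustment is applied across the sets tested
in one call.

## Variance partitioning

For a one-way factor with a levels the unbiased variance-explained
estimator is

    ω² = (SS_treatment − (a − 1)·MS_within) / (SS_total + MS_within).

Unlike η², ω² is unbiased under the null and may be slightly negative for
uninformative factors; negative values are reported as-is.  Each factor
needs at least two levels with at least two observations each; others are
skipped with a warning.

The response for "variation explained by metadata" is a reconstruction,
not a published procedure: by default each dataset is scored on the first
principal axis of the row-centred log2 fold-change matrix (absent cells
contribute zero after centring), with an alternative that averages ω² over
per-transcript responses on complete rows.  The PC1 default summarises the
dominant expression axis in one number per dataset, which is what a
between-dataset ANOVA needs.

## Reports and maps

The per-transcript report carries raw fold change in tables and log2 in
plots, q values, and the count of datasets with q ≤ α.  Map output is one
point per dataset in which the transcript is significant, categorised as
`down` (FC < 1), `up_low` (1 < FC ≤ 5) or `up_high` (FC > 5).  The
boundary FC = 5 is assigned to `up_low` (the "1–5" bin read as inclusive);
a significant fold change of exactly 1 triggers a data-quality warning and
is skipped rather than forced into a category.  Output is GeoJSON plus
TSV; no tile service is involved.

## Synthetic data

`simulate_integrated` emulates the study design at the table level:
n_datasets independent comparisons of a resistant population against a
susceptible reference on a shared probe set.  True log2 fold changes are

    log2FC[g, d] = planted_g + loading_g · f_d + ε,   f_d ~ N(0, 1),

with planted_g = ±planted_log2fc for the planted up/down sets and latent
factors f_d generating co-expression modules (expected within-module
correlation loading²/(loading² + σ²)).  Observed values come from
simulated replicate arrays (Gaussian noise, SD `noise_sd` per array);
per-dataset q values are obtained by the same moderated-t-plus-BH test the
raw-signal pipeline applies, so table-level and signal-level simulations
are consistent.  Probe-level values then pass through the real consensus
aggregation, so every generated table has traversed the same code path
real data would.

Defaults mirror the emulated study: 31 datasets, 6 replicate arrays,
replicate noise SD 0.5 on the log2 scale, 56 planted up and 30 planted
down transcripts at log2 FC 2 (fourfold — typical of strong detoxification
candidates), one six-transcript module with unit loading and residual SD
0.1, significance level 0.05, 1000 transcripts (a desk-scale stand-in for
the ~15k-probe platform), ~30% of transcripts with 2–3 probes, 2% of
background probes cross-hybridising and 15% of genes with a second splice
variant.  Cross-hybridising probes are confined to background transcripts:
a probe mixing a planted transcript with a background gene genuinely
measures a mixture, which would make the planted ground truth ambiguous —
the benchmark instead keeps contamination observable (via the warning
flags) but separate from the planted signal.

`simulate_raw_signals` adds the signal level: probe A values uniform on
[6, 14] log2 units, a smooth intensity-dependent dye bias
(0.4·sin-shaped in A by default) injected into the raw log-ratio so loess
has a real trend to remove, and a configurable fraction of dye-swapped
arrays.

What the generator does **not** emulate: array spatial artefacts,
background subtraction, probe sequence effects and saturations, correlated
noise between probes of one transcript beyond the shared true value,
population structure among datasets, or realistic numbers of non-null
transcripts.  Passing the benchmark therefore shows the algorithms are
correct and calibrated under the stated model, not that real arrays meet
that model.

## Numerical choices

- Variance floor 1e−8 before log-variance moments and shrinkage.
- Trigamma inverse by Newton iteration, 60 iterations max, relative
  tolerance 1e−12.
- Loess fallback to median-centering below 50 probes.
- Pearson r clipped to [−1, 1] against rounding excursions.
- BH uses a stable mergesort so tied p-values adjust identically.
- Geometric means are computed as exp(mean(log FC)), never as products.

## Reproducing the results

`scripts/acceptance.py --seed N --out results/acceptance.json` regenerates
every headline quantity from scratch: the frequency-screen threshold for a
31-dataset study, agreement rates of the consensus filter, probe-consensus
rule and BH adjustment against independent oracles, hypergeometric
agreement with exhaustive enumeration, the ω² worked example, DEA type-I
error / p-value uniformity / power on planted raw-signal simulations,
dye-swap invariance, latent-module network recovery, and planted-signature
recall on the full default synthetic study.  Problem sizes are those
stated above (2000 probes and 6 arrays for the signal-level runs; 31
datasets and 1000 transcripts for the study-level runs) — large enough for
stable rates, small enough to run on a laptop in well under a minute.

## Known limitations

- Only direct R-vs-S designs; no loop designs, no spot quality weights,
  no print-tip loess, no background correction.
- q values of aggregated transcripts are averaged probe-level q values,
  not a recomputed transcript-level test.
- Correlation networks carry no multiple-testing control on r (by design —
  the cutoff is the stringency control), and no partial correlations.
- The ω² metadata screen depends on the chosen per-dataset response; the
  PC1 default is one reasonable summary, not the only one.
- Numeric output of the DEA chain is not expected to be bit-identical to
  any other implementation of the same procedure (different loess
  windowing and hyperparameter estimation details); the tests pin
  behaviour against oracles and calibration instead.
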