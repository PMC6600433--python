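# Methods

This note documents the statistical procedures, parameter choices and
numerical conventions behind `concordx`, and what the synthetic-data
generator does and does not emulate.

## Spot-level miRNA preprocessing

Each array is a GenePix-style table of spots: triplicate spots per
probe, a set of negative-control spots, per-spot quality flags, and a
per-array background-region SD (raw intensity units, measured off-spot
by the scanner software and carried as metadata).

* **Spot intensity** is foreground median − background median and may
  be ≤ 0. Non-positive intensities become *missing* before the log2
  transform rather than being clamped: they carry no usable signal, and
  because they can never exceed the detection threshold this choice
  cannot change detection semantics.
* **Detection threshold.** T(raw) = 10% trimmed mean of the
  negative-control spot intensities + 5 × background SD, then
  T(log2) = log2 T(raw). The threshold is computed in raw units first
  and transformed, matching the order in which the quantities are
  defined. Comparison against T is strict (`>`).
* **Trim convention.** "10%/20% trimmed mean" removes that fraction
  from *each* tail; when n·trim is fractional the per-tail count is
  truncated (the `scipy.stats.trim_mean` convention). Both-tails was
  chosen over total-fraction trimming as the dominant convention in
  statistical software; tests pin the behaviour against a brute-force
  sort-and-slice oracle.
* **Normalization.** A probe counts as detected in an array when the
  mean of its unflagged log2 spot intensities exceeds that array's
  T(log2). N(array) is the 20% trimmed mean of the array's spot
  intensities over the probes detected in *all* arrays; normalized
  values are x − N + mean(N), and each array's threshold is shifted by
  the same amount so detection is assessed on the normalized scale.
  The detection judgement at probe level (mean of spots) rather than
  spot level is a documented choice; the upstream definition does not
  distinguish them.
* **Triplicate collapse** averages unflagged, non-missing spots per
  probe per array, recording the contributing count; zero contributors
  yield a missing cell, which the detection filter treats as
  not-above-threshold.

## In vivo differential expression

Contrasts are independent two-group comparisons: each treatment group
versus the vehicle control at the same time point. The test is a
one-way ANOVA with two groups, whose F statistic is exactly the square
of the pooled-variance t statistic (asserted numerically in the
tests). Per contrast, q-values are Benjamini–Hochberg; a probe is
called when p < α (0.05), q ≤ FDR (0.10) and linear fold change ≥ 1.5
in either direction. Fold change is reported signed:
FC = sign(Δ)·2^|Δ| for Δ the log2 group-mean difference. A probe with
zero pooled variance gets p = 1 with a warning.

The variance filter removes probes with across-sample variance
*above* the cutoff (default 0.2). Removing high-variance probes before
testing is unusual — it discards exactly the probes most likely to
respond — but it reproduces the upstream QC rule this pipeline
implements, where the rule was vacuous in practice; it is off by
default in `de_invivo` and exposed as a config value.

## Two-class unpaired SAM

The moderated statistic is d = (x̄₂ − x̄₁)/(s + s₀) with s the pooled
standard error √((1/n₁+1/n₂)·Σss/(n₁+n₂−2)). Internals follow the
canonical published formulation; each is an explicit function or
parameter:

* **s₀ selection** minimizes the coefficient of variation of the d
  spread (median absolute deviation / 0.64) across 100 s-quantile
  windows, over candidate s₀ values at the 0, 5, …, 100th percentiles
  of s. Deterministic given the data. A degenerate s distribution
  (zero range) falls back to median(s) with a warning; on data where s
  is constant all choices give rank-identical d.
* **Permutation null.** All distinct treated-label splits are
  enumerated when there are ≤ 10,000 of them (e.g. 20 for 3 vs 3, 924
  for 6 vs 6), making the run seed-independent; otherwise `n_perm`
  (default 500) random splits are drawn from a seeded generator.
  d̄₍ᵢ₎ is the mean of the i-th order statistic across splits.
* **Calling rule.** For each delta on a 100-point grid from 0 to
  max|d − d̄|: the upper cut is the smallest d with d − d̄ ≥ delta, the
  lower cut the largest d with d − d̄ ≤ −delta; genes beyond either cut
  are called. Counts use the union of the two regions (at tiny delta
  the regions can overlap; a gene is never counted twice, and on the
  rare overlap a gene's direction follows the sign of d).
* **FDR estimate.** median-over-permutations count of permuted d
  beyond the cuts, × π₀, / #called. π₀ is the fraction of observed d
  inside the interquartile range of the pooled permuted d values,
  scaled by 2 and capped to [0, 1]. The FDR curve is monotonised by a
  running minimum over increasing delta, and the chosen delta is the
  smallest grid point with estimated FDR ≤ target and a non-empty
  called set; if none exists the called set is empty and the full
  delta/FDR table is still returned.

No numerical identity with any particular SAM implementation is
claimed; correctness is defined by the statistic's algebraic reduction
to the pooled t at s₀ = 0 and by exact agreement of the delta/FDR
table with brute-force enumeration on exhaustive-permutation cases.

## In vitro chain

Masking reasons are applied in priority order: control spot →
saturated (either channel) → non-uniform outlier (either channel) →
not above background (fails only when *neither* channel is above
background) → present. The min-present filter (default 10) applies to
the collated multi-array table, so small per-condition sample counts
are fine as long as the experiment as a whole has ≥ 10 usable values
per probe.

"k-nearest-neighbour imputation" replaces each missing value by the
mean of the k (default 10) nearest *probes* at that sample, with
NaN-aware Euclidean distances rescaled by the fraction of co-present
columns so sparsity does not shrink distances; this is delegated to
`sklearn.impute.KNNImputer`, whose semantics match exactly. Present
values are never altered. k = 10 is the long-standing default of
gene-expression imputation routines; it is a parameter, not a fitted
value.

SAM needs complete data, so it runs on the imputed matrix; fold
changes and directions are computed from pre-imputation group means
(NA-omitting), and the final called set is the intersection of the SAM
calls with |FC| ≥ 1.5. A probe whose group is entirely NA before
imputation is excluded from that contrast with a reason flag rather
than being given an imputed fold change.

## Ortholog resolution and concordance

Ambiguous ortholog records (one-to-many, many-to-many) are grouped
into connected components of the bipartite human–mouse symbol graph;
each component contributes exactly one pair, drawn uniformly from a
per-component RNG stream derived from the user seed and the component's
canonical (lexicographically minimal) member — so results are
invariant to row order and reproducible across runs. Conflicting
duplicate one-to-one records are a hard error.

Concordance pools in vivo calls over MWCNT dose groups ("called in any
dose" qualifies; a `doses` argument restricts; the asbestos positive
control is excluded by default) and accepts a human call at any in
vitro time point. Direction conflicts — across doses in vivo, or
across time points in vitro — exclude the gene and are logged, rather
than letting an arbitrary dose/time win. The same exclusion logic
applied to cross-compartment summaries means a gene only appears in
the lung∩blood intersection when every record of it shares one
direction. Matching is case-insensitive on symbols with uppercase
output; miRNA names are first harmonised (species prefix stripped,
`miR-` casing unified, mature-arm suffixes such as `-3p` preserved and
required to match).

## Synthetic data

The generators emulate the study designs the pipeline targets: spot
arrays with triplicate spots, negative controls, Bernoulli per-spot
flags and an optional fraction of probes at negative-control signal
level; complete in vivo log2 matrices (gene baselines ~ N(8, 2),
default 8 samples/group); in vitro log-ratio matrices centred at 0
(default 3 samples/group, two cell types × two time points collated so
the min-present filter is meaningful at its default) with missingness
injected through the "not above background" QC column. The raw spot
model is foreground = background draw + 2^(log2 baseline + planted
shift + N(0, noise_sd)), chosen so median-background subtraction and
the 5×SD threshold margin behave realistically.

Default effect and noise sizes for the end-to-end recovery experiment
are planted |log2 FC| = 1.5 with noise_sd = 0.2 — a strong but
plausible microarray response — among 2000 genes with 12 concordant,
10 discordant and 10 + 10 one-sided planted genes. Sub-seeds are
derived deterministically per array/stage (CRC-based spawn keys), so
identical configs are byte-reproducible.

What the generator does *not* emulate: probe-sequence effects,
intensity-dependent (lowess-type) dye bias, correlated missingness,
batch structure, or real biological covariance between genes (each
gene's noise is independent). Passing recovery tests therefore
demonstrate the correctness of the statistical chain under its own
assumptions, not performance on real arrays, where effect sizes are
smaller and noise is structured.

## Scale choices

Test and demo problem sizes (2000 genes for recovery, 200–500 probes
elsewhere, 50 null replicates, 500 permutations or exhaustive) were
chosen so the full suite runs in well under a minute while keeping
Monte-Carlo noise far from every asserted margin.

## Known limitations

* The permutation FDR is coarse for tiny designs (3 vs 3 has only 20
  splits); delta selection then lands on whatever the 20-split median
  allows. This mirrors the method itself, not an implementation limit.
* `choose_s0` needs enough probes (≥ 50 recommended) for stable
  quantile windows; below that it warns.
* The in vitro reader consumes the package's own feature-table dialect
  (explicit QC boolean columns); adapting vendor feature-extraction
  schemas is a thin mapping the caller supplies.
* Pathway/enrichment analysis of the concordant sets is out of scope.
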