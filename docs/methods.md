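# Methods

## The model

Dynamic network biomarker (DNB) theory describes a dynamical system near
a codimension-one bifurcation: as the dominant eigenvalue of the
linearised system approaches the stability boundary, the state variables
spanned by the critical eigendirection lose their restoring force.  In
expression data this manifests as a group of genes whose fluctuations
grow (critical slowing down), whose mutual correlations approach one
(they are all driven by the same soft mode), and whose correlation with
genes outside the critical subspace decays.  The composite index

    CI = SD_d · PCC_d / PCC_o

aggregates the three signatures for a candidate group within a window of
samples: `SD_d` is the mean across group genes of the sample standard
deviation (n − 1 denominator); `PCC_d` the mean absolute Pearson
correlation over unordered gene pairs inside the group (defined as 1 for
a singleton); `PCC_o` the mean absolute correlation over all group ×
non-group pairs.  Pairs involving a gene constant within the window
contribute 0; if `PCC_o` is exactly zero the index is reported as +inf
with a warning.  CI is not scale-invariant — scaling a group's values by
k scales CI by k — which is why the scan requires rank-normalised input.

## Normalisation

Each sample (column) is mapped to a uniform distribution on (0, 1) by
`value -> rank / (G + 1)` with average ranks for ties.  This is the
canonical monotone map of a sample to uniform margins; it removes
array-level intensity effects and makes SD comparable across genes.  Raw
values are retained alongside, because fold changes and ANOVA are
meaningless on uniform ranks.  Normalising twice is an error by
construction.

A consequence worth knowing (see Limitations): per-sample ranking is
*compositional*.  When a sizeable gene block surges to the extremes of a
sample's distribution it displaces every other gene's rank in that
sample, which induces spurious block-versus-rest correlation.

## Sliding windows

Samples are sorted by age; windows cover `[i, i + w)` for starts
`0, step, 2·step, …`, with a final window anchored at `S − w` so no
window is ever short.  Each window is labelled with the median age of
its members.  The default is `w = 7, step = 1`.  Seven is a deliberate
choice: at n = 4 points the null distribution of the Pearson
correlation is exactly uniform on [−1, 1] (E|r| = 0.5; one pair in ten
shows |r| > 0.9 by chance), so window correlations carry almost no
signal; at n = 7 the null E|r| drops to ≈ 0.36 and module structure
becomes estimable, while a 13-sample infant course still yields seven
windows of trajectory.

## Dominant-group search

Per window: (1) candidate genes are pre-selected as the 100 highest-SD
genes within the window — rising SD is itself one of the three DNB
criteria, and restricting the pool keeps the dendrogram from being
dominated by chance correlation structure, which at these sample sizes
otherwise swamps any real module; (2) the candidates are hierarchically
clustered (average linkage) on the distance 1 − |r|; (3) every cluster
produced by a dendrogram merge whose size lies in `[min_size, max_size]`
(defaults 5 and G/5) is scored with the full-transcriptome CI; (4) the
cluster with maximal finite CI wins, ties broken toward the smaller
cluster, then the lexicographically smallest member id.  The tipping
point is the window of maximal CI (earliest on ties) and the DNB gene
set is the winning group there.

A structural caveat: the exhaustive scoring competes a real module
against its own luckiest small sub-cluster.  With window-level
correlation estimates (Fisher z spread ≈ 1/√(n−3) ≈ 0.58 at n = 7) a
5–7-gene core of the module typically shows PCC_d within 2% of 1, while
the full module pays a small estimation penalty; the PCC_o penalty for
leaving module members outside pulls the other way.  The net margin is
on the order of 1–2% of CI, so on some datasets the reported DNB set is
a high-purity core of the underlying module rather than the whole
module.  Group sizes across neighbouring windows (the `group_size`
column of the per-window table) make this visible in practice.

## Significance

Two instruments, one crude and fast, one honest and slow:

- **Leave-peak-out z**: `z = (max CI − mean(rest)) / sd(rest)`,
  significant at `z ≥ z_threshold`.  Because each window's CI is itself
  the maximum over many candidate clusters, the null peak z is far
  larger than pointwise intuition suggests: on transition-free
  synthetic data (flat schedules) the null z has median ≈ 2.4 and 95th
  percentile ≈ 4.0.  The default threshold 4.5 is calibrated to that
  null (measured over 100 flat-schedule simulations at the default
  generator geometry).  Conversely a *genuine* transition that spans
  several overlapping windows produces a broad CI plateau, which
  inflates the leave-one-out spread and deflates z — the statistic is
  conservative exactly when the signal is strong and smooth.  Treat it
  as a screen, not a verdict.
- **Age-permutation test** (`fit(permutations=B)`): shuffle the
  age-to-sample assignment, rebuild windows, rerun the full scan, and
  report the fraction of permutations whose peak CI reaches the
  observed peak.  This accounts for the adaptive per-window search and
  the window overlap; it is B full scans, so it costs B times the scan.

With fewer than three windows no significance is assessed (verdict
false, z undefined).

## Differential expression

Per-gene one-way fixed-effects ANOVA on `log2(raw + 1)` (log stabilises
the variance of intensity-scale data), Benjamini–Hochberg step-up
adjustment, and a linear-scale fold change `(mean_after + c)/(mean_before
+ c)` with the matrix's smallest positive value as default pseudocount.
A gene is a DEG when `q < 0.01` and `max(FC, 1/FC) > 2` — the fold
criterion is direction-symmetric, so 2-fold down counts.  The default
design splits samples at the tipping age (before: age ≤ split); an
explicit group mapping supports multi-period ANOVA.  Genes with zero
between- and within-group variance get p = 1; zero within-group variance
with a real mean difference gives p = 0.

When validating against the generator, the 3-vs-3 contrast compares the
stable periods immediately flanking the transition rather than the
tipping period itself: during the transition the planted module's
variance surge moves 3-sample means by more than 2-fold without any
planted mean shift, which is a property of the transition, not a false
discovery of the caller.

## Ordination

PCA centres each gene and decomposes by SVD; each axis is oriented so
its largest-magnitude gene loading is positive.  The 1-D age trajectory
uses classical (Torgerson) MDS — double-centred squared Euclidean
distances, top eigenvector scaled by the root eigenvalue — oriented so
the youngest sample sits below the oldest.  Classical MDS on Euclidean
distances equals the PCA first axis up to sign; the test suite asserts
this to 1e−8, which also serves as the cross-check between the two
implementations.  The "fraction of change in the first year" statistic
is operationalised as the coordinate range covered by samples at or
below the cutoff age divided by the full coordinate range; it is
monotone in the cutoff by construction.

## The synthetic generator

A linear-Gaussian latent-factor model generates `n_periods × 
samples_per_period` age-stamped samples over `n_genes` genes:

    x_gene = b_gene + s_gene · a · g_t + [L_p · f_t]  + e,
    f_t ~ N(0, σ_p²),  g_t ~ N(0, 1),  e ~ N(0, noise_sd²)

- `b_gene`: gene-specific baseline, N(baseline_mean, baseline_gene_sd²)
  for background genes (default 100 ± 12) — real transcriptomes are
  heterogeneous in level, and this heterogeneity is what makes a gene's
  per-sample rank stable in the absence of signal;
- `g_t`: a weak transcriptome-wide factor entering with a *random sign*
  `s_gene` per gene and amplitude `a` set so background pairs correlate
  at `background_corr` (default 0.25).  The random signs matter: a
  common shift of every gene is invisible to per-sample ranking;
- the DNB block (default 50 genes) shares one common baseline and loads
  on its own factor `f_t` with loading `L_p` (0.5 off-tipping, 3.0 at
  the tipping period) and factor sd `σ_p` (1.0 off-tipping, 200.0 at the
  tipping period).  The tipping-period surge is deliberately violent —
  the factor's variance diverges at a bifurcation, and at window-level
  correlation estimates a modest surge is statistically invisible.
  Downward excursions bottom out at a small positive floor, the
  generator's detection limit, as silenced genes do on an array;
- the DE block (default 40 genes) has its mean multiplied by `de_fold`
  (default 4) for every period after the tipping period.  DE baselines
  are drawn from the upper tail of the level distribution so the mean
  step, which is co-located with the transition, stays nearly invisible
  in rank space: the two planted signals — a correlation/variance
  transition and a mean shift — remain separable, and each validation
  battery tests its own target.

Within-block correlation has the closed form
`(L²σ² + a²)/(L²σ² + a² + noise_sd²)`, which the tests compare against
simulation at n = 500.  Ages default to `0.05·(period+1)` years with the
tipping period at index 3 (0.2 years), echoing an infant course.  The
flat-schedule `null_config()` plants nothing: constant loading and
factor sd, no DE step.

What the generator does **not** emulate: probe-level noise, batch
effects, inter-individual variability beyond i.i.d. noise, age-dependent
background drift, and gradual (rather than single-period) transitions.
Passing the validation battery therefore shows the machinery is correct
and well-calibrated under the planted model, not that every real course
with these properties will be detected.

## Recovery evaluation

`evaluate_recovery` compares a scan with the planted truth: the window
offset is measured against the set of windows whose age label is nearest
the planted tipping age (pooled windows repeat median ages, so the
nearest label is generally shared by several windows); a hit is an
offset of at most one window.  Module recovery is the Jaccard index
between the reported DNB set and the planted block.

## Numerical choices

- Pearson correlations are computed by normalised inner products;
  constant rows give zero rows in |r| (their pairs contribute 0).
- Sample SD uses the n − 1 denominator everywhere.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`;
  an independent step-up oracle cross-checks it in the tests.
- Ties in ranks get average ranks (deterministic).
- The pipeline seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence(entropy=seed, spawn_key=(stage,))`, so a
  stage run standalone reproduces its in-pipeline behaviour.

## Known limitations

- **PCC_o under rank normalisation.**  When the surging module is a
  non-negligible fraction of the transcriptome (50/1000 by default), its
  occupancy of the extreme ranks compresses every other gene's
  percentile in the surge samples, inducing spurious anti-correlation
  between module and background.  Measured on the default generator,
  the true block's PCC_o is ≈ 0.36 in quiet windows but 0.5–0.6 at the
  tipping window: the third DNB criterion (PCC_o drop) is *inverted* in
  rank space.  CI still peaks strongly at the transition because the
  SD_d and PCC_d surges dominate, but PCC_o should not be interpreted
  as an independent confirmation on rank-normalised data with large
  modules.
- **Core-versus-module ambiguity** of the exhaustive cluster scoring,
  described above.
- **Peak z conservatism on broad plateaus**, described above; use the
  permutation test for real claims.
- Windows are positional in the age-sorted sample list; unequal
  replicate counts per period shift window/period alignment, which the
  median age label only partly absorbs.
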