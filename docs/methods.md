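# Methods

`gbsdiv` quantifies how random missingness and map-independent genotype
imputation bias the standard estimators of a crop genetic diversity
analysis.  This note records the models, the defaults and why they were
chosen, and the limits of what the test suite establishes.

## Data model

Genotypes are diploid and biallelic, coded per cell as 1 (homozygote AA),
2 (heterozygote Aa), 3 (homozygote aa), with missing cells allowed
anywhere.  Matrices are oriented lines × markers throughout.  Two views of
a genotype are used: the raw 1/2/3 code scale (regression and PCA operate
directly on it, and the binning thresholds are defined on it) and the
allele-count scale x = 3 − code ∈ {2, 1, 0}, which counts copies of allele
A and underlies the AMOVA distance.  Keeping a single documented bijection
between the two avoids sign errors.

## Missingness simulation

A "missing level" m means: draw exactly round(m·N) of the N = lines ×
markers cells uniformly without replacement and set them missing, ignoring
any pre-existing missingness, line identity, and marker identity.  On a
complete matrix the realized missing fraction equals m; on data that
already contain missing cells the realized fraction is slightly below
m + m₀ because draws can hit already-missing cells.  This literal "count
the draws" reading is the implemented one; masking the whole matrix and
then subsampling is distributionally equivalent to masking the subsample,
which the test suite checks by Monte Carlo.

Uniformity is a deliberate simplification: real genotyping-by-sequencing
missingness is structured by depth, locus, and library.  Non-uniform
mechanisms are out of scope.

## Imputation

All three imputers leave observed cells untouched, fill missing cells on
the continuous code scale, and convert estimates to genotypes with one
binning rule: estimate ≤ 1.5 → code 1, ≤ 2.5 → code 2, otherwise code 3
(closed on the left genotype; out-of-range estimates fall into the open
tails).  The thresholds are fixed, not tuned per dataset.

**Probabilistic PCA (PP).**  The Tipping–Bishop latent-variable model with
isotropic noise, fitted by EM with missing cells treated as latent: each
sweep computes expected scores and their second moments, updates loadings
and the noise variance, and refreshes missing cells from the current
low-rank reconstruction; iteration stops when the relative change of the
observed-cell reconstruction error drops below `tol` (default 1e−5, at
most 1000 iterations; non-convergence returns a flagged result rather than
raising).  The final readout projects each line onto the converged
principal subspace by least squares — the noise variance is excluded at
readout — so on a complete matrix the reconstruction equals the
truncated-SVD reconstruction exactly, which is the oracle the tests use.

**NIPALS (NI).**  Components are extracted one at a time by alternating
regressions in which every sum runs over observed cells only; missing
cells are excluded, never filled.  Each component is deflated from the
observed residuals; the reconstruction is the observed-cell column means
plus the retained components (zero components therefore reduces to mean
imputation).  Default 2 components, `tol` 1e−5, 500 inner iterations per
component.

**Random forest (RF).**  Missing cells are initialized at observed column
means; for each marker with masked cells a random-forest regressor
(default 100 trees, ⌈(p−1)/3⌉ features per split — the regression-forest
convention) is fitted with that marker's observed codes as response and
all other current-filled markers as predictors, and the masked cells are
overwritten with its predictions.  One sweep by default; the sweep count
is configurable.  The forest itself is scikit-learn's regressor; the
sweep, the fill policy, and the binning are this package's.

The choice of 2 principal components follows the upstream PCA-imputation
package's default, since no value is stated for the original analyses; the
"row averages" initialization phrase there is orientation-ambiguous, and
per-marker (column) means are adopted here.

## Diversity statistics

Per locus, with N1/N2/N3 the counts of codes 1/2/3 among observed cells
and n their sum: p = (2N1 + N2)/2n, Ho = N2/n, He = 1 − p² − (1−p)²,
F = (He − Ho)/He where He > 0.  Summaries pool all lines.  F is
summarized as the mean of per-locus F over loci with He > 0 — not as
1 − mean(Ho)/mean(He) — because published per-crop values are consistent
only with the per-locus mean; the ratio-of-means variant is also computed
and exposed.  Monomorphic loci contribute He = 0 to the He mean but are
excluded from F.  Because p is estimated from the observed cells only, He
carries the classical small-sample downward bias E[Ĥe] ≈ (1 − 1/n)·He,
which is exactly the mechanism that makes He shrink as missingness grows;
the tests pin this against the closed form.

**AMOVA / Φst.**  One level (among/within groups) on squared pairwise
distances in the allele-count view: per co-observed locus the squared
difference is 0, 1, or 4, and each pair's sum is rescaled by
L / L_valid(i,j) so that pairs sharing few observed loci are not
artificially close (the unrescaled variant is available).  SS_total is the
mean over all pairs scaled by 1/N; SS_within sums per-group pair sums
scaled by 1/n_g; variance components follow the standard
weighted-group-size coefficient n0, and Φst = Va/(Va + Vw) is reported
unclipped — negative estimates are information, not errors.  A pair with
zero co-observed loci has no distance; the strict mode raises, and the
harness enables a fallback that substitutes the mean defined distance with
a warning.

## Trees and topology accuracy

Line-pair similarity is the simple matching coefficient over co-observed
loci; the distance is its complement.  Trees are Saitou–Nei
neighbor-joining with deterministic tie-breaking (lowest pair of active
node indices).  For four taxa the NJ join criterion is equivalent to the
four-point rule, and a tie between pairings returns a star topology rather
than an arbitrary resolution, so topology-accuracy counting never credits
a coin flip; a star matches only a star.  Topology accuracy is the percent
of runs whose quartet over the four group representatives matches the
quartet from the aligned original data.

## Assessment harness

Per missing level and run: mask the whole matrix → subsample (default 130
lines × 1000 markers, retrying until every group is represented) → extract
the aligned original cells → impute with each requested method → compute
Ho/He/F and Φst on original, unimputed-missing, and imputed subsets → draw
one representative line per group (the same four lines for every method)
and score quartet topology → score imputation accuracy on the masked cells
whose original genotype is known, overall and split by the original
genotype's class (major homozygote / heterozygote / minor homozygote, the
major homozygote decided by the original-data allele frequency, ties going
to code 1).  Relative bias is 100·(estimate − reference)/reference against
the same run's original-subset estimate.  RNG streams derive from
(master seed, level index, run), so sweeps are bit-reproducible; stage
failures are logged and excluded from aggregates with counts reported.

## Synthetic worlds

The generator emulates the three empirical minor-allele-frequency regimes
— uniform (Uniform(0.05, 0.5)), an excess of high MAF (Beta(3,2) rescaled
to (0.05, 0.5)), and a strong excess of MAF < 0.1 (Beta(0.6, 3) rescaled
to (0.01, 0.5)) — with group differentiation from the Balding–Nichols
model (group frequencies Beta-dispersed around the ancestral frequency
with θ equal to the Φst target) and within-group inbreeding from the
F-model: P(AA) = q² + f·q(1−q), P(Aa) = 2q(1−q)(1−f), P(aa) = (1−q)² +
f·q(1−q).  Defaults (4 groups × 100 lines, 2000 markers, θ = 0.03,
f = 0.98) describe a selfing crop panel with weak structure: observed
heterozygosity well below 10% and Φst in the low single-digit percents.
The Beta shape parameters of the MAF regimes are calibration knobs of this
package, documented here, not estimates of any published panel.

Markers are generated independently: there is no linkage disequilibrium
and no pedigree relatedness beyond group membership.  A green test on
synthetic data therefore establishes the estimators' and the harness's
correctness and the missingness mechanisms' consequences — it does not
certify imputation behaviour that depends on real-panel correlation
structure.  Concretely: on these synthetic panels the PCA imputers have
little signal beyond observed column means, and with f ≈ 1 a column mean
is 3 − 2q, so every locus with MAF < 0.25 bins to the major homozygote
and the imputed He falls *below* the unimputed He at moderate missingness
— whereas panels with LD and relatedness scatter estimates into the
heterozygote bin and push He up.  The Ho inflation from imputation
(roughly 30-fold here) and the m = 0.9 reversal are reproduced either way.

## Numerical choices and degenerate inputs

Markers with zero observed genotypes are excluded from imputation and
reported; their cells stay missing.  Lines with zero observed genotypes
are reported by NIPALS and left missing (PP falls back to column means).
Rank-deficient moment matrices in the PP EM use pseudo-inverses, so
constant matrices degrade to mean imputation instead of failing.
Monte-Carlo checks at reduced run counts use well-separated missing
levels for monotonicity claims, because the true He bias between adjacent
low levels (≈ He/n) is smaller than the Monte-Carlo error of a 25-run
mean.

## Known limitations

Uniform missingness only; one-level AMOVA only; quartet-level topology
accuracy only (full trees are built, but only the four representatives are
scored); no map- or haplotype-aware imputation; binning thresholds fixed;
execution-time comparisons are logged but are not a result surface.
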