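# Methods

## Scope and data model

`culteval` evaluates how well cultured colony arrays ("prints") recover the
microbial community of their inoculum, using finished sample × feature count
tables — it deliberately consumes the *output* of an amplicon pipeline
(features with taxonomy lineage strings), not reads. The universal container
is `TaxonProfile`: a non-negative features × samples matrix with a lineage
per feature and a units flag (`reads` = integers, `relative` = columns
summing to 1; conversion is always explicit). Lineages follow the fixed rank
order domain → phylum → class → order → family → genus → species/feature;
ranks absent from an input are filled with an `unclassified-at-<rank>`
sentinel so aggregation at any rank is total. No 16S rRNA gene copy-number
correction is applied anywhere — abundances are read proportions.

## Recovery scoring

For a taxonomic level and abundance cut-off *c*, the *eligible* set contains
the features reaching relative abundance ≥ *c* in **any** inoculum sample of
the group (the inclusive reading; a `mean`-profile mode is available). A
feature is *recovered* when it reaches the print-side detection threshold in
at least one print sample; that threshold defaults to the same *c*
(symmetric thresholds, the least surprising default) and may be set to 0,
meaning presence. The recovered fraction is undefined (`None`) when the
eligible set is empty — never silently 0. *Enriched* features are below the
detection threshold in every inoculum sample yet detected in at least one
print: taxa the culture step amplified past molecular detection.

Per-class abundance shifts between two sample groups use the two-sided
Mann–Whitney U test: exact enumeration of all C(n₁+n₂, n₁) assignments when
both groups have ≤ 8 samples (two-sided p = probability of a U at least as
far from n₁n₂/2 as observed; midrank 0.5 credit for ties), otherwise the
tie-corrected, continuity-corrected normal approximation
(`scipy.stats.mannwhitneyu`). The only multiplicity correction is
Bonferroni, p_adj = min(1, k·p) over the k classes tested. The two paths
agree to about 1% at n₁ = n₂ = 8; that residual is the normal
approximation's own error, which is why the cross-path test tolerance is
0.015 rather than the nominal 0.01.

The transcriptional-activity coverage of an isolate collection is, per
biofilm sample, the sum of genus-level relative activity over genera present
in the collection; the headline statistic is the mean of those per-sample
sums (`mean_profile` mode — coverage of the averaged profile — is provided
as the alternative reading). The input/output cell-ratio bound scales a
reference colony's cell yield by the cube of the colony-radius ratio
(sphere-volume scaling) and divides the maximal droplet input by the scaled
yield.

## Diversity suite

All indices are computed from one sample's positive integer counts
(features with zero count are ignored): Shannon H′ = −Σ pᵢ ln pᵢ (natural
log), Margalef d = (S−1)/ln N, Pielou J′ = H′/ln S, Brillouin
H = (ln N! − Σ ln nᵢ!)/N via log-gamma, Simpson λ = Σpᵢ² and the unbiased
λ′ = Σnᵢ(nᵢ−1)/(N(N−1)) (both 1−λ and 1−λ′ are exposed because both
conventions circulate; callers must name one), Hill numbers N1 = exp(H′),
N2 = 1/λ, N∞ = 1/p_max and the ratios N10 = N1/S, N10′ = (N1−1)/(S−1),
N21 = N2/N1, N21′ = (N2−1)/(N1−1). Fisher's α solves α·ln(1+N/α) = S by
bracketed root finding on [10⁻⁸, 10⁸] with tolerance 10⁻¹⁰ (the defining
function is monotone; `brentq` is used — bracketed and derivative-free).
Hurlbert's ES(m) = Σᵢ[1 − C(N−nᵢ, m)/C(N, m)] is evaluated with log-gamma to
avoid overflow; Good's coverage is 1 − F₁/N with F₁ the singleton count.
Undefined quantities (J′, N10′, N21′ at S = 1; λ′ at N = 1; Fisher's α at
S = N) are reported as `None`, and an all-zero vector is an error.

Depth rarefaction subsamples each column without replacement (multivariate
hypergeometric draw), so output totals equal the depth exactly; samples
below the depth are dropped with a warning rather than erroring, matching
how a low-depth sample is normally excluded from a study. The default depth
offered by the CLI is 6,070 reads. Accumulation curves average cumulative
unique-feature counts over uniformly random sample orderings (default
n_perm = 999; all orderings are enumerated exactly when n! ≤ n_perm).

## Beta diversity

The fixed order is standardize → transform → Bray–Curtis: each feature is
divided by its maximum across samples (all-zero features left at zero),
values are fourth-root transformed, and similarities are
S(x,y) = 100·(1 − Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)) on the 0–100 scale. A pair of all-zero
samples has undefined similarity (NaN sentinel). UPGMA (unweighted
group-average agglomeration) runs on the 100−S dissimilarities via
`scipy.cluster.hierarchy.linkage(method="average")`; merge heights are
reported back as similarities, which are non-increasing along the
agglomeration, and flat clusters are cut at a similarity threshold
(default 60). An export to Newick is provided.

Non-metric MDS is implemented directly (no external MDS dependency): each of
n_restarts (default 20) random starts alternates Kruskal's primary monotone
regression — pool-adjacent-violators (`scipy.optimize.isotonic_regression`)
of configuration distances against the dissimilarity ranking, with tied
dissimilarities left free for the fit — with a Guttman (SMACOF) majorization
update. The reported badness-of-fit is Kruskal stress-1,
√(Σ(d−d̂)²/Σd²). Because the stress-1 denominator depends on the
configuration, the majorization step does not formally guarantee stress-1
descent; the implementation therefore records stress-1 each iteration and
terminates a restart the moment it fails to improve (keeping the best
configuration), making the recorded trace non-increasing by construction.
The best configuration over restarts is returned, centred; everything is
deterministic under the seed. The vector overlay reports the Pearson r of
each variable against each ordination axis and the vector length √(Σr²);
constant variables get zero-length vectors with a warning.

## Media ranking

Per-medium recovered sets come from one recovery-scoring pass restricted to
each medium's samples; their universe is the eligible set. The greedy
complementarity ranking starts from a caller-chosen base medium and at each
step adds the medium contributing the most not-yet-covered features, ties
broken lexicographically by medium label (a documented, stable choice —
required for determinism, not a scientific claim). Greedy is step-wise
optimal only; an exhaustive panel search (≤ 12 media) is provided to
quantify the greedy gap. UpSet counts assign each covered feature to exactly
one combination — the set of media that recovered it — so exclusive counts
partition the union; the combination enumeration is guarded at 20 media.

## FT-IR classification

Preprocessing is the two-step pipeline stated in the module docstring:
endpoint baseline correction (slope (aₙ−a₁)/(wₙ−w₁), offset a₁ − slope·w₁,
a′ₖ = aₖ − (wₖ·slope + offset), forcing a′₁ = a′ₙ = 0) followed by vector
normalization (a″ = a′ − mean a′, a‴ = a″/‖a″‖₂, so Σa‴² = 1). The
composition is invariant to adding any linear ramp and to positive scaling;
stages are tracked on the `Spectrum` object and enforced in order.
Classification features are the fingerprint (900–1800 cm⁻¹) and
CH-stretching (2800–3000 cm⁻¹) regions, each preprocessed independently
(the endpoint line and the vector norm are region-local) and concatenated.

PCA is covariance-based (no correlation scaling), computed by SVD of the
centred spectra matrix. Fisher LDA solves the generalized symmetric
eigenproblem S_B v = λ S_W v; with many more wavenumber points than spectra
S_W is singular, so the default regularization first projects onto the
principal components explaining ≥ 99% of variance, additionally capped at
n − c components so S_W stays full-rank (a ridge on the S_W diagonal is the
alternative; `none` errors on singularity). Prediction assigns the nearest
class mean in discriminant space (uniform priors — the intended use has
balanced classes). Cross-validation is class-stratified k-fold (default
k = 5; leave-one-out available), seeded; the report pools out-of-fold
predictions into a confusion matrix and an accuracy with a Wilson score 95%
interval (chosen for its behaviour near accuracy 1).

## Synthetic-data generator

The generator emulates the structure — not the biology — of a culturomics
study on a host-associated biofilm:

- **Inoculum**: abundances are log-normal draws (default σ = 1.5, a
  conventional dispersion for host-associated communities), ranked and
  normalized; lineages come from recursive random branching over the rank
  hierarchy (default branching 4·3·3·3·3 above the terminal level).
- **Media effects** factorize into a hard 0/1 survival indicator
  (culturability; default survival probability 0.5 per feature × medium) and
  a soft log-normal growth bias (default σ = 0.75). Two knobs reproduce the
  two phenomena of interest: taxa dropping out entirely on a medium, and
  abundance shifts among survivors.
- **Prints** renormalize abundance × survival × bias and draw reads
  multinomially; per-sample depths default to uniform on [6,640, 26,728],
  the realistic per-sample read range for full-length 16S profiling.
  Independent survival across media and features means phylogenetically
  correlated medium effects are *not* modelled.
- **Activity tables** are Dirichlet draws (columns sum to 1).
- **Spectra** are class-specific Gaussian peak mixtures (default 4
  fingerprint peaks + 1 CH-stretch peak per class, centred in class-private
  slots so templates never coincide) times a random intensity scale, plus a
  random linear baseline and additive Gaussian noise, on a 2 cm⁻¹ grid
  (≈ the 4 cm⁻¹ optical-resolution regime) spanning 525–4000 cm⁻¹.

What passing tests on this generator show: the scoring, ranking, diversity
and classification machinery is correct with respect to known ground truth
under multinomial sampling noise. What they do not show: robustness to
compositional artefacts of real amplicon data (copy-number variation,
chimeras, contamination, taxonomy curation errors) or to spectra with
instrument drift, water-vapour bands or ATR distortions — none of which the
generator emulates.

## Problem sizes and determinism

Every stochastic operation takes an explicit integer seed
(`numpy.random.default_rng`); re-running an unchanged configuration
reproduces byte-identical outputs (checksummed in the pipeline manifest).
The packaged verification uses desk-scale problems chosen to exercise the
statistics well past sampling noise: 200-feature communities on 16 media at
depth 10,000 over 200 seeds for parameter recovery, 1,000 random spectra for
the preprocessing identities, 200 random communities for the diversity
identities, and 5-class × 8-replicate spectra sets for classification.

## Known limitations

- Recovery matching is by exact feature/lineage identity; reconciling
  renamed taxa across nomenclatures is the caller's responsibility.
- nMDS is a local optimizer; with few restarts, bad local minima are
  possible (the default 20 restarts makes this rare at typical sample
  counts).
- The exact Mann–Whitney path enumerates C(n₁+n₂, n₁) assignments and is
  only used when both groups have ≤ 8 samples.
- No phylogenetic diversity, PERMANOVA/ANOSIM/SIMPER, or second-derivative
  spectral preprocessing; plotting is out of scope (outputs are tables).
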