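# Methods

## Problem setting

A buried body is colonised by soil microbes; the exogenous ("necrobiome")
fraction of an ancient sample's shotgun data therefore reflects the burial
site's soil community. Given a reference panel of samples with known
origin from two candidate locations, the task is to assign a query sample
to one of them, with a calibrated probability. The pipeline is
alignment-free: it never classifies reads against a reference database for
the core comparison, so the (large) unclassifiable fraction of soil
metagenomes still contributes signal.

## Read QC

Inputs are assumed host-depleted. The filter cascade is:

1. length window 30–80 bp inclusive (long reads are likely modern
   contamination; very short reads carry too little information),
2. 4 bp trimmed from each read end, where post-mortem deamination damage
   concentrates,
3. minimum length re-checked on the trimmed read (so a 38 bp read
   survives at exactly 30 bp; a 36 bp read does not) — the stage order
   and the re-check are an interpretation, since trimming and the length
   window could be composed either way,
4. linguistic complexity = (# distinct k-mers)/min(L−k+1, 4^k) with
   k = 4, threshold 0.7; windows containing N are excluded from the
   numerator, sequences shorter than k score 0. k = 4 saturates the
   256-state k-mer space appropriately for 30–80 bp reads.

Quality strings are carried through but never used. Subsampling is
uniform without replacement, seeded, order-preserving.

## Sketching and similarity

Canonical k-mers (lexicographic min of window and reverse complement;
windows with N skipped) are encoded in 2 bits/base and hashed with a
splitmix64 finalizer XORed with a seeded constant (default hash seed 42).
A sketch retains every hash below 2⁶⁴/`scaled` together with its count.
Defaults: k = 21 (supported sweep 11/15/21/25/31), scaled = 1000 for real
data. Correctness is anchored at scaled = 1, where the sketch is an exact
canonical k-mer count table and the angular similarity must equal a
brute-force string-counting oracle to 1e−12 (tested).

Angular similarity maps the cosine between the two retained count vectors
into [0, 1] via A = 1 − 2·arccos(c)/π. The cosine is clamped to [0, 1]
before arccos: negative values are impossible with non-negative counts
and only arise from float error. Two empty sketches compare as 0 with a
warning. Abundance weighting makes A invariant to uniform count scaling
(library size), tested as a property.

## Ordination

`pca_rows` (default) treats each row of the similarity matrix as that
sample's feature vector, column-centres, and decomposes by SVD — i.e.
a PCA of the similarity matrix itself, matching the practice of feeding
such matrices directly to a PCA routine. `torgerson` implements classical
MDS (double-centred squared dissimilarities, eigendecomposition, scaling
by √eigenvalue) for taxa-table distances and as a cross-check. Axes with
variance below 1e−12 of the leading axis are dropped; each axis's sign is
fixed so its largest-magnitude loading is positive, making downstream
fits reproducible. Explained-variance shares come from the eigenvalue
spectrum (positive part, for Torgerson).

## Penalised logistic classification

The classifier minimises mean binomial deviance plus λ‖β‖₁ with an
unpenalised intercept on standardized coordinates (glmnet
parameterisation). All positive-variance ordination axes are supplied;
the L1 penalty performs axis selection. Implementation is an IRLS +
cyclic coordinate-descent path solver with warm starts along a 100-point
log-spaced grid from the analytic λ_max down to λ_max·1e−4, an active-set
strategy, IRLS weights floored at 1e−6 and the working linear predictor
capped at ±30. Fold fits during cross-validation converge to 1e−5
(penalty ranking only); the returned model is polished to 1e−9. λ = 0
reduces to the unpenalised MLE and is verified against an independent
Newton oracle to ≤1e−6; a fixed positive λ is verified against an
independent saga L1 solver; λ ≥ λ_max yields exactly zero coefficients
and intercept equal to the prior log-odds.

λ is selected by stratified K-fold cross-validated deviance
(K = min(10, smallest class size), shuffled with the run seed), taking
the deviance minimiser (the lambda.min convention, not 1-SE); ties
resolve to the sparser model. A selected model with no nonzero
coefficient is valid and flagged `prior_only`.

On perfectly separable data at very small λ the MLE diverges; iteration
caps leave large finite coefficients, which only saturate the predicted
probabilities.

## Evaluation

* **Jackknife**: the ordination is computed once on all n samples, then
  the logistic model is refit n times with one sample held out and used
  for prediction. The held-out sample thus contributes to the axes — a
  small leakage accepted deliberately because it matches how such
  pipelines are run in practice; a stricter mode (axes from training
  samples only, held-out sample projected; `pca_rows` only) is available
  behind `re_embed_per_fold=True`.
* Predicted label is the class with probability > 0.5; an exact 0.5 tie
  goes to the reference (alphabetically first) class. p_true is the
  probability assigned to the true class.
* **Accuracy curve**: share of samples that are correct *and* have
  p_true ≥ t, for t ∈ [0.5, 1] — a confidence-aware accuracy.
* **Permutation control**: labels are reassigned to two mock groups of
  ⌊n/2⌋/⌈n/2⌉ uniformly at random (seeded), the jackknife is repeated,
  and the number of axes selected by a full-data mock fit is reported.
* **Target classification**: a query sample is embedded jointly with the
  references, the model is trained on reference coordinates only, and
  each target is processed independently.
* **Gates**: samples below 10⁶ post-QC reads (whole-metagenome runs) or
  below 10⁵ marker-genus reads (genus-restricted runs) can be excluded;
  both boundaries are inclusive on the "keep" side.

## Taxa-table analyses

Host taxon (ID 9606) and taxa with < 10 reads summed over samples are
removed. Genome-size normalisation divides counts by each taxon's average
genome size and renormalises columns (longer genomes shed more reads);
taxa without a size entry are dropped first. Rarefaction draws exactly
`depth` reads per sample without replacement (multivariate
hypergeometric, seeded), excluding shallower samples with a warning.
Because rarefaction needs integers, size normalisation and rarefaction
are separate branches from the filtered counts: normalised abundances
feed ordination, rarefied counts feed Jaccard distances. Jaccard is
presence/absence by default (the textbook metric); a quantitative mode
d = 2b/(1+b) on Bray–Curtis b matches the convention of common
community-ecology software, and which of the two a given upstream
analysis used is often unstated — both are provided.

## Synthetic necrobiome generator

The generator produces data with the statistical structure the classifier
assumes, not sequence-realistic reads:

* **World**: `n_taxa` = 150 random genomes of 5 kb (a deliberately
  scaled-down community; real soil has thousands of taxa and Mb genomes,
  scaled down to keep k-mer space and runtime desk-sized), base
  abundances ~ Dirichlet(α = 1), per-location profiles obtained by
  tilting the base profile with exp(δ·z), z ~ N(0,1) i.i.d. per
  taxon×location, renormalised. δ (`divergence`, default 1.0) is the
  single knob for how distinguishable locations are; δ = 0 makes
  locations exchangeable. KL divergence between location profiles grows
  monotonically in δ (tested).
* **Covariates**: 15% of taxa form a marker genus (the analogue of a
  ubiquitous soil genus used for batch-robust analysis), 10% an oral
  set. An extraction-protocol batch effect multiplies a 30% taxon subset
  by exp(σ·z) (σ = `protocol_bias_strength`); the subset is drawn from
  non-marker taxa only, so restricting analysis to the marker genus
  removes the batch effect by construction — the mechanism the
  batch-effect audit tests. Tooth samples draw a fraction `oral_mix`
  (default 0.2) of reads from the oral subset.
* **Reads**: uniform lengths on [30, 80] (so QC is pass-through by
  default), uniform start positions, optional reverse-complement
  emission (on by default — canonical sketching must not depend on
  strand), 5′ C→T damage with probability δ_dam·r^j at offset j
  (geometric decay, default r = 0.5), uniform base error. Every sample
  records a truth manifest (read → source taxon).
* **Seeding**: one master seed; each sample's stream derives from
  (master seed, sample index), so any sample regenerates in isolation.

What the simulator does **not** model: real genome content or homology
between taxa, within-location between-sample community variability
beyond multinomial sampling, indel damage, fragment-size chemistry, or
museum-storage contamination. Passing tests therefore demonstrate that
the statistical machinery recovers planted structure under controlled
noise — not field performance on real necrobiomes.

## Problem sizes used in tests and the acceptance script

End-to-end checks use 20+20 samples of 5×10⁴ reads at k = 21,
scaled = 200 (three fixed seeds); the depth comparison pairs 10³ against
5×10⁴ reads on 8+8 samples; the batch audit uses 10+10 samples of 2×10⁴
reads with σ = 1.0. These sizes were chosen so the full suite runs on a
single CPU in minutes while keeping the statistical tests adequately
powered.

## Known limitations

* Only binary (two-location) classification is implemented.
* Leave-one-out evaluation of an intercept-only (prior-only) model is
  systematically anti-conservative under the null: removing a sample
  makes its own class the training minority, so the prediction is wrong
  for every sample and mock-label accuracy can sit near 0 rather than
  0.5. Conversely, when the mock-label cross-validation picks up a few
  weakly overfit axes, the mock model can be *less* sparse than a
  true-label model that needs a single axis on cleanly separated data.
  Both behaviours are reproduced by an independent R glmnet
  cross-validation on the same matrices; they are properties of
  balanced leave-one-out under the null, not solver artifacts.
* The coordinate-descent solver caps iterations on separable data
  (coefficients are large but finite).
* Sketch hashes are not bit-compatible with other sketching tools;
  sketches are comparable only within matching parameters.
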