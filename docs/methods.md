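# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions a reimplementation would need.

## Dissimilarity matrices

A representational dissimilarity matrix (RDM) holds, for every stimulus pair,
`d(i,j) = 1 − r(xᵢ, xⱼ)` where `r` is the Pearson correlation between the two
stimuli's feature rows (range [0, 2]), or alternatively the Euclidean distance
between rows scaled to unit L2 norm ("normalized Euclidean"). The
normalization choice removes overall activation magnitude, which is the
evident intent of normalizing; other readings (per-feature z-scoring) exist
but change little in practice because the downstream statistic is itself a
correlation.

The diagonal is stored as NaN and treated as *undefined*, never as zero.
This matters for resampling: when a stimulus is drawn twice in a bootstrap
replicate, every cell pairing it with itself is a disguised diagonal cell and
would contribute a spurious perfect agreement; such cells are dropped from
the correlated upper triangle exactly as the diagonal is.

RDM-to-RDM agreement is the Pearson correlation of the strictly-upper
triangles. Rank-based variants are deliberately out of scope.

MDS uses the classical Torgerson double-centering solution rather than
iterative stress minimization: it is deterministic, needs no seed, and is
adequate for visualization. Axis signs are fixed by making the first nonzero
loading of each axis positive.

## Consistency of naming responses

For mostly-binary accuracy data, correlation is a poor agreement measure
(there is almost no variance when most responses are correct), so agreement
between accuracy vectors is `1 − Σ(xᵢ−yᵢ)²/n` — one minus a normalized
squared Euclidean distance, which on binary vectors equals one minus the
Matching distance. The between-human ceiling band for naming uses this same
statistic in place of Pearson correlation: the upper bound averages each
participant's consistency with the panel mean including themselves, the
lower bound with the leave-one-out mean.

## Bootstrap inference

All intervals are percentile bootstrap intervals: 2.5th and 97.5th
percentiles of 1000 replicate values (`n_iter` configurable; every function
takes an explicit seed and stores the full replicate distribution so results
are exactly reproducible).

* **Accuracy CIs** resample the item-level 0/1 vector with replacement.
* **RDM-correlation CIs** resample stimulus indices with replacement, index
  both matrices with the same multiset, drop undefined cells (diagonal and
  duplicate pairs), and correlate the surviving upper-triangle entries.
  Degenerate replicates (fewer than three valid cells or zero variance) are
  recorded as NaN and excluded from the percentiles.
* **Stratified resampling** draws each stimulus only from its own stratum
  (its shape class or semantic category), so every replicate preserves the
  design's class composition. Strata of size one are rejected — resampling
  within them is vacuous.
* **Paired group test.** To compare two groups of models, each model's
  replicate correlations are computed on *shared* stimulus draws; per
  replicate the correlations are averaged within group and differenced. The
  one-tailed p-value is the fraction of difference replicates below zero,
  floored at `1/n_iter` (an empty tail is reported as `p < 1/n_iter`, not
  zero); two-tailed doubles it, capped at 1. Identical groups (all
  differences exactly zero) return p = 1 by convention. Sharing draws across
  *all* models in both groups is an implementation choice; the pairing
  requirement only dictates sharing within a comparison, but a single draw
  sequence is the simplest construction that satisfies it.

## Noise ceilings

Each participant's upper-triangle vector is z-scored (per participant, over
cells — the natural axis when participants differ in scale use). The upper
bound is the mean over participants of the correlation with the grand mean
including that participant; the lower bound uses the leave-one-out mean. The
upper bound is optimistic (the target contains the participant), the lower
bound pessimistic, so the achievable ceiling for a true model lies between
them; identical participants collapse both to exactly 1.

## Synthetic generators: what they emulate

The generators exist so that every downstream stage can be tested against
planted ground truth. They are deliberately minimal models of the real data:

* **Shape sets.** One binary silhouette per (perceived class, envelope) cell.
  Contour style encodes the perceived class — radial star perturbation
  (spiky), low-frequency radial harmonics (smoothie), rectilinear blob with
  axis-aligned bumps (cubie) — and the foreground bounding box encodes the
  envelope as a width/height aspect ratio, geometrically spaced around 1
  (0.5 / 1.0 / 2.0 at three levels), with the long axis at 80% of the canvas.
  Rendering is binary with anti-aliasing off so pixel-level oracles are
  exact; the grayscale variant adds interior shading kept strictly below the
  0.5 silhouette threshold, the color variant a per-class tint. What this
  does *not* emulate: 3-D geometry, texture, lighting, or the within-class
  exemplar variability of real stimulus sets — passing tests show the
  pipeline recovers planted structure, not that any model explains real
  judgments.
* **Observers.** Participant RDMs are the true RDM plus i.i.d. Gaussian noise
  on the upper triangle, mirrored (preserving symmetry) and clipped at zero.
  Clipping rather than resampling introduces a small positive bias,
  negligible at the default noise (sd 0.3 on dissimilarities of order 1).
  The Gaussian-on-dissimilarities choice is a stand-in: real
  similarity-arrangement noise is not specified by any model we commit to.
  The default panel of 8 participants matches a typical arrangement-task
  sample.
* **Layer stacks.** For a mixing weight `w`, the target similarity matrix
  `1 − [(1−w)·D_physical + w·D_perceived]` is projected to the nearest
  correlation matrix and features are drawn with exactly that sample row
  correlation (rows are exactly whitened before coloring), so at `noise_sd=0`
  a weight-1 layer reproduces the perceived RDM to machine precision.
  Gaussian feature noise then blurs the embedding. The default plan rises
  monotonically 0 → 1 over six layers with 200 features each and feature
  noise 0.1 — a clean caricature of the physical-to-perceived crossover, not
  of any particular architecture.
* **Triplets.** Each base vector gets a non-accidental variant at Euclidean
  distance `d_nap = 0.8` and a metric variant at `d_metric = 1.0`
  (`d_nap ≤ d_metric`: the conservative ordering in which a linear metric
  ranks the NAP variant *closer*). The NAP displacement is confined to the
  leading `⌈n_features/10⌉` "diagnostic" coordinates; multiplying those
  coordinates by the perceptual gain (default 5) scales `d(base, NAP)` by the
  gain while leaving `d(base, metric)` untouched, reversing the ordering for
  every triplet. Any fixed subspace works; the leading block keeps tests
  deterministic. Default 22 triplets, 100 features.
* **Naming panels.** Independent Bernoulli responses per (participant, item)
  with planted item difficulties; the default synthetic panel draws
  difficulties from Beta(4, 1.5) (mostly nameable objects) with a model
  tracking the same difficulties at a 0.15 handicap.

## Naming slope test

Whether model correctness tracks per-item human accuracy is tested by
logistic regression of the model's 0/1 vector on mean human accuracy, with a
Wald z-test on the slope. Under complete separation the Wald standard error
diverges; the fallback is a likelihood-ratio test of a lightly
L2-regularized fit (ridge penalty 0.01 on the slope only) against the
intercept-only model, reported with the slope's sign. A constant model
vector is a degenerate case reported as such (slope and p undefined), never
an exception.

## Triplet evaluation

A triplet scores 1 only when the representation places the NAP variant
*strictly* farther from the base than the metric variant; ties score 0 and
are tallied separately rather than split, so degenerate representations
cannot inflate accuracy. Chance is 50% by symmetry of the two comparisons.
Under the normalized-Euclidean metric the outcome is invariant to any common
orthogonal transform of feature space.

## Orthogonal shape × category designs

In a balanced crossed design (six categories × nine shapes, every cell
occupied once), the block-structured shape and category reference RDMs are
*mutually exclusive* on the upper triangle — a same-shape pair is never a
same-category pair — which produces a small negative correlation
(≈ −0.14 at 6 × 9) rather than exactly zero. This is the unavoidable floor
of "as orthogonal as possible" for crossed designs and is what the
orthogonality checks assert against.

## Problem sizes and numerical conventions

Monte-Carlo calibrations in the test suite use 20–200 replications with
9–12-stimulus RDMs and 50–200 bootstrap iterations per replication; the
chance-level evaluation uses 10,000 triplets of dimension 100. These sizes
give standard errors comfortably inside the asserted bands (binomial SE
≈ 0.5% at 10,000 triplets). Grids and images are row-major, origin top-left;
grayscale conversion uses Rec.601 weights; the Gabor jet uses octave-spaced
center frequencies descending from 0.25 cycles/px with ~1-octave bandwidth,
DC-corrected complex kernels, FFT convolution with edge-replication padding
(so constant images give exactly zero magnitudes at every grid node, border
included), and grid nodes at cell centers excluding the border. The Gabor
bank's exact frequencies and node placement are pinned conventions, not
claims about any particular published implementation.

## Known limitations

* Deep-network activations are consumed as data, never computed: all
  conclusions about "layers" in the synthetic pipeline concern planted
  structure.
* The observer noise model is i.i.d. Gaussian on cells; real arrangement
  data has correlated, scale-dependent noise.
* No multiple-comparison correction is applied anywhere; the bootstrap
  p-value floor of `1/n_iter` limits how small a reportable p can be.
* The silhouette rule keeps only the largest connected component; stray
  sub-threshold pixels in secondary components are discarded by design.
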