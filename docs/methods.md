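# Methods

## Problem setting

Multilabel protein subcellular localization images carry 1–5 organelle
labels each, over a heavily right-skewed class distribution. Oversampling
a rare class replicates whole label sets, so when rare and common labels
co-occur frequently, oversampling amplifies the common labels too and the
synthetic labels become noisy. The package therefore (a) measures whether
the dataset is in the low-concurrence regime where oversampling is safe,
(b) constructs synthetic samples whose label sets are provably defensible,
and (c) schedules them into minibatches so rare classes are seen more
often without displacing the original data.

## Imbalance metrics

**IRL.** For label *l*, `IRL(l) = max_{l'} n(l') / n(l)` where `n(·)` is
the positive-instance count. The most frequent label scores exactly 1. A
zero-count label makes the ratio undefined and is rejected with an error
naming the label.

**Class partition.** With `m = mean(IRL)` and `d = median(IRL)` over all
labels: minority iff `IRL > m`; medium iff `d < IRL < m`; majority
otherwise. Both inequalities are strict, so a label tied with the mean or
the median falls to majority; when all IRL values are equal the whole
dataset is majority. The median of an even number of values is the
midpoint of the two central order statistics. The strictness convention
matters only on exact ties, which the count-exact generator can produce
deliberately in tests.

**SCUMBLE.** Per instance *i* with active-label ratios `IRL_1..IRL_k`:

    SCUMBLE_i = 1 − (∏ IRL_j)^(1/k) / mean(IRL_j)

the geometric over the arithmetic mean, subtracted from 1 — zero when the
instance's labels are equally (im)balanced, approaching 1 when an extreme
majority and minority label coexist. The dataset value is the mean over
instances, and a value ≤ 0.1 flags the dataset as benefiting from
resampling. Two deliberate choices:

* the geometric mean runs over the instance's **active labels only**
  (exponent 1/k). Taking the product over all |L| labels with absent
  labels contributing 0 would force every instance that lacks some label
  to score exactly 1, destroying the metric's meaning; the active-labels
  reading reproduces the standard behaviour that single-label instances
  score 0.
* instances with empty label sets have no defined score; they are
  excluded from the mean with a logged warning, and an all-empty dataset
  is an error.

The vectorized implementation (masked row product raised to 1/k) is tested
against a literal per-instance loop to 1e-12 on random matrices.

**Macro F1.** Per label, `F1 = 2TP / (2TP + FP + FN)`, macro = unweighted
mean. A label with `2TP + FP + FN = 0` contributes 0 — conservative, and
it keeps the mean defined. Thresholding predicted probabilities is the
caller's job (a `binarize` helper defaults to 0.5). The implementation is
a direct count formula cross-checked against scikit-learn in the tests.

## Augmentation operators

All operators map 4-channel (red, green, blue, yellow) images with values
in [0, 1] to images of the same shape and range.

**Geometric and colour transforms (GCT).** Horizontal flip, vertical
flip, rotation by one of 90°/180°/270°, brightness scaling by a factor
uniform in [0.5, 1.5] (clipped to [0, 1]), and a random crop retaining a
uniform fraction in [0.8, 1.0] of each dimension, re-placed at a random
offset on a zero canvas of the original size. Each transform is
independently included with probability 1/2; a draw selecting none is
redrawn, so GCT never returns the identity. For non-square frames the
90°/270° rotations would change the frame and are replaced by 180°. The
crop geometry and inclusion probabilities are this package's choices;
only the transform inventory and the brightness range are fixed by the
method.

**Matrix mixup.** `I = λ ⊙ I_a + (1 − λ) ⊙ I_b` with λ a height × width
matrix of iid Uniform(0.35, 0.65) draws — one matrix shared across all
four channels, since the interpolation is defined on images rather than
per channel. The bounds keep the synthetic image away from either parent;
being a convex combination, the output needs no clipping. The label set is
the parents' intersection, and an empty intersection is an error (the
caller pairs images from the same minority class, which guarantees a
shared label). A degenerate class with a single sample self-pairs with a
logged warning; the subsequent colour rotation still diversifies it.

**Non-linear mixup.** The mixup image's per-pixel (red, green, yellow)
triple — blue is replaced by yellow because the targeted minority classes
live in the outer nuclear region — is treated as a row vector and
right-multiplied by

    Rot_G(θ) = [[cos θ, 0, sin θ], [0, 1, 0], [−sin θ, 0, cos θ]]
    Rot_R(θ) = [[1, 0, 0], [0, cos θ, −sin θ], [0, sin θ, cos θ]]

Rotation about G moves each pixel on a circle centred on the green axis:
the green (protein-of-interest) channel is returned bit-identical while
the red/yellow background changes; rotation about R preserves the red
(microtubule) channel. The blue channel participates in the mixup
interpolation but is untouched by the rotation. θ is drawn alternately
from [60°, 110°] and [120°, 300°] — a stateful sampler with a seeded coin
choosing the starting set, then strict alternation — so successive
synthetic images differ visibly from their mixup intermediates and from
each other. Both axes use the same two θ sets. Rotated values can leave
[0, 1] (cos θ < 0 over much of the second set); they are clipped, which
cannot disturb the preserved axis channel. The pre-clip rotation exactly
preserves the per-pixel Euclidean norm of the colour triple, and the
implementation exposes `clip=False` so tests can verify that invariant
directly.

Angles are degrees at every interface; radians are internal.

## Sampler

Defaults follow the published configuration: batch size 32, 17 originals,
supplement capacity 15, `n = 1`, minority fraction 0.65.

* **Schedule.** Exactly `round(0.65 · K)` of the K iterations per epoch
  are minority-kind (round half up, so the allocation is deterministic and
  exactly testable), the rest medium-kind, in seed-shuffled order. The
  65/35 split is realized as a deterministic allocation rather than
  per-iteration Bernoulli draws, which would only hit the fractions in
  expectation.
* **Minority supplement.** Per minority class, `n` triples: a GCT of one
  drawn original, one NL mixup (R) and one NL mixup (G), each mixup from a
  random same-class pair. With 5 minority classes and n = 1 this is
  exactly 15 entries. If demand exceeds capacity, entries are truncated
  class-round-robin with a warning; a shortfall (as with the 4-minority
  test preset) is filled with extra GCT variants of minority originals so
  the minibatch size stays fixed. A per-class override map allows
  different n per class.
* **Medium supplement.** `capacity // 3` classes contribute three GCT
  variants of one drawn original each; contributing classes rotate
  round-robin across medium iterations so per-class usage over an epoch
  differs by at most one contribution. Mixup operators never appear here:
  medium classes are populous with diverse label sets, so intersected
  label sets would perturb other classes' labels.
* **Originals.** Drawn label-agnostically, without replacement within an
  epoch (reshuffled with an epoch-derived seed; recycled with a fresh
  shuffle if an epoch needs more draws than the dataset holds).

The sampler yields pixel-free manifests (sample ids, operator, parents,
θ); `materialize_record` turns a manifest entry into pixels, and a
recorded θ takes precedence over a live angle sampler so re-materializing
reproduces the original image.

## Synthetic data generator

Emulates the Kaggle layout: four 8-bit grayscale PNGs per sample plus an
`Id,Target` CSV. Label sets are built from an explicit pairing table
(label set → instance count), every remaining label occurrence becoming a
single-label instance, so realized per-label counts equal the
specification *exactly* — IRL and SCUMBLE of generated datasets are
closed-form. Infeasible tables (pair usage exceeding a class count, label
sets larger than 5) are rejected with an explanatory error.

Pixels: each assigned label deposits an amplitude-0.7 Gaussian blob at a
deterministic label-specific ring position (±2 px jitter) in its assigned
channel (green by default), over an amplitude-0.8 central blue nucleus
blob, smoothed-noise red/yellow reference textures (amplitudes 0.30/0.25),
and iid Gaussian noise of sd 0.02. The blob clears the noise floor by far
more than 5 standard deviations, so augmentation tests can track the
signal. Default frames are 64×64 — the structures of interest fit
comfortably and the full suite stays fast; size is configurable.

The `tiny` preset (12 labels, counts 90…3 in a power-law-like decay, 297
instances) mimics a right-skewed PSL class distribution: it yields 4
minority and 2 medium classes and dataset SCUMBLE ≈ 0.007. What the
generator does **not** emulate: organelle morphology, cell-line
heterogeneity, spatial label correlations, or realistic channel
cross-talk. Passing tests therefore demonstrate the pipeline's metric,
operator and scheduling contracts — not classification gains on real
imagery, which require GPU-scale training on the external dataset.

## Numerical and interface choices

* Per-instance SCUMBLE values are clipped at 0 to absorb ~1e-16 negative
  rounding residue from the geometric/arithmetic mean ratio.
* PNG writing is always 8-bit (`round(v · 255)`); 16-bit PNGs are accepted
  on read and rescaled by 1/65535; grayscale-with-alpha drops alpha with a
  warning. Write-then-read round-trips within 1/255 per pixel.
* One user seed derives per-purpose sub-seeds via a CRC-tagged
  `SeedSequence`, so partial re-runs (e.g. only the schedule, or only one
  epoch's supplements) reproduce their streams independently.
* The kaggle CSV dialect stores integer column indices; non-numeric label
  names survive in memory but not through that dialect (use the wide
  format to keep names).

## Known limitations

* The medium-class round-robin assumes at least one medium class; datasets
  whose IRL distribution yields an empty medium (or minority) set are
  rejected by the sampler rather than silently degenerating.
* With fewer medium classes than `capacity // 3`, a class contributes more
  than once per medium iteration; the fairness guarantee is per-epoch, not
  per-iteration.
* Brightness scaling and clipping are applied jointly to all four
  channels; per-channel colour jitter is not implemented.
* `compose_minibatch` validates sizes but not label coverage of the
  originals; originals are uniform draws by design.
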