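# Methods

This note documents the models, conventions and numerical choices behind
`classimage`, and what its synthetic validation does and does not show.

## The noise model

Noise images are weighted sums of a fixed dictionary of hard-windowed
sinusoid patches. At scale *s* ∈ {2, 4, 8, 16, 32} cycles/image the image
is split into a g×g grid (g ∈ {1, 2, 4, 8, 16}) and each patch carries one
sinusoid per (orientation, phase) pair, with orientations
{0°, 30°, …, 150°} and phases {0, π/2}. Each patch sinusoid spans
`cycles_per_patch = 2` cycles, so grid dimension g produces 2g
cycles/image — exactly the scale label. The parameter count is
K = Σ g² × 6 × 2 = 4,092, split (12, 48, 192, 768, 3,072) across scales.
Amplitudes are i.i.d. U(−1, 1).

Conventions:

* **Orientation** is degrees counterclockwise from the horizontal image
  axis; pixel row 0 is the top of the image (so the visual rotation on
  screen is clockwise). Nothing statistical depends on this choice.
* **Windowing** is a hard rectangle (no taper). This is the simplest
  construction and matches the standard parametric-noise toolchain this
  dictionary mirrors.
* **Normalization**: every component has peak amplitude 1 before
  weighting, which makes amplitude parameters comparable across scales —
  the property the per-parameter effect-size screening relies on. A
  consequence is that component L2 norms differ by scale (a coarse patch
  has more pixels), which matters for recovery fidelity (below).
* Synthesis is exactly linear and never clipped or quantized; the basis
  exploits the tiled-patch structure instead of materializing K component
  images, with value-identical output (tested against the brute-force
  component sum).

**Non-orthogonality.** Oblique gratings sampled on a discrete grid leak
spectrally, so components are only approximately orthogonal, within and
across scales. The classification image therefore converges not to the
axis itself but to the axis filtered through the dictionary's Gram
operator, which re-weights content by squared component norm and thus
favors coarse scales. This is an inherent property of the construction,
not an estimation artifact: fine-scale template content is recovered with
visibly lower pixel-space fidelity than coarse-scale content.

## Stimuli

A stimulus is `(1 − blend)·template + blend·rescale(noise)` with
`blend = 0.5` by default (the conventional 50/50 mixture; configurable).
`rescale` maps the noise affinely from its theoretical amplitude range
[−B, B] to [0, 1], where B = n_scales × n_orientations × n_phases (60 for
the default dictionary) bounds |noise| at any pixel, since each pixel is
covered by exactly one patch per scale and all its orientation/phase
components, each of magnitude ≤ 1. Because B is a hard bound, stimuli
never clip for blend ≤ 1; the stimulus is an exactly affine function of
the amplitudes, which is what licenses the fast parameter-space observer
path (`classify_from_parameters`) as an exact equivalent of classifying
pixel stimuli. Quantization to 8 bits happens only on PNG export.

Prototypes rescale the CI to a target peak amplitude (default 0.2 of the
dynamic range — large enough to be visible, small enough that clipping on
a mid-gray template is rare; the underlying convention fixes only "same
maximum pixel value", so the peak is exposed as a parameter) and add it
to (female) or subtract it from (male) the template.

## Observers

The linear template observer computes
v = Σ (stimulus − template)·axis + ε, ε ~ N(0, σ²), and answers "female"
iff v > θ. Subtracting the template makes the observer respond to noise
content only, so with σ = 0, θ = 0 each label is a deterministic sign of
the noise–axis inner product and CI recovery is exact in expectation.
Ties (v = θ) go to "male"; a fixed rule is needed for determinism.
Four-level confidence responses split at a threshold on |v − θ| (default:
the within-batch median) and always collapse onto the binary label; only
the binary label feeds the analysis.

Two criteria are supported. `fixed_threshold` uses a constant θ.
`mean_activation` sets θ to the batch mean of v (two passes), the
bias-correction used for classifiers with a constant response offset; it
is by construction identical to `fixed_threshold` at θ = batch mean,
which the tests assert as exact label equality. Internal noise is drawn
from a per-trial substream seeded by (observer seed, trial index), so
single-trial and batch classification agree and reruns are
bit-reproducible.

External two-class classifiers enter through `external_adapter`: the
decision variable is (female score − male score), so at θ = 0 a trial is
male exactly when the male unit's activation is at least the female
unit's.

## Classification images and statistics

The CI is the female-minus-male mean difference of the amplitude vectors,
synthesized to pixels; the sign convention is fixed so that adding the
rescaled CI to the template gives the female prototype. Scales partition
the dictionary, so per-scale CIs are exact and sum to the full image.
Similarity between CIs is Pearson r on flattened pixel images by default
(parameter space offered as the basis-exact alternative); r is invariant
to the affine display normalization, so raw vs displayed CIs give the
same number. Zero-variance CIs yield NaN, never 0.

Per-parameter screening uses the classic pooled-variance two-sample t
(not Welch): class sizes are near-balanced by design, and Cohen's d uses
the pooled SD, so pooled t keeps the two statistics monotonically
consistent (their orderings coincide exactly for equal class sizes).
Significance is Bonferroni at α/K over all K parameters jointly — one
family for the whole Manhattan plot, not per scale. Zero-variance
parameters are flagged degenerate and never significant. Top-contributor
sets sort by |d| descending with ties broken by ascending parameter index
and return the shortest prefix reaching the requested share of Σ|d|.
Spearman correlations of contribution profiles are reported as NaN for
any scale holding fewer than 3 subset parameters.

## CI as a one-layer classifier

"Convolving" a face with the CI means the full-image inner product — one
output unit with the CI as its incoming weights — not a sliding
convolution. Each input image is mean-centered first (default,
switchable), which removes overall-brightness confounds and makes the
activation invariant to adding a constant to the image. Separation is
Cohen's d (pooled SD) signed as female mean minus male mean. The chance
baseline permutes the CI's pixels uniformly (seeded), preserving the
weight histogram while destroying spatial structure; the report gives the
permutation distribution's mean |d| and 95th percentile.

## Synthetic data: what it emulates, and what it does not

The generator stands in for three assets of a real study: the
gender-neutral template face (flat / radial / schematic-face styles; the
analysis is template-agnostic and the validation uses the flat style),
the observer's internal gender template (a known sparse combination of
basis components, unit-normalized in pixel space), and populations of
aligned face photographs (class mean = template ± effect_size × axis plus
i.i.d. N(0, noise_sd²) pixel noise, clipped to [0, 1]).

The `low_freq` axis preset fixes the per-scale composition
deterministically — largest-remainder counts from weights 0.6/0.3/0.1 on
the three coarsest scales, i.e. 90% of squared coefficient mass at 2–4
cycles/image — and randomizes only component identities and signs. The
coarse-dominant composition is the regime the generator is meant to
emulate (face-gender information concentrates at low spatial
frequencies), and it is also where linear-observer recovery is clean:
because of the Gram re-weighting described above, axes dominated by fine
scales are recovered with systematically lower pixel correlation.

Population defaults (effect 0.1, pixel noise SD 0.05, 500 images per
class) keep clipping negligible on a mid-gray template and admit a
closed-form check: with the axis itself as classifier weights,
d = 2·effect·‖axis − mean(axis)‖ / noise_sd = 4.0, which the measured
separation matches within sampling error.

What passing these validations shows: the estimator, statistics and
classifier behave correctly for an observer that *is* linear with a
*known* template, under noise that exactly matches the analysis basis.
What they do not show: behavior for real faces (non-Gaussian, spatially
correlated image statistics), nonlinear observers, misaligned inputs, or
templates unlike the internal axis — for real data the CI remains an
estimate of the best linear account of the observer's decisions, and
face sets fed to the classifier must be pre-aligned by the user.

## Problem sizes and numerical choices

The validation suite runs at image size 128 with the full 4,092-parameter
dictionary: 20,000-trial recovery runs (with 1,250 and 5,000-trial points
for the convergence curve, three seeds), a 5,000-trial null calibration,
200 familywise-error replicates on a reduced 30-parameter dictionary
(100 trials each), and 200 CI permutations against a 500-per-class
population. These sizes give stable statistics at desk scale; everything
scales to 512-pixel images unchanged. All stochastic stages take explicit
seeds; per-stage substreams are derived deterministically, so runs and
reruns are bit-identical. Float comparisons in invariant tests use
standard `allclose` tolerances; the only deliberate tie-break rules are
the observer's v = θ → "male" rule and the top-contributor index
ordering.

## Known limitations

* Hard-windowed sinusoids leak across scales; per-scale decompositions
  are exact in parameter space but not perfectly band-limited in the
  Fourier sense (the spectral centroid of each scale layer stays within
  half/double its nominal frequency).
* CI recovery is biased toward coarse scales by the dictionary's Gram
  operator (see above); comparisons *between* CIs estimated in the same
  basis are unaffected, since both carry the same filtering.
* The mean-activation criterion is batch-defined: labels depend on the
  composition of the stimulus set.
* No smoothing or Z-scoring of CIs is applied, and no FDR-style
  multiplicity control is offered — Bonferroni only.
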