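# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, and what the synthetic data do and do not
establish.

## Conventions

**Coordinates.** Pixel centers sit on integer coordinates, x increases
rightward, and the origin of a patch or kernel is its center (index
`n // 2`).

**Disparity sign.** Positive disparity means *far* and is applied as a
rightward shift of the right-eye feature: `right(x) = left(x - d)`.
Near surfaces carry negative disparity. Under this convention the
interocular receptive-field cross-correlogram is defined as
`c(d) = sum_x W_L(x) * W_R(x + d)`, so a unit whose right-eye field is the
left-eye field translated rightward by k pixels peaks at lag +k — its
preferred disparity. Depth-sign maps are reported as far minus near
activity (positive = far), and the convention is recorded in map metadata.

**Intensity.** Images live in [−1, 1]; bright, dark and mid-gray pixels
are +1, −1 and 0. A gray-level threshold of G (0–255 scale) corresponds to
G/127.5 in these units.

**Phase wrapping.** Phases are wrapped to [−π, π); values congruent to the
branch point map to −π.

## Gabor receptive fields and fitting

Binocular simple units are parameterized as per-eye Gabors; the right eye
may differ from the left in envelope position (position disparity), in
carrier phase (phase disparity), or both (hybrid). 1-D fits use a
two-stage optimizer: a coarse grid search over (center, envelope width,
frequency, phase) with the amplitude solved in closed form per candidate,
followed by bound-constrained L-BFGS-B with the frequency restricted to
±10% of the profile's Fourier peak (the profile is mean-subtracted before
the peak search, because zero-padding otherwise leaks DC into low
frequencies). The grid is 12 centers × 8 widths × 8 frequencies × 12
phases by default; negative-amplitude candidates are folded into a π phase
shift so the amplitude stays positive. Cross-sections for encoding
classification are taken through the row of peak absolute filter energy
(summed over both eyes), and units whose per-eye fit R² falls below 0.5
are flagged and excluded from population summaries.

Octave bandwidth and envelope width interconvert through the standard
Gabor relation σ = (1/πf)·√(ln2/2)·(2^b+1)/(2^b−1); at f = 0.0625
cycles/px and b = 1.5 octaves this gives σ = 6.28 px. The non-parametric
(FFT FWHM) estimate agrees with the parametric one to better than 2%
across b ∈ [1, 3.5] octaves *when the mirrored negative-frequency carrier
lobe is suppressed* by measuring the quadrature-pair spectrum; on a single
real profile the plain FWHM is biased upward for bandwidths much above 2
octaves, which is worth remembering when reading non-parametric bandwidth
numbers for broadly tuned filters.

## Stimuli

Random-dot stereograms draw their dots on a field wider than the image by
|d| and give each eye a horizontally offset crop, so every column of both
images is binocularly matched (no wrap-around strip). Anticorrelation
inverts dot contrast in the right eye by default (switchable); background
pixels are untouched. Step-edge stereograms (240×240 px, 8-px dots, ~15%
density) give each dot ±step/2 px of disparity by image half plus Gaussian
disparity noise (s.d. 8 px, rounded to integer pixels), place dots by
rejection sampling so no two dots overlap in either eye, and support
mixed, bright-only and dark-only polarity with three covariate controls
(per-image DC removal, peak-to-trough range matching to 2, and DC removal
followed by range matching).

The naturalistic-scene generator stands in for a photographic training
set. Each scene is a gray-scale texture with a power-law amplitude
spectrum (slope −1, s.d. 0.35 in [−1, 1] units) and a piecewise-constant
depth map over Voronoi regions. The default depth levels place surfaces on
one near and one far plane at ∓2 px of disparity (full depth scale maps to
the 10-px maximum shift): the depth-discrimination task is a binary
near/far classification trained on a small set of discrete disparities,
and ±2 px both sits comfortably inside the initial kernels' passband
(carrier period 10 px) and matches the 2-px step of the psychophysical
step-edge task. Stereo pairs are rendered by per-pixel horizontal shifts
with nearer surfaces overwriting farther ones on collision; disoccluded
pixels are filled by linear interpolation along the row and flagged.
Patches (30×30) are excluded when their gray-level s.d. is below 20 (0–255
scale), when more than 5% of their pixels were interpolated, or when their
ground-truth disparity is not a consistent near/far signal (mixed signs or
mean |d| < 1 px); survivors are split 70/15/15 into disjoint
train/validation/test sets.

What the generator does *not* emulate: photometric structure of real
scenes (shading, specularity, perspective), vertical disparities, sparse
edge/occlusion statistics of photographs, and continuous depth gradients.
Results obtained on these scenes show that the model class behaves as
described under naturalistic *second-order* statistics; they do not certify
performance on real photographs.

## Simple units, tuning, and the cross-correlogram

A simple unit computes `g(<W_L, s_L> + <W_R, s_R> + b)` with a static
nonlinearity (rectified linear, squaring, rectified squaring, or rectified
power). For broadband stimuli whose right image is a shifted copy of the
left, the squaring unit's mean disparity tuning is the affine-transformed
cross-correlogram `f(d) ≈ 2 c(d) E(S²) + C`; the per-pixel stimulus energy
E(S²) (0.5 for 50%-density ±1 dots) and the monocular constant C are
estimated from the ensemble rather than assumed. Empirical tuning curves
average fresh random-dot stimuli per disparity; map-mode responses apply
the unit convolutionally (valid, no padding) and sum the rectified map.
Cross-correlogram lags are restricted to the RF half-width in analyses;
out-of-support samples are zero.

## Shannon information of disparity encoders

Specific information is the KL divergence between the response
distribution conditioned on one disparity and the marginal; the total
information folds in a uniform disparity prior (the printed form of the
population sum omits the prior, but without it the log2(#disparities)
bound does not hold, so the prior-weighted form is used). Responses are
quantized into 10 equal-width bins per unit over the observed range — ten
levels per unit is what the stated memory footprint of a ten-unit joint
histogram implies — and joint histograms are stored densely, which caps
populations at five units (a capacity error reports the memory a larger
population would need). Estimates are plug-in; with the reduced sample
sizes used in tests they carry positive bias, so comparisons are always
made between quantities estimated from the same ensemble, and ordering
tests average over two independent ensembles.

The encoding comparison fixes σ = 5 px and f = 0.05 cycles/px. All units
share the envelope position but carry their own base carrier phase;
the encoding type sets the interocular offset: position shifts drawn over
± half a carrier period (the preferred-disparity span that phase encoding
can reach, which makes the encodings comparable), phase shifts over
[−π, π), or both. Uniformly spaced populations tile the same ranges, with
the base phases assigned by a stride-2 (Latin square) permutation so that
no tiled dimension is correlated with another. Broadband stimuli are
i.i.d. uniform pixel images whose right image is the wrap-shifted left.

## The binocular network

Architecture: 30×30×2 input → 28 binocular kernels (19×19×2, valid
convolution, stride 1) → rectification → 2×2 max pooling (non-overlapping,
first-occurrence tie-break) → softmax readout. For the 2-way model the
readout is antisymmetric: one 1,008-element weight vector drives far with
+w and near with −w plus two biases, for 21,254 learnable parameters
(20,244 convolutional + 1,010 readout); N-way variants use a full M×N
matrix. Kernels initialize as identical left/right vertical Gabors
(f = 0.1 cycles/px, σ = 3 px, phases equally spaced in [0, π]); readout
weights and all biases start at zero. The loss is categorical
cross-entropy; training is plain mini-batch gradient descent
(class-balanced batches of 100, constant learning rate) with validation
after each epoch and an iteration-based patience rule (initial limit
10,000 iterations without improvement, doubled whenever validation
accuracy improves by at least 0.5 percentage points); the best-validation
model is returned. Gradients are hand-derived reverse-mode and checked
against central finite differences.

Two desk-scale adaptations apply when the full optimization budget
(hundreds of thousands of iterations) is unavailable. First, the exact
symmetric initialization is a saddle: with identical eyes and zero
readout, near and far are statistically indistinguishable and only
mini-batch noise breaks the tie, which is slow. Scaled runs add a small
Gaussian perturbation (s.d. 0.1, seed-controlled) to the initial kernels;
the library default keeps the exact symmetric start. Second, scaled runs
use a learning rate of 0.004 rather than the 0.001 default, which at
O(10³) iterations trades some gradient-noise smoothing for convergence
speed. With these settings the reference configuration (300 scenes →
~3,500 training patches, 90 epochs, ~2,500 iterations, a few minutes on
one CPU) reaches ceiling validation accuracy, ~99% transfer to correlated
random-dot stereograms and single-digit accuracy on anticorrelated ones
(systematic inversion), with readout weights strongly correlated with the
units' cross-correlograms.

Lesioning removes named kernels with their readout weights. The optimal
stimulus of an output unit is computed by 100 gradient-ascent steps
(step size 1) on the unit's pre-softmax activity starting from uniform
noise; convergence is monitored by the correlation between consecutive
iterates. Depth-sign maps apply the convolutional layer at the input's
native size, weight each rectified map by the unit's mean readout weight,
and report far-minus-near activity; an FFT path (`ConvBank`) makes
repeated large-field maps cheap. The step-arrangement decision compares
the mean depth-sign activity of the two image halves; applied to the
ground-truth disparity maps this rule is exact, so task errors are model
errors. The polarity experiment renders each trial's dot layout in all
three polarity conditions (mixed as drawn; bright/dark with every dot set
to ±1), a paired design that compares conditions on identical geometry and
disparity noise.

## The binocular likelihood model

Complex units read out simple-unit rates with weights equal to the
interocular RF cross-correlogram at the complex unit's disparity
(`log L(d) = Σ_i r_i c_i(d)`): positive lobes act as detection, negative
lobes as proscription. The weighted sum agrees with the full Gaussian
log-likelihood up to disparity-independent terms when the population
tuning tiles disparity homogeneously. When rates are averaged over trials
to form a likelihood curve, the population-mean rate is subtracted first:
the disparity-independent monocular component of each rate otherwise adds
a Σ_i c_i(d) bias to the curve.

The nine-unit instantiation crosses position disparities {−3, 0, 3} px
with phase disparities {−π, −π/3, π/3} rad at f = 0.0625 cycles/px and
b = 1.5 octaves (σ = 6.28 px), applied as convolutional maps with periodic
boundaries whose rectified output is summed over space; the two complex
units read out at lags ∓3 px (the bank's position offsets; a
mean-over-near/far-lags mode is also provided). Simple units are rectified
linear, matching the network architecture the readout rule is derived
from. The rectification matters: with an unrectified squaring
nonlinearity the anticorrelated tuning curve is the *exact* mirror of the
correlated one (an algebraic identity), so the amplitude ratio is 1;
rectification breaks the symmetry and yields genuine attenuation
(ratio ≈ 0.98 at baseline). Raising the rectified drive to an exponent p
models compressive (p < 1) or expansive (p > 1) simple-cell output
nonlinearities; the amplitude ratio is monotonically non-decreasing in p,
i.e. compression deepens the attenuation. The same stimulus set is reused
across disparities (circular shifts) and exponents, so these comparisons
are made on matched noise.

Tuning-curve Gabor fits are performed on mean-centered curves (the Gabor
model carries no baseline term). The complex unit's spatial-frequency
bandwidth is estimated parametrically from the σ and f of the Gabor fit to
its correlated-stereogram disparity tuning curve, converted through the
octave-bandwidth relation — the same parametric estimator used for
receptive-field profiles; at the defaults it gives ≈1.05 octaves, narrower
than the 1.5-octave simple units, consistent with spatial pooling
narrowing frequency selectivity. A grating-probe alternative
(disparity-matched sinusoids across frequency, phase-averaged, FWHM in
octaves) is provided and gives systematically different numbers (0.9 for
energy units, 1.4 for rectified-linear ones); the probe choice matters and
is recorded with results.

## Amplitude-ratio bootstrap

Disparity tuning trials are resampled with replacement per disparity;
a Gabor is fit to each resampled mean cRDS and aRDS curve and the ratio of
fitted amplitudes recorded, pooling across complex units. Fits that fail
or fall below a configurable R² floor are excluded and counted; a warning
fires if more than 20% of resamples are lost.

## Known limitations

- The trained network's transfer accuracies depend on the synthetic-scene
  conditions; the mixed-polarity advantage in the step-edge task is small
  (1–2 percentage points) in this regime, compared with the large benefit
  reported for photographically trained networks and human observers.
- Plug-in information estimates at test-scale sample counts are biased;
  only within-ensemble comparisons are meaningful.
- The scene generator's Gaussian textures lack the sparse edge structure
  of photographs; kernels trained on them restructure less than
  photographically trained ones at matched iteration counts.
- The polarity task's efficiency ratio relative to human observers is not
  computed (the underlying psychophysical formula is not reproduced here);
  proportions correct are reported instead.
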