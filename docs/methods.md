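# Methods

`paflux` synthesizes the optical-forward half of a photoacoustic imaging
pipeline: randomized virtual forearm cross-sections with per-wavelength
optical-parameter maps, a reference Monte Carlo photon-transport simulation
producing initial pressure maps, and two differentiable surrogate networks
(a U-Net and a Fourier Neural Operator) that learn to replace the Monte
Carlo step. This note records the models, the parameters that matter, the
numerical choices, and what the desk-scale experiments do and do not show.

## Virtual tissue model

A sample is a 2-D cross-section over (depth z, lateral x) with square
pixels; depth increases downward from the illuminated surface at row 0.
The full-scale grid is 128 x 256 pixels at 0.15625 mm (20 x 40 mm); the
desk-scale grid halves the resolution (64 x 128 at 0.3125 mm) over the
same field of view.

Geometry: a skin band of uniform thickness (U[0.5, 2] mm by default,
optionally with sinusoidal undulation to emulate deformed skin) over soft
background tissue, with circular vessel cross-sections placed strictly
below the skin. Vessel count, radius and depth are drawn uniformly
(defaults: count U{2..6}, radius U[0.5, 3] mm, center depth U[2, 15] mm,
lateral position uniform). These uniform ranges are an explicit stand-in
for literature-derived anatomical distributions; every range is
configurable. Vessels alternate artery/vein so arteries come with
accompanying veins, are rejection-sampled to be non-overlapping, and each
carries its own oxygen saturation (arteries U[0.8, 1], veins U[0.4, 0.8],
constant within a vessel).

Optical properties: the absorption coefficient of each tissue class is a
volume-fraction-weighted sum over a packaged chromophore table
(oxy-/deoxyhemoglobin per whole-blood-equivalent fraction, water, fat,
melanin per melanosome fraction; 700-850 nm at 10 nm knots, linear
interpolation between knots; values compiled from standard tissue-optics
references). Scattering follows the power law
mu_s(lambda) = mu_s(800 nm) (lambda/800)^-b per class; anisotropy g is
constant per class. Units are mm and mm^-1 throughout.

Because voxel Monte Carlo engines commonly take a single scalar g, the
generator can substitute a fixed anisotropy using the similarity relation:
mu_s is rescaled by (1 - g)/(1 - g_fixed) so the reduced scattering
coefficient mu_s' = mu_s (1 - g) is preserved pixelwise. This is exact in
the diffusive regime and approximate in the quasi-ballistic regime near
the source. The desk-scale dataset default fixes g = 0 (mu_s becomes
mu_s'), which shortens photon histories by roughly the factor 1/(1 - g)
and makes the 10^6-photon fixture generation practical on one CPU;
per-pixel-g transport is fully supported and tested.

## Monte Carlo transport

Weighted-packet ("hop-drop-spin") transport on a voxel grid. The 2-D maps
are extruded uniformly out of plane into a slab (default half-thickness
10 mm) and transport runs in three dimensions, so out-of-plane photon loss
is represented; fluence is scored on a thin central out-of-plane bin
(default one voxel). Illumination is a collimated slit (default 30 mm) at
the top surface. Details:

- Step sampling: optical depth s ~ Exp(1) consumed against per-voxel
  mu_t = mu_a + mu_s; voxel traversal is DDA-style with the voxel index
  triple as explicit state, stepped along the binding axis at each
  crossing (no epsilon nudges, hence no grazing-incidence stalls).
- Absorption: at each interaction a packet deposits w mu_a/mu_t; fluence
  is deposited weight / (mu_a x scoring volume x photons launched), in
  mm^-2 per launched photon.
- Scattering: Henyey-Greenstein inverse-CDF sampling of the deflection
  cosine, uniform azimuth.
- Termination: matched (absorbing) boundaries; Russian roulette below
  weight 1e-4 with survival probability 0.1. The weight ledger
  (launched = deposited + escaped + roulette loss - roulette gain) is an
  exact floating-point identity and is asserted on every run.
- RNG: xorshift64* with a splitmix64-scrambled seed; single-threaded and
  bitwise reproducible for a fixed seed on one build.
- Initial pressure: p0 = Grueneisen x mu_a x phi with Grueneisen = 1 (a
  scalar hook exists). Dataset files store p0 scaled by the illuminated
  area, i.e. in units of the incident fluence, so surface p0 is O(1) and
  the logarithmic compression below has a meaningful dynamic range.

Validation oracles (all in the test suite): Beer-Lambert depth profile in
the absorption-only limit within 3 binomial standard errors; deep-fluence
decay rate in a scattering-dominated medium within 10% of the diffusion
value mu_eff = sqrt(3 mu_a (mu_a + mu_s')) — measured in a box large
enough (80 mm wide/out-of-plane) that transverse confinement adds < 5% to
the decay rate; Henyey-Greenstein first moment equal to g within Monte
Carlo error; noise MAE between runs scaling as 1/sqrt(N).

## Surrogate architectures

Both networks map the 3-channel optical stack (mu_a, mu_s, g) in physical
units to the 1-channel log-compressed initial pressure
p0' = log10(1 + p0), expanded back with p0 = 10^p0' - 1 (negative network
outputs clipped at expansion). The wavelength is never an input; it enters
only through the optical parameter values.

U-Net: depth 4 (four 2x2 max-pool downsamplings), two 3x3 conv + batch
norm + leaky-rectifier (slope 0.01) blocks per level, channel width
doubling from a base width of 8 (desk default; 64 at full scale),
nearest-neighbour upsampling + 3x3 convolution on the way up,
concatenation skip connections (an additive-skip variant sits behind a
flag), dropout 0.5 after each decoder block, 1x1 output head. Conv -> norm
-> activation ordering; dropout placed in the decoder. Grid dimensions
must be divisible by 16.

FNO: a pointwise lift to a latent width of 10 (desk default; 128 at full
scale), four Fourier layers, and a two-layer pointwise projection head
with a Gaussian-error activation between. Each Fourier layer runs two
paths in parallel — a spectral convolution and a local convolution (1x1
default, 3x3 behind a flag) — concatenates them along channels, restores
the latent width with a 1x1 convolution and applies the Gaussian-error
activation (an additive path combination sits behind a flag). The
spectral convolution transforms the field with a full 2-D FFT, retains the
symmetric low-frequency set {k : |k| < 12} per axis (2m-1 = 23 indices),
multiplies each retained mode by a learnable complex weight and returns
the real part of the inverse transform. Retained indices are recomputed
per input size, so one trained model applies at any resolution that
resolves the modes. At the desk defaults the FNO has ~425k parameters
against the U-Net's ~542k; widening the FNO to 16 channels did not lower
its validation plateau on the desk fixture, so the smaller width stands.

Both models run on a compact numpy reverse-mode autodiff engine written
for this package (conv/pool/upsample/batch-norm/activation/spectral
primitives with hand-derived adjoints). Every primitive and both
end-to-end architectures are validated against central finite differences
(relative error < 1e-5 in float64), and the spectral convolution against a
brute-force DFT-matrix oracle. Float32 is the training precision; float64
is available per model for gradient checks.

## Training recipe

Adam (beta1 0.9, beta2 0.999) with initial learning rate 0.01 and weight
decay 1e-4, batch size 16 (8 on the desk fixture, where an epoch is 70
pairs), reduce-on-plateau scheduling (factor 0.5, patience 5 epochs,
relative improvement threshold 1e-4 — with a constant validation loss the
first halving lands after epoch 6), up to 200 epochs at full scale.
Horizontal flips with probability 0.5 are applied jointly to input and
target. The U-Net minimizes mean squared error, the FNO the relative L2
loss (per-sample ||est - ref||2 / ||ref||2, batch-averaged); both losses
act on p0'. History row 0 records the untrained validation loss; the
checkpoint is taken at the epoch of minimal validation loss. Training
aborts on a non-finite loss. Fixed seeds reproduce loss histories exactly
on one platform; across BLAS builds small numerical drift is expected.

Evaluation metrics are computed on linear p0 after max-normalization
(both fields divided by the reference image's maximum; a log-domain
recomputation is available): max-normalized MAE, SSIM (Gaussian window
sigma 1.5, k1 = 0.01, k2 = 0.03, data range 1) and PSNR (data range 1,
identical pairs reported as an infinite sentinel and excluded from
aggregates). The dataset split is stratified on vessel count with exact
global bucket sizes; ablation subsets are nested prefixes of one seeded
permutation, so the fraction-1.0 run coincides bitwise with the standard
full-set training under the same seed.

## Desk-scale study conditions

The full-scale study conditions (1100 samples, 770/110/220 split, 16
wavelengths 700-850 nm, 5e8 photons, 128 x 256 grid) are preserved as a
configuration preset and used for bookkeeping checks. The experiments
that require simulation and training run on a desk fixture chosen to fit
a single CPU: 100 samples at 64 x 128, one wavelength (800 nm — the
wavelength at which the single-wavelength results are reported), 10^6
photons per reference map, 70/10/20 split, FNO trained 12 epochs and
U-Net 8 epochs at reduced widths. On this fixture the trained FNO reaches
a median test MAE of ~1.7% of the reference maximum (SSIM ~0.90), below
the ~2.4% median MAE of Monte Carlo rerun with 100x fewer photons (10^4)
— the desk analogue of the full-scale equivalence between surrogate
error and reduced-photon Monte Carlo error.

What the fixture does not show: absolute error levels of the full-scale
study (its references are 5e8-photon 3-D simulations; ours carry visible
reference noise), multi-wavelength generalization (one training
wavelength), device-twin illumination detail (divergence, angular spread),
refractive-index mismatch at the skin surface, or acoustic propagation —
all out of scope or configuration-only here.

### Error-character statistic

`error_map` reports the boundary-error concentration: the fraction of the
total absolute error of a max-normalized difference map lying within a
2-pixel band around tissue-class boundaries. Spatially white error
concentrates like the band's area fraction (verified in the tests);
errors locked to anatomy exceed it. Both trained surrogates exceed the
band fraction by a factor of ~3 (concentration ~0.5-0.6 against a band
fraction of ~0.18), i.e. their errors are strongly structure-localized.
Reduced-photon Monte Carlo error, however, is *not* spatially white: its
amplitude is signal-proportional, and the brightest tissue (the skin
band) lies inside the boundary band, so its concentration (~0.68) exceeds
the surrogates' at this training scale. In the perfect-surrogate limit
the surrogate error map degenerates to reference noise with that same
concentration; surpassing it requires boundary errors to dominate over
the smooth background misfit that remains at 70 training samples. The
package therefore reports both concentrations side by side rather than a
single pass/fail contrast.

## Numerical and degenerate-input choices

- Transparent voxels (mu_t = 0) are traversed ballistically; a medium
  with mu_t = 0 everywhere is rejected as degenerate.
- Fluence voxels with mu_a = 0 would divide by zero in the absorbed-
  weight estimator and are reported as zero fluence (the generator always
  produces mu_a > 0).
- The relative L2 loss adds 1e-20 under the square root for a finite
  gradient at exact zero error; references with zero norm are rejected.
- Max-pool ties route the gradient to the first maximum; max-normalized
  metrics reject all-zero references.
- Stratified splitting floors per-stratum allocations and tops up from a
  shuffled remainder pool, guaranteeing the exact global 770/110/220
  counts at full scale.
- Seeds: every stage seed is blake2b-derived from (master seed, stage
  name, index) and kept below 2^31.
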