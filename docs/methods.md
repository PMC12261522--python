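# Methods

## Problem and model

Optical Monte Carlo simulation of scintillation detectors tracks every
optical photon through hundreds of interactions (bulk absorption,
diffuse reflection at the wrapping, Fresnel reflection/refraction at
the readout face) before it reaches the photodetector. For a fixed
detector configuration, the per-photon outcome at the detector face is
fully described by a six-dimensional phase-space vector — position
(X, Y), direction (dX, dY, dZ) and kinetic energy (EKine) — whose
distribution depends only on the photon's emission point inside the
crystal. `scintigan` replaces tracking with sampling: a conditional
generative model learns the mapping from emission coordinates to the
joint phase-space distribution, after which producing a photon costs
one network forward pass instead of a random walk.

The package has three layers:

1. **Toy transport simulator** (`scintigan.optics`) that produces
   training and reference data.
2. **Conditional WGAN-GP surrogate** (`scintigan.gan`) trained on
   simulator phase-space tables.
3. **Evaluation** (`scintigan.evaluation`) by per-feature histogram
   Jensen–Shannon similarity, the field's standard way to quantify
   agreement between a surrogate and its source simulation.

## Transport model and its assumptions

The simulator is intentionally a desk-scale stand-in for a full
Geant4-style optical simulation. It models a cuboid crystal
(default 3 × 3 × 10 mm³, BGO-like refractive index 2.15) with the
coordinate origin at the centre of the exit face, Z increasing away
from the photodetector. Physics per photon:

- isotropic emission at a point, energies from a truncated Gaussian
  (mean 2.58 eV ≈ the 480 nm BGO emission peak, sd 0.15 eV);
- straight-line flight with exponential bulk attenuation
  (default 300 mm attenuation length; Rayleigh scattering is folded
  into this single length rather than modelled as a separate step);
- Lambertian (cosine-lobe) reflection with scalar survival
  probability 0.95 at the five reflector-wrapped faces, standing in
  for a measured-surface lookup-table model;
- unpolarized Fresnel reflect/transmit at the exit face against the
  optical coupling medium (default n = 1.56), with deterministic
  Snell refraction on transmission and total internal reflection
  beyond the critical angle (≈ 46.5° for 2.15 → 1.56);
- a 1000-bounce cap; capped photons are reported separately, never
  silently dropped;
- ideal photodetector (detection efficiency 1).

These choices reproduce the qualitative structure a surrogate must
learn — multimodal direction marginals from the interplay of the
direct cone, total internal reflection and diffuse wall bounces, and
position marginals that shift with the emission point — without any
external surface-model dataset. What the toy model does *not*
reproduce: electron transport and ionization (events begin as photon
bundles at a point), wavelength-dependent optical constants,
polarization, and measured surface microfacet distributions. Passing
tests therefore demonstrate that the surrogate learns *this*
simulator's distributions, not that it would match a laboratory
detector.

Tracing is vectorized over photon arrays; a fixed seed gives bitwise
identical output tables. Detected-photon collection efficiency with
the default geometry is ≈ 0.5, so producing n detected rows costs
≈ 2n emitted photons.

## Training data

The emission grid covers one octant of the crystal cross-section with
the 10-point triangular lattice {(x, y) : x, y ∈ {0, 0.5, 1.0, 1.49} mm,
y ≤ x} at three depths {1, 5, 9} mm — 30 points, including the
reference point (0.5, 0.5, 1.0). Boundary points are inset by 0.01 mm
to stay strictly inside the crystal. Each grid point is re-simulated
until exactly 30 000 detected rows are accumulated, giving the
900 000-row training table. All nine columns (six features plus the
three emission-coordinate condition labels) are z-scored; the
per-column means and population standard deviations (ddof = 0) are
persisted with a content hash of the dataset and are the only
statistics used for denormalization at generation time.

## Surrogate

Generator: latent 64 (standard normal) ⊕ condition 3 → hidden widths
H, 2H, 2H, 4H → 6, ReLU hidden, linear output. Critic: features 6 ⊕
condition 3 → 4H, 2H, 2H, H → 1, ReLU hidden, no output nonlinearity.
Default H = 128; the scaled benchmark uses H = 64. Conditioning is by
concatenation, the baseline mechanism for conditional GANs. Losses are
the Wasserstein critic loss with gradient penalty (λ = 10, gradient
taken with respect to the interpolated feature block) and
L_G = −E[f(fake)]; both networks use Adam (lr 5 × 10⁻⁵, β₁ = 0.5,
β₂ = 0.9) with three critic updates per generator update.

The networks are implemented directly over numpy with hand-written
reverse-mode gradients. The gradient penalty needs the derivative of
the critic's input gradient with respect to the weights; for ReLU
networks this has a closed form with the activation masks held fixed
(exact almost everywhere), costing one extra masked forward pass per
batch. All gradients are verified against central finite differences
in float64 in the test suite. Training math is float32.

Two training refinements are package design choices (both standard
GAN practice, both configurable):

- **Checkpoint weight averaging.** Checkpoints store an exponential
  moving average of the generator weights (decay 0.999) rather than
  the instantaneous weights. Raw WGAN-GP trajectories on this problem
  oscillate around equilibrium by several similarity points;
  averaging turns the similarity trajectory monotone and removes the
  oscillation.
- **Damped final-layer initialization.** The generator's output layer
  is initialized at 0.1 × its He-init scale, so the initial output
  distribution starts near the (z-scored) data mean instead of an
  arbitrary wide Gaussian.

Checkpoints are scored each epoch by mean 1 − JSD similarity between
generated and held-out simulator samples per emission point; the best
checkpoint (ties to the later epoch) is the one used by the pipeline.
Held-out data — never the training rows — is used for scoring. A
non-finite loss aborts training with the offending epoch/iteration.

## Generation pipeline

The event side mirrors a tracking-free fast simulation: photons are
counted at creation and immediately discarded, so an event log
supplies each event's photon count n_op and its emission point (the
first recorded electron position). `run_surrogate` draws all latents
up front from the seeded generator and evaluates the network in
batches (default 65 536 rows), so batch partitioning cannot change the
sampled randomness; outputs agree across partitionings to float32
round-off, and output files are byte-identical for a fixed seed at a
fixed batch size. Generated features are denormalized with the
training statistics carried inside the checkpoint. No clipping to
physical ranges is applied by default; an optional clip mode clamps
positions to the detector face and renormalizes directions.

Event counts follow Poisson(activity × duration) and per-event photon
yields Poisson(2400) by default, so 1000 Bq over 1 s gives ≈ 2.4–2.5
million photons. The acquisition duration is taken as 1 s when only
an activity is specified.

## Similarity methodology

Two samples are compared per feature on 1-D marginals: 100 bins
spanning the combined min–max of both samples, histograms normalized
to probabilities, Jensen–Shannon distance with base-2 logarithms
(bounded by 1), similarity = 1 − JSD. Empty bins contribute zero via
the 0·log 0 convention. The binning-sensitivity helper reports the
similarity spread over a list of bin counts. Because the metric is
histogram-based it has a sampling floor: two independent 30 000-row
draws from the same simulator point score ≈ 0.965–0.97, which is the
practical ceiling for any surrogate under this protocol.

## Scaled benchmark and problem sizes

The reference benchmark (`scintigan.experiments.
run_scaled_similarity_experiment`, also what `scripts/acceptance.py`
runs) trains at reduced scale chosen so the full three-seed experiment
completes comfortably on a single CPU: 4 emission points spanning the
octant and all three depths, 10 000 training rows per point, H = 64,
batch 384, 4 500 generator updates (9 epochs × 500), checkpoint
scoring on 10 000 held-out rows per point, final scoring on 30 000
held-out rows per point with 100 bins. All randomness derives from a
single seed.

Under the pinned optimizer settings this configuration converges
smoothly but does not saturate: longer probes show the similarity
still limited by the small learning rate and the adversarial noise
floor rather than by model capacity. The achievable mean similarity
at this scale is documented by the acceptance script output rather
than asserted here.

## Numerical choices and degenerate inputs

- Photons are nudged 10⁻¹² mm off a face after reflection to avoid
  zero-length steps; positions exactly on a face are clipped inward.
- `fresnel_reflectance` returns exactly 1 beyond the critical angle;
  refraction signals total internal reflection rather than raising an
  error.
- Constant columns make z-scoring ill-defined; `compute_stats` raises
  and names the offending column (a single-depth dataset has constant
  emZ, so normalization requires at least two depths or an explicit
  column subset).
- Histogram JSD of two identical degenerate samples (all mass at one
  value) is defined as 0.
- Subsampling is uniform without replacement; requesting more rows
  than exist is an error, never silent truncation.

## Known limitations

- The transport model's realism limits what similarity scores mean;
  see above.
- The surrogate does not generalize across detector configurations:
  a new geometry, wrapping or spectrum requires retraining.
- GAN outputs are not constrained to the physical manifold
  (|direction| = 1, positions on the face); the evaluation treats
  features as independent 1-D marginals, as is standard for this
  comparison protocol.
- Wall-clock speed-ups versus full tracking are hardware-dependent
  and deliberately not quantified here.
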