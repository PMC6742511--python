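# Methods

## Model

`synthreg` registers a 2D grayscale image pair of different modalities — an
"MRI" image `M` to be warped and a "histology" image `H` that stays fixed —
by jointly estimating an inter-modality synthesis and a deformable
registration on the target pair alone.  The pieces:

* **Deformation model.** `U(x)` is discrete: each pixel's displacement lives
  on a square grid of candidate vectors (radius and step in mm).  The prior
  is a pairwise MRF: unary potentials `β₁‖U(x)‖²` shrink displacements,
  binary potentials `β₂‖U(x)−U(x′)‖²` over 4-neighbour edges smooth the
  field.  Each unordered edge is counted once everywhere in the package, so
  `β₂` has a single consistent meaning in the prior, the mean-field update
  and the registration energy.  The MRF partition function is never needed.
* **Landmarks.** Optional point pairs (k on `M`, kʰ on `H`) with isotropic
  Gaussian placement error (std `σ_k`, default 0.5 mm); the residual is
  `kʰ − k + U(kʰ)`, with the landmark factor applied at the histology pixel
  (the deformation is defined on histology space).
* **Synthesis.** A regression forest maps Gaussian-derivative features of
  `H` (orders 0–3 at scales 0/2/4 mm; scale 0 means central differences on
  the unsmoothed image; all axis-aligned partials of each order) plus the
  pixel location in mm — 32 features — to the intensity of the warped `M`.
  Prediction pools T trees with a conjugate Inverse-Gamma prior on the
  per-pixel variance, so the predictive variance is
  `(2b + Σ(g_t−μ)²)/(2a+T)`: it never falls below `2b/(2a+T)` and equals
  that bound exactly when all trees agree.

## Inference

Mean-field variational EM.  Beliefs start uniform over the label set
(maximum registration uncertainty); the forest is initialised by a fit under
those uniform beliefs.  The E-step computes the predictive maps and then runs
red–black fixed-point sweeps of the per-pixel update; the pairwise term needs
only each neighbour's first and second belief moments, so a sweep is
O(|Ω|·S).  The M-step retrains the forest, drawing for every training pixel
one displacement per tree from its belief and regressing the image value at
the displaced position (displaced samples leaving the domain are dropped).
Convergence is tracked on the predictive maps — relative L2 change of μ
below `outer_tol` — because the tree parameters themselves fluctuate under
the randomised training; the stochastic M-step forfeits any monotonicity
guarantee, and non-convergence within `max_outer` returns the current state
with a warning flag.

Numerical choices: likelihood factors for out-of-domain displaced samples
are neutralised to the pixel's mean in-bounds likelihood, so border pixels
are decided by the prior and their neighbours; beliefs are renormalised in
log-space with a floor, resetting to uniform on total underflow (logged);
inner sweeps stop at an L∞ per-pixel L1 change of `inner_tol` (default 1e-4,
max 50 sweeps).

## Final registration

* **Graph cuts.**  The discrete energy (variance-weighted SSD + landmark
  quadratic + MRF terms) is minimised by alpha-expansion.  Binary
  subproblems are solved by max-flow (`scipy.sparse.csgraph.maximum_flow`)
  on integer-scaled capacities.  Squared label distance is a semi-metric, so
  some subproblems are non-submodular; they are truncated (an optimistic
  keep-cost-lowering variant, then a conservative move-cost-raising variant
  whose cut provably never raises the true energy), and a move is accepted
  only on strict decrease of the exact energy, with labels visited in fixed
  order.  For small label sets stalled expansion passes are followed by
  exact alpha-beta swap cycles (always submodular for this pairwise cost).
  In heavily frustrated random energies (pairwise comparable to the unary
  spread) expansion can still terminate a few percent above the global
  optimum; at the model's operating weights it is near-exact.
* **B-spline refinement.**  A cubic B-spline free-form deformation minimises
  the α-scaled weighted SSD (α⁻¹ = 9|Ω|/2, so the term is ≈ bounded by 1 and
  equals 1 at uniform 3σ residuals) plus the landmark term, bending energy
  (squared second derivatives) and a linear-elastic term (squared symmetric
  part of the displacement gradient — our reading of "stretch and shear
  after removing rotation"); a log-Jacobian penalty is implemented but off
  by default.  Penalty energies are per-pixel means evaluated in
  control-grid units (multiplying the mm-unit energies by `(cp/spacing)⁴`
  and `(cp/spacing)²`), the normalisation convention of control-point
  registration packages, so the default weights (0.001, 0.01) act at
  comparable strength across grid resolutions.  Optimisation is L-BFGS with
  analytic gradients (image values and gradients from a bicubic spline),
  single resolution level, relative-change stopping at 1e-6.
* **MI baseline.**  Same B-spline model and penalties; the data term is
  −MI from a hard-binned 64×64 joint histogram (intensities min-max scaled
  per image; degenerate constant images give MI = 0).  Hard binning makes
  the objective piecewise constant in the coefficients, so the optimiser is
  Powell's derivative-free method rather than a gradient scheme.
* **Linear pre-alignment.**  The model assumes coarsely linearly aligned
  input.  `registration.prealign_similarity` provides that step when needed:
  a 4-parameter similarity (rotation, log-scale, translation, bounded to a
  "coarse residual" range) fitted by Powell on the hard-binned MI.  The
  experiment pipelines apply it identically to the proposed and MI arms and
  compose the linear and nonlinear fields.  This matters: started from a
  cold uniform belief state, the joint estimation cannot recover a large
  coherent linear misalignment — the forest trained under spread beliefs
  predicts a displacement-blurred version of `M` anchored at each pixel, a
  self-consistent state in which the mean-field update weakly prefers zero
  displacement and the linear component is absorbed into the synthesis.
  Local (velocity-field-scale) deformations are not expressible by the
  synthesis and are recovered normally.

## Synthetic data

The generator emulates preprocessed multi-contrast brain slices:

* a smooth random tissue label map (thresholded smoothed noise) inside an
  elliptical brain mask, 3 classes by default;
* per-class intensities that are non-monotonically related between the
  modalities (no affine intensity map links them), plus a shared smooth
  structural texture with class- and modality-specific gains;
* independent smooth multiplicative bias fields — strong (0.35) on the
  histology-like modality, emulating staining inhomogeneity, mild (0.1) on
  the MRI-like one — giving genuinely spatially varying contrast, which is
  the regime where global intensity-mapping metrics are at a disadvantage;
* a 0.8 px point-spread blur (partial volume of acquisition + resampling),
  Gaussian noise (std 2 gray levels, the level of well-preprocessed data),
  rescaling to [0, 255] and 8-bit quantisation.

Deformations: a stationary velocity field (i.i.d. bivariate Gaussian noise
of std `σ_v`, Gaussian-smoothed at 5 mm, multiplied by a boundary window
`1 − exp(−0.1·D)` with D the distance to the image edge in mm — zero at the
boundary, ≈1 beyond ~30 mm inside, a rate chosen so desk-scale images get
full-strength interior deformations) integrated by scaling and squaring
(auto-chosen number of squarings, floor 4, so the scaled step is under half
a pixel), composed with a random similarity (stds 2°, 1 px, 0.1 log-scale).
Because the deformed image is produced by resampling with the composed map
ψ, the pair stores both ψ's displacement (`warp_field`, for reproduction
checks) and the displacement of ψ⁻¹ (`truth_field`, computed exactly via the
integrated negated velocity and the analytic similarity inverse), which is
what a registration of the deformed image onto the fixed one should recover.
Landmarks come from an iterated Harris-corner argmax (k = 0.05, 1 px
smoothing, row-major tie-break) with complementary-Gaussian suppression
(per-axis σ of a tenth of the image size), mapped through the ground truth
and perturbed with `σ_k` noise.  Artefacts (dark cracks and elliptical
holes) can be injected with an exact corruption mask.

What the phantom does *not* model: MRI physics, realistic neuroanatomy,
fine-scale self-similar tissue texture, non-diffeomorphic histology damage
(tears, folds) and slice-specific staining chemistry.  Passing tests on the
phantom therefore demonstrate mechanism (uncertainty-weighted matching,
artefact downweighting, landmark propagation) rather than clinical-grade
accuracy on real sections.

## Evaluation protocol and known limitations

Field errors are per-pixel Euclidean distances to the exact ground-truth
field over the brain mask eroded by the label radius (avoiding boundary
extrapolation); landmark errors use the same residual as the landmark
likelihood with bilinear field lookup.  Experiment sweeps run the proposed
and MI pipelines on the same pairs across noise levels, control-point
spacings and landmark counts, and report a tidy table; a paired Wilcoxon
signed-rank p-value is available for method comparisons but is reported
only, never used as a test gate.  Desk-scale test settings reduce the
ensemble to 15–30 trees, the label grid to a few hundred labels (radius
sized to the post-alignment residual) and the VEM loop to 3–4 outer
iterations.

Limitations worth knowing:

* With a single image pair, uniform belief initialisation leaves a standing
  blur in the synthesis (beliefs and forest stabilise at a nonzero mutual
  uncertainty), which costs a few tenths of a mm of registration accuracy
  relative to a synthesis trained at the converged alignment.  On smooth,
  low-noise phantom pairs with sub-mm deformations this overhead can exceed
  the advantage of the intra-modality metric, and the MI baseline —
  operating right in its comfort zone on such pairs — can be the more
  accurate method; the advantage of the joint model shows on artefact-laden,
  spatially varying contrast, which is its target domain.
* The discrete stage's output need not be diffeomorphic; only the synthetic
  generator guarantees diffeomorphisms.
* The B-spline stage is single-resolution; no multi-level pyramid.
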