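# Methods

This note records the models, numerical choices and assumptions behind
`tdtract`, in the order data flows through the package.

## Signal model and tensor estimation

Diffusion-weighted signals follow the mono-exponential model
S(g, b) = S₀·exp(−b·gᵀDg) with a symmetric positive tensor D per voxel.
The fit is weighted linear least squares (WLLS) on the log-signal: one
ordinary least-squares pass of
ln S = ln S₀ − b·gᵀDg, followed by one reweighted pass with weights equal
to the squared model-predicted signals — the standard scheme that undoes
the noise distortion introduced by the log transform. Voxels with any
non-positive signal are excluded from the validity mask; rank-deficient
gradient schemes (fewer than six directions distinct up to sign, or
coplanar sets) are rejected outright. No negative-eigenvalue repair is
applied: implausible voxels simply fail the FA window during tracking.

FA is √(3/2)·‖λ − mean λ‖/‖λ‖ (clipped to [0, 1], defined as 0 for the
zero tensor); MD is the eigenvalue mean. Eigenvalues are reported in
descending order; the principal direction is defined up to sign.

## Tracking

Integration is fixed-step Euler along the principal eigenvector of the
trilinearly interpolated tensor (component-wise interpolation, then
eigendecomposition; interpolating eigenvectors directly is ill-defined
under their sign ambiguity). The eigenvector's sign is aligned with the
previous step; at an exact 90° flip the angle criterion terminates the
track for any limit below 90°. A candidate step must satisfy, at the new
point: FA inside the window (trilinear), angle to the previous direction
within the per-step limit, normalized TD at or below the threshold when
the TD criterion is active (nearest-voxel lookup — TD is a count map and
interpolation would smear the tendon ridge), membership of the boundary
mask when active (nearest voxel), position inside the volume, and total
length within a 500 mm safety cap. Tracks grow bidirectionally from each
seed and the halves are concatenated; tracks shorter than the minimum
length are dropped and counted. The batched implementation propagates
seeds in chunks (principal directions from a closed-form trigonometric
3×3 eigensolver, verified against LAPACK in the tests); chunking does not
change results, and identical inputs give bit-identical tractograms.

Default parameters: pass 1 (whole volume, builds the TD map) FA 0.1–0.7,
20°/step, 1 mm steps, 2 mm minimum length, seeds on a 1 mm lattice over
the foreground; pass 2 (per muscle) 10°/step, 20 mm minimum length,
TD threshold 1.5, seeds on a 2 mm lattice inside the muscle mask eroded
to 90 % of its volume. The pass-2 step length is specified as a fraction
(0.2) of the in-plane working voxel, i.e. 0.3 mm at the default
1.5 × 1.5 × 3.0 mm grid; the unit of the protocol's "step length = 0.2"
is not fixed by convention, so the voxel interpretation is the default
and the value is config. The pass-2 seed spacing is likewise a free
protocol detail; 2 mm gives ~10⁴ streamlines per phantom muscle, ample
for a stable distribution fit. Erosion to a target fraction applies
repeated one-voxel 6-connected erosions and returns the first mask at or
below the target, never an empty one. The FA upper bound applies at the
seed as well as during propagation.

## Tract density and tendon segmentation

TD counts, per voxel, the number of **distinct streamlines** whose
polyline crosses it — each streamline increments a voxel at most once, so
the map is independent of the tracking step length; the voxels crossed by
a segment are found with an exact Amanatides–Woo 3D traversal (step
lengths can exceed the slice thickness). Normalization divides by the
mean count over the tissue foreground (voxels above 25 % of the robust
b=0 maximum) rather than the rectangular FOV: air voxels carry no tracks
and would deflate the mean. The normalized map therefore averages exactly
1 over the foreground, muscle sits near 1, and voxels above the threshold
(default 1.5) — tendinous sheets, plus occasional artifacts — form the
stopping mask of the second pass.

## Fascicle length

Tracks with an endpoint within one slice thickness of either axial
(z) volume face are excluded: they are truncated by the FOV, not full
fascicles (the margin is config). The "skewed Gaussian" is the
skew-normal family SN(ξ, ω, α), fitted by maximum likelihood on the raw
sample (bin-free, reproducible; a histogram least-squares fit would add a
binning choice). Initialization is method-of-moments; a failed or
non-finite optimization falls back to the sample mean with α = 0 and a
cleared convergence flag, as do degenerate (zero-variance) samples.
Samples below a configurable minimum (default 50) are reported without a
fit. The headline "mean fascicle length" is the fitted distribution's
mean ξ + ωδ√(2/π); the mode and location are also emitted since the
convention is not universal. Lengths are stored in mm and reported in cm
with one decimal in summary tables.

## Repeatability statistics

For paired sessions: differences d = s₁ − s₂ (the sign convention is
cosmetic; only symmetric quantities are reported), bias = mean d,
sd = SD of d (n−1 denominator), limits of agreement bias ± 1.96·sd,
CV = 100·sd/(mean of all 2n measurements), MDD = 1.96·sd. These are
definitional identities and the tests hold them to 1e-12. Incomplete
pairs are excluded with a warning. The summary table reports, per muscle
and condition, the between-subject mean ± SD of per-subject means along
with CV and MDD. Inferential testing across conditions (repeated-measures
MANOVA and post-hoc corrections) is deliberately out of scope: the tidy
CSV output is designed to drop into any statistics environment.

## The synthetic phantom

The phantom emulates the acquisition the method targets: a lower-leg
style protocol (12 electrostatically spread gradient directions at
b = 400 s/mm², one b=0 volume, muscle SNR 40, working grid 40×40×60 at
1.5 × 1.5 × 3.0 mm) on a unipennate muscle: a planar aponeurosis complex
(normal along x, tendon axis z) flanked by two muscle compartments whose
fibers lie in the x–z plane at ±30° pennation, bounded by fasciae, with
air outside. Ground truth is exact: L = w/sin θ = 44 mm at the default
half-width w = 22 mm.

Choices that matter, with the reasoning:

* **Tissue fractions are exact slab overlaps.** All interfaces are planes
  normal to x, so the tendinous volume fraction of a voxel is a 1D
  interval overlap — the partial-volume structure is analytic, and a
  supersampling oracle in the tests confirms it.
* **Diffusivities.** Muscle (2.2, 1.5, 1.3)×10⁻³ mm²/s (FA ≈ 0.28,
  mid-range for human lower-leg muscle; the λ₁−λ₂ gap controls how noisy
  fitted fiber directions are). Tendon (1.8, 0.4, 0.4)×10⁻³ (FA ≈ 0.74,
  above the 0.7 tracking bound, so pure tendinous voxels halt tracking —
  values with FA below 0.7 turn the aponeurosis into an endless guide
  rail for streamlines, which no real muscle shows). Both are config.
* **Mixing is at the tensor level**, weighted by signal contribution:
  tendon is strongly hypointense (fast transverse relaxation), so a
  tendinous volume fraction f contributes f·w of the voxel signal
  (w = 0.5 by default) and the voxel tensor is the mixture with effective
  fraction f·w/(m + f·w). This reproduces the central partial-volume
  mechanism: interface voxels' principal axes rotate toward the tendon.
* **Aponeurosis 4 mm, fascia 3 mm, voxel-aligned.** The aponeurosis
  complex spans two pure-tendon columns (FA 0.74 — the runner-killing
  core) and two f = 1/3 partial-volume flanks (the redirection zone where
  tract density piles up); the fasciae are pure columns. This is the
  minimal geometry that exhibits, at once: muscle TD ≈ 1, a TD > 1.5
  tendon ridge, FA-only track elongation along the sheet, and correct
  TD-stopping.
* **The image noise is the residual after upstream denoising.** The
  preprocessing this pipeline expects (denoising, motion/eddy and EPI
  correction) happens before data reach it. The noise scan — and hence
  the *measured* SNR — reflects the raw acquisition (σ = S₀/SNR), while
  the image volumes carry Rician noise of σ/denoising_gain
  (default gain 2, typical of modern Rician denoisers at 13 volumes).
  Without this distinction the fitted direction field is noisier than
  any data the method would see in practice, and spurious tract-density
  speckle halts second-pass tracks early.
* **Labels emulate manual segmentation, including its error.** The
  muscle masks are the true compartments perturbed by a smooth random
  boundary displacement (SD 2 mm, correlation length 20 mm — in-plane
  delineation plus registration-propagation error). With exact labels the
  boundary-stopping comparison method would be indistinguishable from
  TD-stopping on this idealized geometry; the displacement reproduces the
  documented short-fascicle clipping. Setting the amplitude to 0 disables
  it (and the tests confirm all three methods then agree).
* **Determinism.** All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical phantoms
  and, because tracking is deterministic, bit-identical pipelines
  (content-hashed in the run manifest).

What the phantom does **not** model — and hence what passing tests do not
show about real data: curved fascicles and sheets, fiber dispersion and
multi-compartment diffusion, EPI distortion, motion, eddy currents, fat
signal, T2/TE effects beyond the single tendon-hypointensity factor,
inter-muscle contact (each phantom muscle borders tendon or air, never
another muscle), and registration between sessions. Repeatability on real
data includes repositioning and physiology; the synthetic paired cohort
used in the tests has purely Gaussian session noise and checks the
statistics, not scanner test-retest behaviour.

## Problem sizes in tests and the acceptance script

The study-conditions phantom (40×40×60 grid, ~5·10⁵ pass-1 seeds) runs
the full pipeline in about a minute and is used directly for the
contrast and method-comparison checks. Unit tests use a 30×20×24 phantom
with 40° pennation (L = 23.3 mm) where full realism is not needed; the
bit-reproducibility check re-runs that small configuration twice. The
skew-normal recovery uses n = 5000 samples, the repeatability cohort 100
subjects; both finish in seconds.
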