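# Methods

This note records the models implemented in `elastimap`, the numerical
choices behind them, and what the synthetic test bed does and does not
establish.

## Variational registration model

Given a reference image `R` and a template `T` on a 2D pixel grid, the
displacement field `u` minimises `J[u] = D[u] + α S[u]` with

* similarity: the normalized gradient field,
  `D = ½ Σ_x (1 − ⟨n(R,x), n(T,x+u(x))⟩²)`, where
  `n(I,x) = ∇I(x)/‖∇I(x)‖_ε` and `‖g‖_ε = √(g₁²+g₂²+ε²)`. Only edge
  orientation matters: the measure is invariant to multiplying either
  image by any nonzero constant (including sign flips), which is what an
  inversion-recovery series requires. The domain measure is the pixel
  count (unit pixel area); physical spacing is metadata applied at I/O.
* regularizer: the linear-elastic potential with Lamé parameters μ
  (shear) and λ (volume), discretised with the same `np.gradient`-style
  stencils as the solver operator (central differences inside, one-sided
  at the border — Neumann-type, so constant fields cost nothing).

**ε rule.** `ε = epsilon_fraction × mean |∇I|` per image, with a floor of
`1e-8 × intensity range + 1e-12` so constant images stay well-defined.
ε scales linearly with intensity, which is what makes `D` scale-invariant.
Default `epsilon_fraction = 0.1`.

**Discrete objective and exact force.** The template is represented by a
bicubic spline on an edge-padded domain (padding prevents the spline
library from clamping out-of-range coordinates, which would break
differentiability at the border). The similarity force is the analytic
gradient of this exact discrete objective — first and second spline
derivatives at the warped positions — and agrees with a central
finite-difference perturbation of `D` to truncation error (≈2e-6
relative on 8×8 tests).

## Solver

Each outer iteration solves `(α L + τ I) δu = −(f + α L u)` by conjugate
gradients, where `L` is the sparse symmetric elastic operator
(`⟨u, L u⟩ = 2 S[u]`) and τ is a small Tikhonov weight (default 0.01)
that makes the system definite on the translation null space. The step is
capped at `max_step` (2 px) and halved until `J` does not increase, so the
joint functional is non-increasing across accepted iterations; iteration
stops when the applied update's max-norm falls below `update_tolerance`
(0.05 px) or after `max_outer_iter` (50). The whole solve runs
coarse-to-fine in a Gaussian pyramid (factor 2, σ = 1 px smoothing,
default 3 levels, coarsest level kept ≥ 16 px), with the displacement
up-sampled and doubled between levels.

Three choices deserve explanation because the bare functional does not
behave the way users expect at its edges:

* **Edge-significance weighting.** The search direction weights the force
  by `(‖∇R‖²/(‖∇R‖²+ε²))^p` (default p = 4). ε's stated role is to
  separate noise from information; the weight enforces it on the force
  itself, so pixels whose gradients sit at the noise scale cannot drag
  the field.
* **Null-calibrated level gate.** The ε-regularised NGF strictly
  *rewards* edge sharpening: even for two identical images the functional
  can be lowered by ~0.5 % by compressing edge flanks toward the crest,
  at any ε (the gain comes from pixels with `‖∇I‖ ≈ ε`, a set that never
  empties). An optimizer that accepts every decrease therefore drifts by
  ~0.5 px on perfectly aligned inputs. Before iterating a level, the
  solver measures this "null gain" — the decrease one iteration achieves
  registering each image onto *itself* — and skips the level unless the
  real pair's first iteration gains more than `gate_factor` (default 2)
  times the smaller of the two null gains. Registering an image onto
  itself then returns exactly the initial field, while sub-pixel genuine
  misalignments still pass the gate at the level where they become
  visible.
* **Pre-smoothing.** The images that drive the similarity are smoothed
  with a Gaussian of `presmooth_sigma` (default 0.8 px) before the
  pyramid is built. Parametric maps are piecewise constant with
  single-pixel edges on which the spline gradient field is aliased;
  without pre-smoothing a 3 px shift of a T1 map was recovered with a
  3.5 px error, with it the error is below 0.1 px. The image that is
  finally warped never passes through the smoother.

**Known behaviour.** Frames of one MOLLI series share geometry but not
contrast; near a tissue null the magnitude operation creates V-shaped
edges whose position genuinely differs from the reference frame's edges.
The functional can reduce this cross-contrast mismatch by a sub-pixel
deformation, so motion correction of a perfectly still series returns
fields of up to ~1 px at such frames (tissue overlap is preserved to
Dice > 0.98). This is a property of the similarity model, not an
optimizer artefact, and it is bounded by the deliberately stiff
regularization.

**Defaults.** μ = 1, λ = 0 (zero Poisson ratio), α = 1. The absolute
scale of μ, λ, α is intensity-scale-dependent by construction; the
defaults suit images in an O(100–1000) intensity range, and the stiffness
is chosen conservatively — small, smooth deformations, local volume
changes within ~±20 % — because distorting a quantitative map is worse
than under-correcting it. The two-circle demonstration (a clean phantom
whose only difference *is* a 3 px boundary deformation) uses a looser
setting (α = 0.1, `max_step` 3 px, tolerance 0.02 px, no pre-smoothing)
to recover most of the prescribed volume change.

## T1 mapping

Pixel-wise Levenberg–Marquardt fit of `S(t) = A − B e^(−t/T1*)`
(initialised at `A = max S`, `B = A − min S`, `T1* = 1000 ms`; analytic
Jacobian; exponent clipped so trial steps cannot overflow), followed by
the Look-Locker correction `T1 = (B/A − 1) T1*`. Magnitude data first
passes polarity restoration: every candidate inversion index k (negate
the first k samples in TI order) is fitted and the smallest residual
wins; candidates must be physical (`A > 0`) and beat the incumbent by
more than float noise, so monotone curves keep k = 0. Pixels are masked
invalid when the fit fails or `T1*`/`T1` leaves (1, 5000) ms — a window
covering native and post-contrast myocardium and blood at 1.5–3 T. The
SD fitting-error map propagates the residual-scaled fit covariance
through the Look-Locker correction with the delta method; it is zero for
noiseless data and grows monotonically with noise.

## ECV pipeline

Stages: motion-correct both series onto their longest-TI frame → fit both
T1 maps → register the post-contrast map onto the native map → segment
blood (strictly `T1 > 1400 ms` inside the endocardial contour; native
blood at 3 T lies at 1600–2200 ms, myocardium near 1300 ms, so the
boundary choice is inconsequential but fixed) → compute
`ECV = ΔR1_myo/ΔR1_blood (1 − hct) × 100 %` per pixel with median blood
T1 per map → QA maps. The myocardial ROI is the epi–endo annulus eroded
2 px from both borders minus any exclusion polygons. ECV is stored
unclipped with an out-of-range QC flag and clipped to [0, 100] % for
display. A non-positive blood ΔR1 (post not shorter than native) is
rejected; hematocrit must be a fraction in (0, 1) for the pipeline
(`compute_ecv` itself also accepts the degenerate value 1, which gives a
zero map). Invalid (NaN) pixels are filled by normalized convolution
before a map drives registration, so failed background fits cannot punch
spurious edges into the similarity.

## QA maps

`LDF(x) = C(φ(x))` samples a binary checkerboard (default period 8 px)
analytically at the deformed positions; pure translations leave every
line straight. `LVC(x) = det(∇φ) − 1` uses central differences over the
3×3 neighbourhood (one-sided and flagged at the border): 0 means local
area preservation, positive expansion, negative compression; through-
plane motion is outside a 2D model. Both maps can be overlaid with an
isocontour of the native T1 map for anatomical orientation.

## Synthetic test bed

* **Scheme timing.** Second-based MOLLI schemes are parsed from labels
  like `5s(3s)3s`: images per look-locker period = ⌈duration/R–R⌉
  (exact ratios are not rounded up), recovery intervals = fewest whole
  beats covering the stated minimum, breath-hold = total beats × R–R.
  Inversion times start at the minimal TI delay (87.7 ms) and step by one
  R–R within a period; the same minimal delay is used for every period.
* **Phantom.** Concentric short-axis geometry (blood disc in a myocardial
  annulus, optional lesion sector) with per-tissue native/post T1 —
  myocardium 1280 → 597 ms, blood 1900 → 400 ms (the native blood value
  is validated against the 1600–2200 ms 3T range), background 350 →
  300 ms — and a textured equilibrium image (smooth seeded random field,
  ±10 %, inside tissue only) so registration has structure to lock onto.
  A helper inverts the ECV relation to build post-contrast values
  implying any target ECV.
* **Signal model.** `S(t) = M0 (1 − f e^(−t/T1*))` with `T1* = 0.8 T1`
  and `f = 1 + T1/T1*`, so the three-parameter fit plus Look-Locker
  correction reproduces the prescribed T1 exactly on clean data — the
  round trip is exact by construction, which keeps recovery tests sharp.
  A full Bloch simulation of the SSFP readout is intentionally out of
  scope.
* **Motion.** Per-frame global translations (Gaussian, σ = 2 px default)
  plus an optional smooth sinusoidal elastic component; the reference
  frame stays still by default. The generator returns the exact
  correction (inverse) field per frame. Noise is Gaussian (a fraction of
  the peak equilibrium signal); the magnitude operation is optional.
* **Two-circle pair.** Smooth-edged discs of equal size versus grown
  (12 → 15 px) and shrunk (12 → 9 px) counterparts, with sign masks on
  the reference-radius discs where the LVC must come out positive
  (expansion) and negative (compression).

What passing these tests does *not* show: behaviour under through-plane
motion, SSFP banding or off-resonance artefacts, Rician (rather than
Gaussian) noise at low SNR, arrhythmic R–R variation within a series, or
the contrast statistics of real myocardial pathology. The phantom's
texture is smoother than in-vivo speckle, which flatters registration
accuracy; the clinical claim supported here is directional (correction
reduces error), not a guarantee of sub-pixel accuracy on patient data.

## Problem sizes

The test suite runs registration accuracy at 128×128 (the in-plane
matrix order of a cropped short-axis acquisition), pixel-wise fitting and
pipeline tests on a 48–64 px phantom with the 8-image native scheme, and
the co-registration Monte-Carlo (20 random inter-series shifts) on 64 px
maps; these sizes keep the full suite at a few minutes on one core while
every contract is size-independent.
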