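# elastimap

Elastic motion correction and co-registration for cardiac MR T1 and
extracellular volume (ECV) mapping.

## The problem

Myocardial T1 mapping with MOLLI (modified Look-Locker inversion recovery)
acquires 8–14 single-shot images across one breath-hold, each at a
different inversion time, and fits a relaxation model per pixel.
Inconsistent breath-holding and beat-to-beat variation misalign the
frames, and the ECV map — which combines a native and a post-contrast T1
map acquired minutes apart — inherits a second, inter-scan misalignment.
Both corrupt the pixel-wise fits exactly where clinicians read them.

`elastimap` implements an automated two-stage correction for people
working on quantitative cardiac MR: every frame of a MOLLI series is
registered onto the longest-inversion-time frame (motion correction), and
the post-contrast T1 map is registered onto the native map
(co-registration), before the quantitative maps are computed.

## The method

Registration finds a displacement field `u` minimising

```
J[u] = D[u; R, T] + α S[u]
```

where the similarity is the **normalized gradient field** (NGF),

```
D = ½ ∫ 1 − ⟨n(R, x), n(T, x + u(x))⟩² dx,
n(I, x) = ∇I(x) / ‖∇I(x)‖_ε,      ‖g‖_ε = √(g₁² + g₂² + ε²),
```

and `S[u]` is the linear-elastic potential with Lamé parameters (μ, λ).
NGF compares edge *orientations* only — it is invariant to intensity
rescaling and to contrast polarity, which is what survives the drastic
contrast changes along an inversion-recovery series and between native
and post-contrast maps. `ε` is tied to each image's mean gradient
modulus, separating noise from structure. The Euler–Lagrange system is
discretised by finite differences with Neumann boundaries, solved by
conjugate gradients inside a coarse-to-fine pyramid.

Downstream, the pixel-wise three-parameter inversion-recovery model
`S(t) = A − B·exp(−t/T1*)` is fitted by Levenberg–Marquardt (with
polarity restoration for magnitude data), corrected for readout-driven
saturation via `T1 = (B/A − 1)·T1*`, and accompanied by an SD
fitting-error map (delta-method propagation of the fit covariance).
ECV follows `ECV = ΔR1_myo / ΔR1_blood · (1 − hematocrit)` with
`ΔR1 = 1/T1_post − 1/T1_pre`, the blood term taken from median blood-pool
T1 (segmented on the native map at T1 > 1400 ms inside the endocardial
contour). Deformation quality is assessed by a checkerboard (LDF) map and
the local volume change `LVC = det(∇φ) − 1`.

## Worked example

Simulate a short-axis phantom study (64×64, myocardium 1280 → 597 ms,
blood 1900 → 400 ms, 1 % noise, per-frame breathing motion of σ = 2 px and
an inter-series shift of (2.5, −2.0) px), then run the full pipeline:

```python
import numpy as np
from scipy.ndimage import binary_dilation, shift as ndshift
from elastimap import *

spec = PhantomSpec(shape=(64, 64), seed=3)
phantom = make_cardiac_phantom(spec)
timing = simulate_scheme_timing(SchemeSpec.from_string("5s(3s)3s", 60.0))
motion = MotionModel(translation_sigma_px=2.0)
native, _ = simulate_molli_series(phantom, timing.inversion_times_ms, "native",
                                  motion=motion, noise_sigma=0.01, seed=7)
post, _ = simulate_molli_series(phantom, timing.inversion_times_ms, "post",
                                motion=motion, noise_sigma=0.01, seed=8)
post = MolliSeries(np.stack([ndshift(f, (2.5, -2.0), order=1, mode="nearest")
                             for f in post.frames]),
                   post.inversion_times, magnitude=True)

theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
cy, cx = phantom.center
r_in, r_out = spec.blood_radius_frac * 64, spec.myo_outer_frac * 64
contours = ContourSet(
    epicardial=np.column_stack([cx + (r_out + 1.5) * np.cos(theta),
                                cy + (r_out + 1.5) * np.sin(theta)]),
    endocardial=np.column_stack([cx + (r_in + 0.5) * np.cos(theta),
                                 cy + (r_in + 0.5) * np.sin(theta)]),
)
fit_region = binary_dilation(contours.epi_mask((64, 64)), iterations=6)
result = run_pipeline(native, post, contours, hematocrit=0.42, fit_mask=fit_region)
```

Output (as printed by the summary lines of the example script):

```
median blood T1: 1895 -> 405 ms
myocardial T1 (native): 1266 +/- 59 ms
recovered inter-series shift over myocardium (px): 1.61, -1.55  [true 2.50, -2.00]
mean myocardial ECV with co-registration: 28.0 %
mean myocardial ECV without co-registration: 39.6 %
max |LVC| in myocardium: 0.172
```

The phantom's tissue values imply a true ECV of 26.3 %. Without
co-registration the shifted post-contrast map biases the estimate by
+13 percentage points; with it the error shrinks to under 2 points, and
the LVC map confirms the correction is small and smooth
(|LVC| ≤ ~0.2, i.e. ≤ 20 % local area change). The per-pixel T1 SD error
and red/green overlay maps in `result` are the quality-control views.

A CLI mirrors the stages (`elastimap simulate | moco | t1fit | coreg |
ecv | qa`); run `elastimap --help`.

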