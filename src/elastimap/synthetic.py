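"""Synthetic fixtures: scheme timing, cardiac phantom, MOLLI simulation.

Everything a desk test needs without clinical data:

* second-based MOLLI scheme timing (images per look-locker period, total
  beats, breath-hold duration) at a given heart rate;
* a short-axis cardiac phantom (blood pool disc, myocardial annulus,
  optional focal lesion) with per-tissue native and post-contrast T1;
* forward simulation of the inversion-recovery signal per frame, with
  breathing-like inter-frame motion, optional noise and magnitude
  operation, plus the ground-truth correction fields;
* the two-circle pair used to demonstrate the sign semantics of the local
  volume change map.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .registration import warp
from .t1map import MolliSeries

__all__ = [
    "SchemeSpec",
    "SchemeTiming",
    "simulate_scheme_timing",
    "PhantomSpec",
    "Phantom",
    "make_cardiac_phantom",
    "ecv_consistent_post_t1",
    "MotionModel",
    "simulate_molli_series",
    "make_two_circle_pair",
]

#: minimal inversion delay between the inversion pulse and the first
#: readout, ms (vendor sequence value for the second-based schemes)
TI_MIN_MS = 87.7


# ---------------------------------------------------------------------------
# Scheme timing


@dataclass
class SchemeSpec:
    """A second-based MOLLI scheme such as ``5s(3s)3s``.

    ``ll_durations`` are the minimum durations (s) of the look-locker
    acquisition periods; ``recovery_durations`` the minimum recovery
    intervals (s) between them (one fewer than the LL periods).
    """

    ll_durations: tuple[float, ...]
    recovery_durations: tuple[float, ...]
    heart_rate: float

    def __post_init__(self) -> None:
        if len(self.recovery_durations) != len(self.ll_durations) - 1:
            raise ValueError("need exactly one recovery interval between LL periods")
        if any(d <= 0 for d in self.ll_durations + self.recovery_durations):
            raise ValueError("durations must be positive")
        if not 20 < self.heart_rate < 250:
            raise ValueError("heart rate must lie in (20, 250) bpm")

    @classmethod
    def from_string(cls, scheme: str, heart_rate: float) -> "SchemeSpec":
        """Parse labels like ``"5s(3s)3s"`` or ``"4s(1s)3s(1s)2s"``."""
        tokens = re.findall(r"\(?(\d+(?:\.\d+)?)s\)?", scheme)
        if not tokens or scheme.count("(") != scheme.count(")"):
            raise ValueError(f"cannot parse scheme label {scheme!r}")
        values = [float(v) for v in tokens]
        in_paren = [m.startswith("(") for m in re.findall(r"\(?\d+(?:\.\d+)?s\)?", scheme)]
        ll = tuple(v for v, p in zip(values, in_paren) if not p)
        rec = tuple(v for v, p in zip(values, in_paren) if p)
        return cls(ll, rec, heart_rate)


@dataclass
class SchemeTiming:
    """Evaluated timing of a scheme at one heart rate."""

    images_per_period: tuple[int, ...]
    recovery_beats: tuple[int, ...]
    inversion_times_ms: np.ndarray
    total_beats: int
    scan_seconds: float
    rr_seconds: float


def _ceil_ratio(duration: float, rr: float) -> int:
    # smallest integer count of R-R intervals covering ``duration``; a ratio
    # that is a whole number within float tolerance is not rounded up
    return int(math.ceil(duration / rr - 1e-9))


def simulate_scheme_timing(spec: SchemeSpec, ti_min_ms: float = TI_MIN_MS) -> SchemeTiming:
    """Beat-counting rule for second-based MOLLI schemes.

    * images per look-locker period = ``ceil(duration / R-R)``;
    * recovery interval = fewest whole beats whose duration covers the
      stated minimum;
    * total scan (breath-hold) time = total beats x R-R.

    Inversion times within each LL period start at the minimal TI delay and
    increment by one R-R interval per acquired image (ECG-gated single-shot
    readouts on consecutive beats).
    """
    rr = 60.0 / spec.heart_rate
    images = tuple(_ceil_ratio(d, rr) for d in spec.ll_durations)
    recovery = tuple(_ceil_ratio(d, rr) for d in spec.recovery_durations)
    tis = []
    for n in images:
        tis.extend(ti_min_ms + np.arange(n) * rr * 1000.0)
    total_beats = sum(images) + sum(recovery)
    return SchemeTiming(
        images_per_period=images,
        recovery_beats=recovery,
        inversion_times_ms=np.asarray(tis),
        total_beats=total_beats,
        scan_seconds=total_beats * rr,
        rr_seconds=rr,
    )


# ---------------------------------------------------------------------------
# Cardiac phantom

#: per-tissue (native T1, post-contrast T1, equilibrium signal A); T1 in ms.
#: Myocardium and blood use representative patient values at 3 T; the
#: native blood value sits inside the published 1600-2200 ms range.
DEFAULT_TISSUES = {
    "background": (350.0, 300.0, 150.0),
    "myocardium": (1280.0, 597.0, 420.0),
    "blood": (1900.0, 400.0, 560.0),
    "lesion": (1450.0, 480.0, 430.0),
}

LABELS = {"background": 0, "myocardium": 1, "blood": 2, "lesion": 3}


@dataclass
class PhantomSpec:
    """Geometry and tissue properties of the short-axis phantom."""

    shape: tuple[int, int] = (128, 128)
    blood_radius_frac: float = 0.15
    myo_outer_frac: float = 0.30
    edge_width_px: float = 1.2
    tissues: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_TISSUES.items()})
    lesion: bool = False
    lesion_angle: tuple[float, float] = (0.0, 1.0)  # radians, sector in the annulus
    texture_amplitude: float = 0.10  # fractional, within tissue only
    texture_scale_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.blood_radius_frac < self.myo_outer_frac:
            raise ValueError("annulus geometry requires blood radius < outer radius")
        for name, (t1n, t1p, a) in self.tissues.items():
            if t1n <= 0 or t1p <= 0 or a <= 0:
                raise ValueError(f"tissue {name!r} needs positive T1s and signal")
        blood_native = self.tissues["blood"][0]
        if not 1600.0 <= blood_native <= 2200.0:
            raise ValueError("native blood T1 must lie in the 1600-2200 ms 3T range")


@dataclass
class Phantom:
    """Label image plus ground-truth maps generated from a PhantomSpec."""

    labels: np.ndarray  # integer tissue labels (LABELS)
    t1_native: np.ndarray  # ms
    t1_post: np.ndarray  # ms
    m0: np.ndarray  # equilibrium signal, textured
    spec: PhantomSpec

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    @property
    def center(self) -> tuple[float, float]:
        return (self.labels.shape[0] / 2.0, self.labels.shape[1] / 2.0)


def make_cardiac_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Concentric short-axis phantom: blood disc inside a myocardial annulus.

    Ground-truth T1 maps are constant per tissue; the equilibrium signal
    carries a smooth seeded texture inside the tissue so registration has
    structure to lock onto.
    """
    spec = spec or PhantomSpec()
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h / 2.0, w / 2.0
    r = np.hypot(yy - cy, xx - cx)
    r_blood = spec.blood_radius_frac * min(h, w)
    r_outer = spec.myo_outer_frac * min(h, w)

    labels = np.zeros((h, w), dtype=int)
    labels[r < r_outer] = LABELS["myocardium"]
    labels[r < r_blood] = LABELS["blood"]
    if spec.lesion:
        theta = np.arctan2(yy - cy, xx - cx)
        a0, a1 = spec.lesion_angle
        sector = (theta >= a0) & (theta <= a1)
        labels[(labels == LABELS["myocardium"]) & sector] = LABELS["lesion"]
    if not np.any(labels == LABELS["myocardium"]):
        raise ValueError("phantom geometry leaves an empty myocardial annulus")

    t1n = np.empty((h, w))
    t1p = np.empty((h, w))
    m0 = np.empty((h, w))
    for name, lab in LABELS.items():
        if name not in spec.tissues:
            continue
        native, post, a = spec.tissues[name]
        sel = labels == lab
        t1n[sel] = native
        t1p[sel] = post
        m0[sel] = a

    # smooth the proton-density image at tissue borders so edges are not
    # aliased, and add seeded texture inside tissue
    soft = gaussian_filter(m0, spec.edge_width_px)
    rng = np.random.default_rng(spec.seed)
    tex = gaussian_filter(rng.standard_normal((h, w)), spec.texture_scale_px)
    tex /= max(np.abs(tex).max(), 1e-12)
    tissue = labels != LABELS["background"]
    m0 = soft * (1.0 + spec.texture_amplitude * tex * tissue)
    return Phantom(labels=labels, t1_native=t1n, t1_post=t1p, m0=m0, spec=spec)


def ecv_consistent_post_t1(
    t1_native_myo: float,
    target_ecv_pct: float,
    hematocrit: float,
    blood_t1_pair: tuple[float, float],
) -> float:
    """Invert the ECV relation for the post-contrast myocardial T1.

    Given a target ECV (in %), the hematocrit and the blood T1 pair
    (native, post), returns the myocardial post-contrast T1 (ms) such that

        ECV = dR1_myo / dR1_blood * (1 - hct),   dR1 = 1/T1_post - 1/T1_pre.
    """
    b_pre, b_post = blood_t1_pair
    dr1_blood = 1.0 / b_post - 1.0 / b_pre
    dr1_myo = (target_ecv_pct / 100.0) / (1.0 - hematocrit) * dr1_blood
    return 1.0 / (dr1_myo + 1.0 / t1_native_myo)


# ---------------------------------------------------------------------------
# MOLLI simulation


@dataclass
class MotionModel:
    """Breathing-like inter-frame motion: a random global translation per
    frame plus an optional smooth sinusoidal elastic component.

    The reference (last) frame stays still by default, matching the
    convention that every other frame is corrected onto it.
    """

    translation_sigma_px: float = 2.0
    elastic_amplitude_px: float = 0.0
    elastic_wavelength_px: float = 48.0
    move_reference: bool = False


def _invert_field(u: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Fixed-point inverse of phi = id + u (exact for pure translations)."""
    v = -u.copy()
    for _ in range(n_iter):
        v = -np.stack([warp(u[..., 0], v), warp(u[..., 1], v)], axis=-1)
    return v


def simulate_molli_series(
    phantom: Phantom,
    inversion_times_ms,
    contrast: str = "native",
    motion: MotionModel | None = None,
    noise_sigma: float = 0.0,
    magnitude: bool = True,
    seed: int = 0,
    t1star_factor: float = 0.8,
    scheme: str | None = None,
    heart_rate: float | None = None,
) -> tuple[MolliSeries, list[np.ndarray]]:
    """Forward-simulate a MOLLI acquisition of the phantom.

    The per-pixel signal is ``S(t) = M0 (1 - f exp(-t/T1*))`` with
    ``T1* = t1star_factor * T1`` and inversion factor ``f = 1 + T1/T1*``,
    so the three-parameter fit plus Look-Locker correction reproduces the
    ground-truth T1 exactly on noiseless, motion-free data.

    Returns the series (frames in acquisition order, which is ascending TI
    per look-locker period) and, per frame, the ground-truth *correction*
    field: warping the simulated frame by it restores the still frame.

    Parameters
    ----------
    noise_sigma : float
        Gaussian noise SD as a fraction of the maximum equilibrium signal.
    magnitude : bool
        Apply the magnitude operation (sign of the recovery lost).
    """
    if contrast not in ("native", "post"):
        raise ValueError("contrast must be 'native' or 'post'")
    t1 = phantom.t1_native if contrast == "native" else phantom.t1_post
    t1star = t1star_factor * t1
    inv_factor = 1.0 + t1 / t1star  # B/A per pixel
    tis = np.asarray(inversion_times_ms, dtype=float)
    rng = np.random.default_rng(seed)
    motion = motion or MotionModel()

    h, w = phantom.labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    frames = []
    true_fields = []
    ref_idx = int(np.argmax(tis))  # motion-correction reference frame
    for i, ti in enumerate(tis):
        still = phantom.m0 * (1.0 - inv_factor * np.exp(-ti / t1star))
        is_ref = i == ref_idx
        if is_ref and not motion.move_reference:
            u_gen = np.zeros((h, w, 2))
        else:
            shift = rng.normal(0.0, motion.translation_sigma_px, size=2)
            u_gen = np.broadcast_to(shift, (h, w, 2)).copy()
            if motion.elastic_amplitude_px > 0:
                lam = motion.elastic_wavelength_px
                phase = rng.uniform(0, 2 * np.pi, size=2)
                u_gen[..., 0] += motion.elastic_amplitude_px * np.sin(
                    2 * np.pi * yy / lam + phase[0]
                )
                u_gen[..., 1] += motion.elastic_amplitude_px * np.sin(
                    2 * np.pi * xx / lam + phase[1]
                )
        moved = warp(still, u_gen, order=1) if np.any(u_gen) else still.copy()
        if noise_sigma > 0:
            moved = moved + rng.normal(0.0, noise_sigma * phantom.m0.max(), moved.shape)
        if magnitude:
            moved = np.abs(moved)
        frames.append(moved)
        true_fields.append(_invert_field(u_gen) if np.any(u_gen) else np.zeros((h, w, 2)))

    series = MolliSeries(
        np.stack(frames),
        tis,
        magnitude=magnitude,
        scheme=scheme,
        heart_rate=heart_rate,
        spacing=(1.0, 1.0),
    )
    return series, true_fields


# ---------------------------------------------------------------------------
# Two-circle simulation


def make_two_circle_pair(
    shape: tuple[int, int] = (96, 96),
    centers=((48.0, 28.0), (48.0, 68.0)),
    radii_reference: tuple[float, float] = (12.0, 12.0),
    radii_target: tuple[float, float] = (15.0, 9.0),
    edge_width: float = 1.5,
    background: float = 0.1,
    foreground: float = 1.0,
):
    """Reference image with two equal circles vs a target whose circles
    grew and shrank; used to demonstrate expansion/compression signs of the
    local volume change map.

    Returns ``(reference, target, sign_masks)`` where ``sign_masks`` maps
    ``"expand"``/``"contract"`` to boolean masks over the circle whose
    target radius is larger/smaller than in the reference.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def disc_image(radii):
        img = np.full((h, w), background)
        for (cy, cx), rad in zip(centers, radii):
            r = np.hypot(yy - cy, xx - cx)
            img += (foreground - background) * 0.5 * (1 - np.tanh((r - rad) / edge_width))
        return img

    max_r = [max(a, b) for a, b in zip(radii_reference, radii_target)]
    (c0, c1) = centers
    if np.hypot(c0[0] - c1[0], c0[1] - c1[1]) <= max_r[0] + max_r[1] + 2 * edge_width:
        raise ValueError("circles overlap")
    for (cy, cx), rad in zip(centers, max_r):
        if not (rad < cy < h - rad and rad < cx < w - rad):
            raise ValueError("circle leaves the grid")

    ref = disc_image(radii_reference)
    target = disc_image(radii_target)
    # sign masks live on the reference grid (where the LVC of the recovered
    # field is evaluated): the reference-radius disc of each circle
    sign_masks = {}
    for (cy, cx), r_ref, r_tgt in zip(centers, radii_reference, radii_target):
        mask = np.hypot(yy - cy, xx - cx) < r_ref
        if r_tgt > r_ref:
            sign_masks["expand"] = mask
        elif r_tgt < r_ref:
            sign_masks["contract"] = mask
    return ref, target, sign_masks
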