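"""Pixel-wise inversion-recovery T1 estimation for MOLLI series.

The longitudinal recovery sampled at inversion times ``t`` follows the
three-parameter model

    S(t) = A - B * exp(-t / T1*)

fitted per pixel by Levenberg-Marquardt.  The apparent (Look-Locker
shortened) ``T1*`` is corrected for the readout-driven saturation by

    T1 = (B/A - 1) * T1*.

Magnitude (SSFP) data loses the sign of the recovery curve; the polarity is
restored per pixel by trying every candidate inversion index (negate the
first ``k`` samples in inversion-time order) and keeping the sign pattern
whose fit has the smallest residual.

The per-pixel T1 uncertainty ("SD fitting-error map", in ms) propagates the
Levenberg-Marquardt parameter covariance through the Look-Locker correction
with the delta method.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "MolliSeries",
    "IRFit",
    "T1FitResult",
    "restore_polarity",
    "fit_ir_three_param",
    "look_locker_correct",
    "fit_t1_map",
]

# reported T1* / T1 outside this window (ms) mark a pixel invalid; covers
# the native and post-contrast myocardium/blood ranges at 1.5 and 3 T
T1_VALID_RANGE = (1.0, 5000.0)


@dataclass
class MolliSeries:
    """An ordered MOLLI image series with per-frame inversion times.

    Parameters
    ----------
    frames : ndarray, shape (n, H, W)
        Single-shot images, one per inversion time.
    inversion_times : ndarray, shape (n,)
        Inversion times in ms, strictly positive.
    magnitude : bool
        True when intensities are magnitude (sign of the recovery lost).
    scheme : str, optional
        Acquisition scheme label, e.g. ``"5s(3s)3s"``.
    heart_rate : float, optional
        Heart rate in bpm during the acquisition.
    spacing : (float, float)
        Pixel size in mm (metadata only).
    """

    frames: np.ndarray
    inversion_times: np.ndarray
    magnitude: bool = True
    scheme: str | None = None
    heart_rate: float | None = None
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.inversion_times = np.asarray(self.inversion_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.shape[0] < 4:
            raise ValueError("a MOLLI series needs at least 4 frames")
        if self.inversion_times.shape != (self.frames.shape[0],):
            raise ValueError("one inversion time per frame required")
        if not np.all(np.isfinite(self.inversion_times)) or np.any(
            self.inversion_times <= 0
        ):
            raise ValueError("inversion times must be finite and positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def sorted_by_ti(self) -> "MolliSeries":
        """Return a copy with frames in ascending inversion-time order."""
        order = np.argsort(self.inversion_times, kind="stable")
        return MolliSeries(
            self.frames[order],
            self.inversion_times[order],
            magnitude=self.magnitude,
            scheme=self.scheme,
            heart_rate=self.heart_rate,
            spacing=self.spacing,
        )


class IRFit(NamedTuple):
    """Result of one three-parameter inversion-recovery fit."""

    a: float
    b: float
    t1star: float
    residual: float  # root-mean-square residual
    cov: np.ndarray | None  # 3x3 covariance of (A, B, T1*)
    valid: bool


def _ir_model(t, a, b, t1star):
    # clip the exponent so LM trial steps through tiny T1* cannot overflow
    return a - b * np.exp(np.clip(-t / t1star, -700.0, 700.0))


def _ir_jac(t, a, b, t1star):
    e = np.exp(np.clip(-t / t1star, -700.0, 700.0))
    return np.stack([np.ones_like(t), -e, -b * t * e / t1star**2], axis=-1)


def fit_ir_three_param(signal, times) -> IRFit:
    """Levenberg-Marquardt fit of ``S(t) = A - B exp(-t/T1*)``.

    Returns an invalid fit (``valid=False``) for degenerate input (fewer
    than 4 samples, a constant signal, non-convergence) or when the fitted
    ``T1*`` falls outside the physiologically meaningful window.
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(times, dtype=float)
    bad = IRFit(np.nan, np.nan, np.nan, np.inf, None, False)
    if s.size < 4 or s.shape != t.shape or not np.all(np.isfinite(s)):
        return bad
    if np.ptp(s) < 1e-12 * max(1.0, float(np.abs(s).max())):
        return bad  # constant signal: T1* unidentifiable
    a0 = float(s.max())
    b0 = float(a0 - s.min())
    if b0 <= 0:
        b0 = max(abs(a0), 1.0)
    try:
        popt, pcov = curve_fit(
            _ir_model,
            t,
            s,
            p0=(a0, b0, 1000.0),
            jac=_ir_jac,
            method="lm",
            maxfev=400,
        )
    except RuntimeError:
        return bad
    a, b, t1star = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((_ir_model(t, *popt) - s) ** 2)))
    if not np.all(np.isfinite(popt)) or not (T1_VALID_RANGE[0] < t1star < T1_VALID_RANGE[1]):
        return IRFit(a, b, t1star, resid, None, False)
    return IRFit(a, b, t1star, resid, pcov, True)


def restore_polarity(signal, times) -> tuple[np.ndarray, int]:
    """Restore the sign of a magnitude inversion-recovery curve.

    Tries every candidate inversion index ``k`` (negate the first ``k``
    samples, inversion-time-ascending order assumed), fits each candidate,
    and returns the signed curve with the smallest fit residual together
    with the chosen index.  Ties prefer the smallest ``k``, so a curve that
    never crosses zero is returned unchanged.
    """
    signed, k, _ = _best_polarity_fit(signal, times)
    return signed, k


def _best_polarity_fit(signal, times) -> tuple[np.ndarray, int, IRFit]:
    s = np.asarray(signal, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("inversion times must be ascending for polarity restoration")
    best = (s.copy(), 0, fit_ir_three_param(s, t))
    best_res = best[2].residual if best[2].valid and best[2].a > 0 else np.inf
    for k in range(1, s.size + 1):
        cand = s.copy()
        cand[:k] = -cand[:k]
        fit = fit_ir_three_param(cand, t)
        # A is the equilibrium signal and must be positive; require a
        # strictly better residual so float noise cannot flip the sign of
        # an already-consistent curve
        if fit.valid and fit.a > 0 and fit.residual < best_res * (1.0 - 1e-9):
            best = (cand, k, fit)
            best_res = fit.residual
    return best


def look_locker_correct(a, b, t1star):
    """Look-Locker saturation correction ``T1 = (B/A - 1) * T1*``."""
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (np.asarray(b, dtype=float) / a - 1.0) * np.asarray(t1star, dtype=float)
    return np.where(a == 0, np.nan, t1)


def _t1_sd_delta(a, b, t1star, cov) -> float:
    # delta-method propagation of the fit covariance through the
    # Look-Locker correction T1 = (B/A - 1) T1*
    g = np.array([-b * t1star / a**2, t1star / a, b / a - 1.0])
    var = float(g @ cov @ g)
    return float(np.sqrt(var)) if var >= 0 else np.nan


@dataclass
class T1FitResult:
    """Per-pixel maps produced by :func:`fit_t1_map` (all in ms where
    applicable); ``fit_mask`` marks pixels with a valid fit."""

    a_map: np.ndarray
    b_map: np.ndarray
    t1star_map: np.ndarray
    t1_map: np.ndarray
    sd_error_map: np.ndarray
    residual_map: np.ndarray
    fit_mask: np.ndarray
    polarity_map: np.ndarray = field(default=None)  # type: ignore[assignment]


def fit_t1_map(series: MolliSeries, mask=None) -> T1FitResult:
    """Pixel-wise T1 mapping of a (motion-corrected) MOLLI series.

    For magnitude series the polarity is restored per pixel before the
    final fit.  Pixels with an invalid fit, or with a corrected T1 outside
    ``T1_VALID_RANGE``, are masked out (NaN in the maps).

    Parameters
    ----------
    series : MolliSeries
    mask : ndarray of bool, optional
        Restrict fitting to these pixels (default: the whole image).
    """
    srt = series.sorted_by_ti()
    t = srt.inversion_times
    h, w = srt.shape
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (h, w):
            raise ValueError("mask shape does not match the series frames")

    maps = {
        name: np.full((h, w), np.nan)
        for name in ("a", "b", "t1star", "t1", "sd", "resid")
    }
    polarity = np.full((h, w), -1, dtype=int)
    fit_mask = np.zeros((h, w), dtype=bool)

    signals = srt.frames.reshape(srt.n_frames, -1)
    for idx in np.flatnonzero(mask.ravel()):
        s = signals[:, idx]
        if srt.magnitude:
            _, k, fit = _best_polarity_fit(s, t)
        else:
            k, fit = 0, fit_ir_three_param(s, t)
        if not fit.valid:
            continue
        t1 = float(look_locker_correct(fit.a, fit.b, fit.t1star))
        if not (T1_VALID_RANGE[0] < t1 < T1_VALID_RANGE[1]):
            continue
        i, j = divmod(idx, w)
        maps["a"][i, j] = fit.a
        maps["b"][i, j] = fit.b
        maps["t1star"][i, j] = fit.t1star
        maps["t1"][i, j] = t1
        maps["sd"][i, j] = (
            _t1_sd_delta(fit.a, fit.b, fit.t1star, fit.cov) if fit.cov is not None else np.nan
        )
        maps["resid"][i, j] = fit.residual
        polarity[i, j] = k
        fit_mask[i, j] = True

    return T1FitResult(
        a_map=maps["a"],
        b_map=maps["b"],
        t1star_map=maps["t1star"],
        t1_map=maps["t1"],
        sd_error_map=maps["sd"],
        residual_map=maps["resid"],
        fit_mask=fit_mask,
        polarity_map=polarity,
    )
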