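"""Blur estimation and blur normalization of channel energy.

Blurring a dot leaves its contrast energy intact but moves that energy to
lower spatial frequencies, so a fixed high-frequency channel reads less
energy from a blurrier stimulus.  To restore blur invariance the model
observer (i) estimates stimulus blur directly from the image and (ii) divides
the channel energy by a calibrated curve exp(a s^2 + b s + c), the
second-order polynomial relation between blur s (in arcmin) and log energy.

Blur is measured MIRAGE-style: the second spatial derivative of a profile
through an isolated dot has a central zero-bounded region whose flanking zero
crossings sit at +/- s for a Gaussian of standard deviation s, so the
estimate is half the crossing separation (the convention fixed analytically:
d^2/dx^2 exp(-x^2 / 2 s^2) vanishes at x = +/- s).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .filters import Kernel, channel_energy
from .stimuli import (PIXEL_PITCH_ARCMIN, DotPattern, StimulusImage,
                      build_dot_pattern, dot_amplitude, regular_polygon,
                      render_centred)


class BlurEstimationError(RuntimeError):
    """Raised when no usable zero crossings are found around a dot."""


class CalibrationError(ValueError):
    """Raised for a singular or under-determined energy/blur calibration."""


@dataclass
class BlurEstimate:
    """Robust (median) per-stimulus blur estimate with per-dot detail."""

    s_hat: float                    # arcmin
    per_dot: list[float] = field(default_factory=list)  # arcmin
    method: str = "mirage"

    def __post_init__(self) -> None:
        if not self.s_hat > 0:
            raise BlurEstimationError(f"blur estimate must be positive, got {self.s_hat}")


def _profile_crossings(profile: np.ndarray, center: float,
                       presmooth: float) -> float | None:
    """Separation of the two second-derivative zero crossings flanking the
    centre of a 1D profile, by linear interpolation; None if not found."""
    p = gaussian_filter1d(profile.astype(float), presmooth) if presmooth > 0 else profile
    d2 = np.convolve(p, [1.0, -2.0, 1.0], mode="same")
    c = int(round(center))
    if not 1 <= c <= len(p) - 2:
        return None
    sign = math.copysign(1.0, p[c]) if p[c] != 0 else 1.0
    d2 = d2 * sign  # central zero-bounded region now negative
    if d2[c] >= 0:
        return None

    def cross(direction: int) -> float | None:
        i = c
        while 1 <= i + direction <= len(p) - 2:
            j = i + direction
            if d2[i] < 0 <= d2[j]:
                # linear interpolation between samples i and j
                t = d2[i] / (d2[i] - d2[j])
                return i + direction * t
            i = j
        return None

    left = cross(-1)
    right = cross(+1)
    if left is None or right is None:
        return None
    return right - left


def mirage_blur(image: StimulusImage | np.ndarray, dot_center: tuple[float, float],
                presmooth: float = 0.5) -> float:
    """Blur (px) of an isolated dot at ``dot_center`` from the separation of
    second-derivative zero crossings, averaged over the horizontal and
    vertical profiles through the centre.

    The profiles are pre-smoothed with a 0.5 px Gaussian to stabilize the
    crossings; the smoothing variance is subtracted from the estimate.
    """
    v = image.values if isinstance(image, StimulusImage) else np.asarray(image)
    x, y = dot_center
    row = v[int(round(y)), :]
    col = v[:, int(round(x))]
    seps = []
    for prof, cen in ((row, x), (col, y)):
        sep = _profile_crossings(prof, cen, presmooth)
        if sep is not None and sep > 0:
            seps.append(sep)
    if not seps:
        raise BlurEstimationError(
            f"no second-derivative zero crossings around ({x:.1f}, {y:.1f})")
    s2 = (np.mean(seps) / 2.0) ** 2 - presmooth ** 2
    if s2 <= 0:
        raise BlurEstimationError("crossing separation below smoothing scale")
    return float(math.sqrt(s2))


def estimate_pattern_blur(image: StimulusImage, pattern: DotPattern,
                          n_sample_dots: int = 5,
                          presmooth: float = 0.5) -> BlurEstimate:
    """Per-stimulus blur: the model observer isolates the ``n_sample_dots``
    dots with the most distant nearest neighbours, measures each with
    :func:`mirage_blur` and takes the median (reported in arcmin)."""
    nnd = pattern.nearest_neighbour_distances()
    order = np.argsort(nnd)[::-1][:max(1, n_sample_dots)]
    pitch = image.pixel_pitch
    per_dot = []
    for i in order:
        d = pattern.dots[i]
        try:
            per_dot.append(mirage_blur(image, (d.x, d.y), presmooth) * pitch)
        except BlurEstimationError:
            continue
    if not per_dot:
        raise BlurEstimationError("blur estimation failed on every sampled dot")
    return BlurEstimate(float(np.median(per_dot)), per_dot)


@dataclass
class EnergyBlurPoly:
    """Calibrated relation log(E) = a s^2 + b s + c with s in arcmin."""

    a: float
    b: float
    c: float
    calibration_range: tuple[float, float]
    channel_id: str = ""
    resid_rms: float = 0.0

    def log_energy(self, s_arcmin: float | np.ndarray) -> float | np.ndarray:
        s = np.asarray(s_arcmin, dtype=float)
        out = self.a * s * s + self.b * s + self.c
        return float(out) if out.ndim == 0 else out


def fit_energy_poly(s_arcmin: np.ndarray, log_e: np.ndarray,
                    channel_id: str = "") -> EnergyBlurPoly:
    """Least-squares quadratic fit of log energy against blur (arcmin)."""
    s = np.asarray(s_arcmin, dtype=float)
    y = np.asarray(log_e, dtype=float)
    if len(np.unique(np.round(s, 9))) < 3:
        raise CalibrationError("need at least 3 distinct blur levels")
    coef = np.polyfit(s, y, 2)
    resid = y - np.polyval(coef, s)
    poly = EnergyBlurPoly(float(coef[0]), float(coef[1]), float(coef[2]),
                          (float(s.min()), float(s.max())), channel_id,
                          float(np.sqrt(np.mean(resid ** 2))))
    if poly.resid_rms >= 0.05:
        warnings.warn(f"energy/blur calibration residual RMS {poly.resid_rms:.3f} "
                      ">= 0.05; quadratic may be a poor description", stacklevel=2)
    return poly


def calibrate_energy_poly(channel: Kernel, blur_levels_arcmin,
                          rng: np.random.Generator,
                          n_reps: int = 20,
                          n_dots: int = 1,
                          pixel_pitch: float = PIXEL_PITCH_ARCMIN,
                          ) -> EnergyBlurPoly:
    """Empirical blur/energy calibration on single-dot stimuli.

    For each blur level, renders ``n_reps`` stimuli of ``n_dots`` dots at
    random sub-pixel offsets, measures the channel energy and the MIRAGE blur
    of each, and fits log(mean E) against the mean estimated blur (arcmin).
    Fitting against the *estimated* blur absorbs any small bias of the
    estimator, since normalization later plugs in the same estimate.
    """
    levels = np.asarray(list(blur_levels_arcmin), dtype=float)
    if len(levels) < 5:
        raise CalibrationError("calibration needs at least 5 blur levels")
    if np.any(levels <= 0):
        raise CalibrationError("blur levels must be positive")
    s_hat_mean = []
    log_e_mean = []
    for s_arc in levels:
        s_px = s_arc / pixel_pitch
        es, shs = [], []
        for _ in range(n_reps):
            # fixed dot count and contrast; square region scaled to the count
            side = max(12.0 * s_px, 20.0) * math.sqrt(max(n_dots, 1))
            poly = regular_polygon(4, side) + rng.uniform(-0.5, 0.5, size=2)
            pat = build_dot_pattern(poly, n_dots, s_px, rng,
                                    exclusion=10.0 * s_px,
                                    polarities=np.ones(n_dots))
            img, pat = render_centred(pat)
            es.append(channel_energy(img, channel).E)
            shs.append(estimate_pattern_blur(img, pat, n_sample_dots=n_dots).s_hat)
        s_hat_mean.append(np.mean(shs))
        log_e_mean.append(math.log(np.mean(es)))
    return fit_energy_poly(np.array(s_hat_mean), np.array(log_e_mean),
                           channel.channel_id)


def normalize_energy(E, s_hat_arcmin: float, poly: EnergyBlurPoly) -> float:
    """Divide a channel energy by the calibrated curve at the estimated blur,
    rendering it (approximately) blur-invariant.  Estimates outside the
    calibration range +/- 20% are extrapolated with a warning."""
    lo, hi = poly.calibration_range
    if not (0.8 * lo <= s_hat_arcmin <= 1.2 * hi):
        warnings.warn(
            f"blur estimate {s_hat_arcmin:.2f} arcmin outside calibration "
            f"range [{lo:.2f}, {hi:.2f}] +/- 20%; extrapolating", stacklevel=2)
    e = float(E)
    return e / math.exp(poly.log_energy(s_hat_arcmin))
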