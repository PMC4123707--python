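"""Filter bank and contrast-energy measurement.

The model's numerosity proxy is contrast energy: the sum of squared responses
of a band-pass filter over the stimulus.  Channels are isotropic
Laplacian-of-Gaussian (LoG) kernels — "high" spatial frequency at sigma = 2 px
and "low" at sigma = 8 px — plus oriented second-derivative-of-Gaussian
kernels, half-wave rectified on/off energies, and a contrast-sensitivity-
function (CSF) weighted energy computed in the Fourier domain.

All space-domain kernels are zero-DC (blind to mean luminance) and unit L2
norm so that energies are comparable across scales; convolution uses 'valid'
boundary handling so padding never contributes to the energy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .stimuli import StimulusImage


class FilterError(ValueError):
    """Raised for invalid kernel parameters or image/kernel size mismatch."""


@dataclass
class Kernel:
    """A discrete filter: 2D tap grid, underlying Gaussian scale, kind tag."""

    values: np.ndarray
    scale: float
    kind: str
    orientation: float | None = None

    @property
    def channel_id(self) -> str:
        if self.orientation is None:
            return f"{self.kind}-{self.scale:g}"
        return f"{self.kind}-{self.scale:g}-{self.orientation:g}deg"


@dataclass
class ChannelEnergy:
    """Sum of squared filter responses over the valid analysis region."""

    E: float
    channel_id: str
    region: str = "valid"

    def __post_init__(self) -> None:
        if self.E < 0:
            raise FilterError("energy cannot be negative")

    def __float__(self) -> float:
        return self.E


def _finalize(values: np.ndarray, scale: float, kind: str,
              orientation: float | None = None) -> Kernel:
    values = values - values.mean()          # zero DC
    values = values / np.sqrt((values ** 2).sum())  # unit L2
    return Kernel(values, scale, kind, orientation)


def make_log_kernel(scale: float, support_factor: float = 4.0) -> Kernel:
    """Centre-positive Laplacian of Gaussian (-nabla^2 G) of scale ``scale``,
    zero-DC corrected and unit-L2 normalized.

    A white (positive-contrast) blob drives a positive central response.
    """
    if not scale > 0:
        raise FilterError("scale must be positive")
    if support_factor < 3.0:
        raise FilterError("support must be at least 3 sigma per side")
    r = int(math.ceil(support_factor * scale))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    rr = x * x + y * y
    s2 = scale * scale
    log = (rr - 2 * s2) / (s2 * s2) * np.exp(-rr / (2 * s2))
    return _finalize(-log, scale, "log")


def make_oriented_kernel(scale: float, orientation: float,
                         aspect: float = 2.0,
                         support_factor: float = 4.0) -> Kernel:
    """Even-symmetric orientation-tuned kernel: second derivative of an
    elongated Gaussian.  ``orientation`` is the preferred bar orientation in
    degrees (0 = vertical bars); rotating the input by 90 deg maps one
    channel's response onto the orthogonal channel's.
    """
    if not scale > 0:
        raise FilterError("scale must be positive")
    if support_factor < 3.0:
        raise FilterError("support must be at least 3 sigma per side")
    r = int(math.ceil(support_factor * scale * max(aspect, 1.0)))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    th = math.radians(orientation)
    # u: across-bar axis (second derivative), v: along-bar axis (elongated);
    # same carrier convention as the Gabor elements in `stimuli`
    u = -x * math.sin(th) + y * math.cos(th)
    v = x * math.cos(th) + y * math.sin(th)
    s2 = scale * scale
    sv2 = (aspect * scale) ** 2
    env = np.exp(-u * u / (2 * s2) - v * v / (2 * sv2))
    d2 = (u * u / s2 - 1.0) / s2
    return _finalize(-d2 * env, scale, "oriented", orientation)


def make_dog_kernel(center_scale: float, surround_ratio: float = 1.6,
                    support_factor: float = 4.0) -> Kernel:
    """Balanced difference-of-Gaussians (centre:surround = 1:surround_ratio)."""
    if not center_scale > 0:
        raise FilterError("center_scale must be positive")
    ss = center_scale * surround_ratio
    r = int(math.ceil(support_factor * ss))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    rr = x * x + y * y
    gc = np.exp(-rr / (2 * center_scale ** 2))
    gs = np.exp(-rr / (2 * ss ** 2))
    return _finalize(gc / gc.sum() - gs / gs.sum(), center_scale, "dog")


def _values(image: StimulusImage | np.ndarray) -> np.ndarray:
    return image.values if isinstance(image, StimulusImage) else np.asarray(image)


def filter_response(image: StimulusImage | np.ndarray, kernel: Kernel) -> np.ndarray:
    """'valid'-mode linear filter response (no padding contribution)."""
    v = _values(image)
    kh, kw = kernel.values.shape
    if v.shape[0] < kh or v.shape[1] < kw:
        raise FilterError(
            f"image {v.shape} smaller than kernel support {kernel.values.shape}")
    return fftconvolve(v, kernel.values, mode="valid")


def channel_energy(image: StimulusImage | np.ndarray, kernel: Kernel) -> ChannelEnergy:
    """Contrast energy: sum of squared filter responses over the valid region."""
    resp = filter_response(image, kernel)
    return ChannelEnergy(float(np.sum(resp * resp)), kernel.channel_id)


def halfwave_energies(image: StimulusImage | np.ndarray,
                      kernel: Kernel) -> tuple[ChannelEnergy, ChannelEnergy]:
    """Half-wave rectified on/off energies.  E_on + E_off equals the full
    channel energy; with the centre-on LoG convention white dots load E_on."""
    resp = filter_response(image, kernel)
    on = np.clip(resp, 0.0, None)
    off = np.clip(-resp, 0.0, None)
    return (ChannelEnergy(float(np.sum(on * on)), kernel.channel_id + "-on"),
            ChannelEnergy(float(np.sum(off * off)), kernel.channel_id + "-off"))


@dataclass
class CSFParams:
    """Band-pass contrast-sensitivity gain g(f) = (f/f0) exp(1 - f/f0),
    normalized to peak 1 at ``peak_cpd`` cycles/deg."""

    peak_cpd: float = 3.0

    def gain(self, f_cpd: np.ndarray) -> np.ndarray:
        f = np.asarray(f_cpd, dtype=float)
        return (f / self.peak_cpd) * np.exp(1.0 - f / self.peak_cpd)


def csf_energy(image: StimulusImage, params: CSFParams | None = None) -> ChannelEnergy:
    """Energy after weighting the stimulus spectrum by a human contrast
    sensitivity function (Parseval-equivalent to filtering then summing
    squares).  Requires pixel-pitch metadata to convert px^-1 to cycles/deg."""
    if params is None:
        params = CSFParams()
    if not isinstance(image, StimulusImage) or not image.pixel_pitch or image.pixel_pitch <= 0:
        raise FilterError("csf_energy needs a StimulusImage with pixel_pitch")
    v = image.values
    h, w = v.shape
    fy = np.fft.fftfreq(h)[:, None]  # cycles per px
    fx = np.fft.fftfreq(w)[None, :]
    f_cpd = np.hypot(fy, fx) * 60.0 / image.pixel_pitch
    gain = params.gain(f_cpd)
    gain[0, 0] = 0.0
    spec = np.fft.fft2(v) * gain
    e = float(np.sum(np.abs(spec) ** 2) / (h * w))  # Parseval
    return ChannelEnergy(e, f"csf-{params.peak_cpd:g}cpd", region="full")
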