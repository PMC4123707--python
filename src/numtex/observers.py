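"""Trial-by-trial model observers.

Decisions are made per trial, never on averages, so the model observer has
exactly the information a human observer gets:

* :class:`EnergyObserver` — "more energy = more numerous": compares channel
  energy of test and standard, optionally after logarithmic contrast
  compression and/or division by the calibrated blur/energy curve at the
  stimulus's own MIRAGE blur estimate.
* :class:`RatioObserver` — two-channel energy-ratio classifier for mixed
  textures, comparing each trial's log ratio to the running mean ratio of the
  stimuli seen so far.
* :func:`ideal_aperture_pc` — exact ideal counting observer for the aperture
  experiment: counts visible dots without error, limited only by
  hypergeometric sampling of which dots fall inside the aperture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import hypergeom, norm

from .blur_norm import EnergyBlurPoly, estimate_pattern_blur, normalize_energy
from .filters import (Kernel, channel_energy, filter_response,
                      halfwave_energies, make_log_kernel, make_oriented_kernel)
from .stimuli import DotPattern, MixedTexture, StimulusImage, TrialPair


class ObserverConfigError(ValueError):
    """Raised for inconsistent observer configuration."""


class DegenerateStimulusError(RuntimeError):
    """Raised when a channel needed for a ratio decision has zero energy."""


def compress_contrast(image: StimulusImage, c0: float) -> StimulusImage:
    """Logarithmic contrast compression (contrast gain control):
    c -> sign(c) * log(1 + |c|/c0) / log(1 + 1/c0).

    Odd, monotone in |c|, fixes 0 -> 0 and +/-1 -> +/-1; smaller ``c0``
    compresses the contrast range harder.
    """
    if not c0 > 0:
        raise ObserverConfigError("compression constant c0 must be positive")
    v = image.values
    out = np.sign(v) * np.log1p(np.abs(v) / c0) / math.log1p(1.0 / c0)
    return StimulusImage(out, image.pixel_pitch)


@dataclass
class EnergyDecision:
    """Bookkeeping for one energy-observer decision."""

    choice: str  # 'standard' | 'test'
    E_std: float
    E_test: float
    E_std_used: float
    E_test_used: float
    s_hat_std: float | None = None
    s_hat_test: float | None = None


class EnergyObserver:
    """Single-channel energy-difference observer.

    Parameters
    ----------
    kernel:
        The analysis channel (e.g. ``make_log_kernel(2)``).
    normalize_blur:
        Divide each stimulus's energy by ``exp(poly(s_hat))`` where ``s_hat``
        is that stimulus's own MIRAGE blur estimate; requires ``calibration``.
    compress:
        Apply :func:`compress_contrast` with constant ``c0`` before filtering.
    """

    def __init__(self, kernel: Kernel, normalize_blur: bool = False,
                 calibration: EnergyBlurPoly | None = None,
                 compress: bool = False, c0: float = 0.05,
                 n_blur_dots: int = 5):
        if normalize_blur and calibration is None:
            raise ObserverConfigError(
                "normalize_blur requires a calibrated EnergyBlurPoly")
        if c0 <= 0:
            raise ObserverConfigError("c0 must be positive")
        self.kernel = kernel
        self.normalize_blur = normalize_blur
        self.calibration = calibration
        self.compress = compress
        self.c0 = c0
        self.n_blur_dots = n_blur_dots

    def evaluate(self, image: StimulusImage, pattern: DotPattern) -> tuple[float, float, float | None]:
        """(raw energy, decision energy, blur estimate in arcmin) for one stimulus."""
        raw = channel_energy(image, self.kernel).E
        work = image
        if self.compress:
            work = compress_contrast(image, self.c0)
            used = channel_energy(work, self.kernel).E
        else:
            used = raw
        s_hat = None
        if self.normalize_blur:
            s_hat = estimate_pattern_blur(image, pattern, self.n_blur_dots).s_hat
            used = normalize_energy(used, s_hat, self.calibration)
        return raw, used, s_hat

    def decide(self, pair: TrialPair, rng: np.random.Generator) -> EnergyDecision:
        """Choose the stimulus with the greater (normalized) energy as the
        more numerous; exact ties are broken at random."""
        e_std_raw, e_std, sh_s = self.evaluate(pair.standard_image, pair.standard_pattern)
        e_test_raw, e_test, sh_t = self.evaluate(pair.test_image, pair.test_pattern)
        if e_test > e_std:
            choice = "test"
        elif e_test < e_std:
            choice = "standard"
        else:
            choice = "test" if rng.random() < 0.5 else "standard"
        return EnergyDecision(choice, e_std_raw, e_test_raw, e_std, e_test, sh_s, sh_t)


@dataclass
class RatioReference:
    """Running mean of the log channel-energy ratio over past stimuli."""

    running_mean_log_ratio: float = 0.0
    n_seen: int = 0

    def update(self, r: float) -> None:
        self.n_seen += 1
        self.running_mean_log_ratio += (r - self.running_mean_log_ratio) / self.n_seen


class RatioObserver:
    """Two-channel energy-ratio classifier for mixed two-class textures.

    Channel pairs per texture kind: polarity -> half-wave off/on of the
    high-SF LoG; frequency and size -> LoG scales 2 and 8 px (two octaves
    apart); contrast -> one channel thresholded at two response levels;
    orientation -> oriented channels 90 deg apart.  The trial's log energy
    ratio r = log(E_a / E_b) is compared with the mean ratio of stimuli seen
    before that trial (first trial: fair coin), then the reference is updated.
    """

    def __init__(self, kind: str, base_scale: float = 2.0,
                 low_scale: float = 8.0, contrast_thresholds: tuple[float, float] | None = None):
        self.kind = kind
        self.reference = RatioReference()
        if kind == "polarity":
            self._kernel = make_log_kernel(base_scale)
        elif kind in ("frequency", "size"):
            self._kernels = (make_log_kernel(base_scale), make_log_kernel(low_scale))
        elif kind == "contrast":
            self._kernel = make_log_kernel(base_scale)
            self._thresholds = contrast_thresholds
        elif kind == "orientation":
            self._kernels = (make_oriented_kernel(base_scale, 0.0),
                             make_oriented_kernel(base_scale, 90.0))
        else:
            raise ObserverConfigError(
                f"no ratio channels defined for texture kind {self.kind!r}")

    def energies(self, image: StimulusImage) -> tuple[float, float]:
        """(E_a, E_b): energies of the class-a-loaded and class-b-loaded channels."""
        if self.kind == "polarity":
            e_on, e_off = halfwave_energies(image, self._kernel)
            return e_off.E, e_on.E       # class a = black dots -> off channel
        if self.kind in ("frequency", "size"):
            ka, kb = self._kernels
            return channel_energy(image, ka).E, channel_energy(image, kb).E
        if self.kind == "orientation":
            ka, kb = self._kernels
            return channel_energy(image, ka).E, channel_energy(image, kb).E
        # contrast: one channel, response magnitude split at two thresholds.
        resp = np.abs(filter_response(image, self._kernel))
        if self._thresholds is None:
            peak = resp.max()
            # 50% and 150% of the expected low-contrast-class peak (half the
            # high class's): thresholds at 0.25 and 0.75 of the observed peak.
            t1, t2 = 0.25 * peak, 0.75 * peak
        else:
            t1, t2 = self._thresholds
        e_hi = float(np.sum(resp[resp > t2] ** 2))          # high-contrast class (a)
        e_lo = float(np.sum(resp[(resp > t1) & (resp <= t2)] ** 2))
        return e_hi, e_lo

    def decide(self, texture: MixedTexture, rng: np.random.Generator) -> str:
        """Pick the class judged more numerous ('a' or 'b') and update the
        running reference with this trial's log ratio."""
        e_a, e_b = self.energies(texture.image)
        if e_a <= 0 or e_b <= 0:
            raise DegenerateStimulusError(
                f"zero channel energy for kind {self.kind!r} (E_a={e_a}, E_b={e_b})")
        r = math.log(e_a / e_b)
        if self.reference.n_seen == 0:
            choice = "a" if rng.random() < 0.5 else "b"
        else:
            choice = "a" if r > self.reference.running_mean_log_ratio else "b"
        self.reference.update(r)
        return choice


# ---------------------------------------------------------------------------
# ideal sampling observer (aperture experiment)
# ---------------------------------------------------------------------------

def ideal_aperture_pc(N: int, B: int, n: int) -> float:
    """Exact probability correct of an ideal observer that counts the ``n``
    visible dots without error when ``B`` of the ``N`` total dots are black.

    Visibility is sampling without replacement (hypergeometric); the observer
    reports the majority colour among visible dots, guessing on visible ties.
    """
    if not 0 <= n <= N:
        raise ValueError("need 0 <= n <= N")
    if not 0 <= B <= N:
        raise ValueError("need 0 <= B <= N")
    if 2 * B == N:
        raise ValueError("B = N/2 leaves the correct answer undefined")
    if n == 0:
        return 0.5
    rv = hypergeom(N, B, n)
    k = np.arange(max(0, n - (N - B)), min(n, B) + 1)
    pmf = rv.pmf(k)
    black_majority_true = B > N - B
    kk = k if black_majority_true else n - k
    win = pmf[2 * kk > n].sum()
    tie = pmf[2 * kk == n].sum()
    return float(win + 0.5 * tie)


def _fit_sigma_to_curve(w: np.ndarray, pc: np.ndarray,
                        bounds: tuple[float, float] = (1e-3, 10.0)) -> float:
    """Least-squares cumulative-Gaussian slope for a percent-correct curve
    P(correct | W) = Phi(W / sigma)."""

    def loss(log_s: float) -> float:
        p = norm.cdf(w / math.exp(log_s))
        return float(np.sum((p - pc) ** 2))

    res = minimize_scalar(loss, bounds=(math.log(bounds[0]), math.log(bounds[1])),
                          method="bounded")
    return float(math.exp(res.x))


def ideal_aperture_weber(N: int, n: int, w_grid) -> float:
    """Weber fraction (%) of the ideal sampling observer at aperture size
    ``n`` visible dots, at the same 84%-correct criterion used throughout
    (the sigma of a cumulative Gaussian fitted to percent correct vs W).

    The black count per trial is B = round(N/2 * (1 + W)).
    """
    ws, pcs = [], []
    for W in w_grid:
        B = int(math.floor(N / 2 * (1 + W) + 0.5))
        if 2 * B == N:
            continue
        ws.append(W)
        pcs.append(ideal_aperture_pc(N, B, n))
    return 100.0 * _fit_sigma_to_curve(np.array(ws), np.array(pcs))
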