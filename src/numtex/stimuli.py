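"""Synthetic stimulus generators for numerosity-discrimination experiments.

Everything a model observer ever sees is built here: blurred dot patterns
scattered in random polygons (the classic "which field has more dots" 2AFC
displays), thresholded filtered-noise blob textures, mixed two-class textures,
and aperture-masked displays.  Images are dimensionless contrast maps
(background 0, clipped to [-1, 1]) with a pixel pitch of 1.25 arcmin/px.

Dots are rendered analytically as two-dimensional Gaussians

    c(x, y) = A(s) * exp(-((x - m_x)^2 + (y - m_y)^2) / (2 s^2)),

with amplitude A(s) = 0.4 * (2 / s), i.e. a peak contrast of 0.4 at the
reference blur s = 2 px.  Under this law the contrast energy of a dot
(A^2 * pi * s^2) is independent of its blur, while peak amplitude falls with
blur — the property that makes blur a pure spatial-frequency manipulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon as _ShapelyPolygon

PIXEL_PITCH_ARCMIN = 1.25
REFERENCE_BLUR_PX = 2.0
REFERENCE_CONTRAST = 0.4
#: canvas padding; covers the 3*s dot margin plus the half-support of the
#: largest (sigma = 8 px) analysis kernel so dot responses fall in the valid
#: region of a 'valid'-mode convolution.
DEFAULT_CANVAS_PAD = 33.0


class StimulusError(ValueError):
    """Base class for stimulus-construction failures."""


class PlacementError(StimulusError):
    """Raised when dot placement under the exclusion constraint is infeasible."""


class RenderError(StimulusError):
    """Raised when a dot does not fit on the requested canvas."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DotSpec:
    """A single Gaussian dot: centre (x, y) in px, blur s in px, signed amplitude.

    The amplitude sign encodes polarity (positive = white, negative = black).
    """

    x: float
    y: float
    s: float
    amplitude: float

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise StimulusError(f"dot blur must be positive, got s={self.s}")
        if not abs(self.amplitude) <= 1.0:
            raise StimulusError(
                f"|amplitude| must be <= 1, got {self.amplitude}")


@dataclass
class DotPattern:
    """A set of dots plus the bounding polygon they were scattered in."""

    dots: list[DotSpec]
    polygon: np.ndarray  # (k, 2) vertex array, px

    @property
    def n_dots(self) -> int:
        return len(self.dots)

    @property
    def area(self) -> float:
        return polygon_area(self.polygon)

    @property
    def s_max(self) -> float:
        return max((d.s for d in self.dots), default=0.0)

    def centers(self) -> np.ndarray:
        if not self.dots:
            return np.empty((0, 2))
        return np.array([[d.x, d.y] for d in self.dots])

    def translated(self, dx: float, dy: float) -> "DotPattern":
        dots = [replace(d, x=d.x + dx, y=d.y + dy) for d in self.dots]
        return DotPattern(dots, self.polygon + np.array([dx, dy]))

    def nearest_neighbour_distances(self) -> np.ndarray:
        """Euclidean distance from each dot centre to its nearest neighbour."""
        pts = self.centers()
        if len(pts) < 2:
            return np.full(len(pts), np.inf)
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)


@dataclass
class StimulusImage:
    """2D contrast map (background 0, range [-1, 1]) with pixel-pitch metadata."""

    values: np.ndarray
    pixel_pitch: float = PIXEL_PITCH_ARCMIN  # arcmin per px

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialPair:
    """One 2AFC trial: a 64-dot standard and a 64 +/- 64W dot test stimulus."""

    standard_image: StimulusImage
    standard_pattern: DotPattern
    test_image: StimulusImage
    test_pattern: DotPattern
    W: float
    sign: int
    n_test: int
    condition: str
    blur_std: float
    blur_test: float
    contrast_std: float = 1.0
    contrast_test: float = 1.0


@dataclass
class GenConfig:
    """Generator configuration for the dot-number 2AFC experiments.

    ``condition`` selects how the test area behaves: ``'density'`` keeps the
    test area at the standard's (density varies with number) while ``'size'``
    scales the test area with dot number (density held constant).
    ``blur_mode`` is ``'equal'`` (all dots s=2), ``'unequal'`` (one blur per
    stimulus, drawn uniformly from blur_range) or ``'per-element'`` (each dot
    blurred independently).  ``vary_area_scale``/``vary_contrast`` add the
    "kitchen sink" manipulations: overall area of test and standard scaled
    independently in [1, 2] x standard, and overall contrast scaled
    independently in [0.13, 1].
    """

    n_standard: int = 64
    area_standard: float = 50_000.0
    w_grid: tuple = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    condition: str = "density"
    blur_mode: str = "equal"
    blur_equal: float = 2.0
    blur_range: tuple = (2.0, 6.0)
    vary_area_scale: bool = False
    area_scale_range: tuple = (1.0, 2.0)
    vary_contrast: bool = False
    contrast_range: tuple = (0.13, 1.0)
    test_always_more: bool = False
    pad: float = DEFAULT_CANVAS_PAD
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("density", "size"):
            raise StimulusError(f"unknown condition {self.condition!r}")
        if self.blur_mode not in ("equal", "unequal", "per-element"):
            raise StimulusError(f"unknown blur_mode {self.blur_mode!r}")
        for name in ("blur_range", "area_scale_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise StimulusError(f"{name} must be non-degenerate, got {lo, hi}")
        if self.n_standard <= 0 or self.area_standard <= 0:
            raise StimulusError("n_standard and area_standard must be positive")
        if self.vary_contrast and not (0 < self.contrast_range[0] <= 1):
            raise StimulusError("contrast_range must lie in (0, 1]")

    @property
    def condition_tag(self) -> str:
        if self.vary_area_scale or self.blur_mode == "per-element":
            return "kitchen-sink"
        return f"{self.condition}-{self.blur_mode}-blur"


def kitchen_sink_config(vary_contrast: bool = False, **kw) -> GenConfig:
    """The "kitchen sink" design: per-element blur, independent 1-2x area
    scaling of test and standard, test always more numerous, optional
    independent contrast scaling over [0.13, 1]."""
    return GenConfig(blur_mode="per-element", vary_area_scale=True,
                     vary_contrast=vary_contrast, test_always_more=True, **kw)


# ---------------------------------------------------------------------------
# polygons and dot placement
# ---------------------------------------------------------------------------

def polygon_area(vertices: np.ndarray) -> float:
    return float(_ShapelyPolygon(np.asarray(vertices)).area)


def regular_polygon(n_vertices: int, radius: float,
                    center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Regular n-gon inscribed in a circle (the degenerate, randomness-free
    counterpart of :func:`make_polygon`)."""
    ang = 2 * np.pi * np.arange(n_vertices) / n_vertices
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def make_polygon(area_target: float, rng: np.random.Generator,
                 n_vertices: int | None = None,
                 radius_range: tuple[float, float] = (0.5, 1.0)) -> np.ndarray:
    """Random simple ("notional") polygon with shoelace area = ``area_target``.

    A star-shaped polygon is built from 5-12 vertices at sorted random angles
    and random radii, then rescaled isotropically to the target area; star
    shape about the origin guarantees simplicity.
    """
    if not area_target > 0:
        raise StimulusError(f"area_target must be positive, got {area_target}")
    k = int(n_vertices) if n_vertices is not None else int(rng.integers(5, 13))
    if k < 3:
        raise StimulusError("polygon needs at least 3 vertices")
    while True:
        ang = np.sort(rng.uniform(0.0, 2 * np.pi, size=k))
        if np.min(np.diff(ang)) > 1e-3:  # avoid near-duplicate vertices
            break
    rad = rng.uniform(*radius_range, size=k)
    verts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    verts *= math.sqrt(area_target / polygon_area(verts))
    return verts


def place_dots(polygon: np.ndarray, n: int, exclusion: float,
               rng: np.random.Generator,
               max_attempts: int | None = None) -> np.ndarray:
    """Scatter ``n`` points uniformly inside ``polygon`` with a minimum
    pairwise centre distance (rejection sampling).

    Raises :class:`PlacementError` when the packing is infeasible within the
    attempt budget.
    """
    if n < 0:
        raise StimulusError("n must be >= 0")
    if exclusion < 0:
        raise StimulusError("exclusion must be >= 0")
    if n == 0:
        return np.empty((0, 2))
    poly = _ShapelyPolygon(np.asarray(polygon))
    minx, miny, maxx, maxy = poly.bounds
    budget = max_attempts if max_attempts is not None else 500 * n + 5000
    pts = np.empty((n, 2))
    got = 0
    attempts = 0
    excl2 = exclusion * exclusion
    chunk = 128
    while got < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} dots (placed {got}) in polygon of area "
                f"{poly.area:.0f} px^2 with exclusion {exclusion:.2f} px "
                f"after {attempts} attempts")
        m = min(chunk, budget - attempts)
        attempts += m
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        inside = contains_xy(poly, xs, ys)
        for x, y in zip(xs[inside], ys[inside]):
            if got and excl2 > 0:
                d2 = (pts[:got, 0] - x) ** 2 + (pts[:got, 1] - y) ** 2
                if d2.min() < excl2:
                    continue
            pts[got] = (x, y)
            got += 1
            if got == n:
                break
    return pts


def default_exclusion(area: float, n: int, s_max: float) -> float:
    """Exclusion distance between dot centres: 4 * s_max, capped at 60% of the
    mean inter-dot spacing so that placement stays feasible in the dense
    (high-count, high-blur) conditions."""
    if n <= 0:
        return 4.0 * s_max
    return min(4.0 * s_max, 0.6 * math.sqrt(area / n))


def dot_amplitude(s: float, polarity: float = 1.0) -> float:
    """Peak contrast of a dot of blur ``s``: 0.4 at the reference blur s=2,
    scaling as 1/s so contrast energy is blur-invariant."""
    return polarity * REFERENCE_CONTRAST * (REFERENCE_BLUR_PX / s)


def build_dot_pattern(polygon: np.ndarray, n: int,
                      blur: float | Sequence[float],
                      rng: np.random.Generator,
                      exclusion: float | None = None,
                      polarities: Sequence[float] | None = None) -> DotPattern:
    """Place ``n`` dots in ``polygon`` and assign blur and polarity.

    ``blur`` may be a scalar (all dots alike) or a length-n sequence.
    ``polarities`` defaults to independent fair coin flips (+1 white, -1 black).
    """
    s = np.broadcast_to(np.asarray(blur, dtype=float), (n,))
    if np.any(s <= 0):
        raise StimulusError("all blurs must be positive")
    area = polygon_area(polygon)
    if exclusion is None:
        exclusion = default_exclusion(area, n, float(s.max()) if n else 0.0)
    pts = place_dots(polygon, n, exclusion, rng)
    if polarities is None:
        pol = rng.choice([-1.0, 1.0], size=n)
    else:
        pol = np.asarray(polarities, dtype=float)
        if pol.shape != (n,):
            raise StimulusError("polarities must have length n")
    dots = [DotSpec(x=float(p[0]), y=float(p[1]), s=float(si),
                    amplitude=dot_amplitude(float(si), float(pi)))
            for p, si, pi in zip(pts, s, pol)]
    return DotPattern(dots, np.asarray(polygon, dtype=float))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def centre_pattern(pattern: DotPattern,
                   pad: float = DEFAULT_CANVAS_PAD) -> tuple[DotPattern, tuple[int, int]]:
    """Translate a pattern onto its own canvas (bounding box of polygon and
    dot supports plus ``pad``) and return (translated pattern, canvas shape)."""
    xs = [pattern.polygon[:, 0]]
    ys = [pattern.polygon[:, 1]]
    for d in pattern.dots:
        xs.append(np.array([d.x - 4 * d.s, d.x + 4 * d.s]))
        ys.append(np.array([d.y - 4 * d.s, d.y + 4 * d.s]))
    ax = np.concatenate(xs)
    ay = np.concatenate(ys)
    dx = pad - ax.min()
    dy = pad - ay.min()
    width = int(math.ceil(ax.max() + dx + pad)) + 1
    height = int(math.ceil(ay.max() + dy + pad)) + 1
    return pattern.translated(dx, dy), (height, width)


def render_pattern(pattern: DotPattern, shape: tuple[int, int],
                   contrast_scale: float = 1.0,
                   pixel_pitch: float = PIXEL_PITCH_ARCMIN) -> StimulusImage:
    """Render a dot pattern analytically onto a zero-background canvas.

    Each dot contributes ``amplitude * contrast_scale *
    exp(-((x-m_x)^2+(y-m_y)^2)/(2 s^2))``; contributions sum and the result is
    clipped to [-1, 1].  Every dot must fit with at least a 3s margin.
    """
    h, w = shape
    img = np.zeros((h, w))
    for i, d in enumerate(pattern.dots):
        if (d.x - 3 * d.s < 0 or d.x + 3 * d.s > w - 1
                or d.y - 3 * d.s < 0 or d.y + 3 * d.s > h - 1):
            raise RenderError(
                f"dot {i} at ({d.x:.1f}, {d.y:.1f}) with s={d.s:.2f} does not "
                f"fit a {w}x{h} canvas with a 3s margin")
        r = int(math.ceil(4 * d.s))
        x0 = max(int(math.floor(d.x)) - r, 0)
        x1 = min(int(math.ceil(d.x)) + r, w - 1)
        y0 = max(int(math.floor(d.y)) - r, 0)
        y1 = min(int(math.ceil(d.y)) + r, h - 1)
        gx = np.exp(-((np.arange(x0, x1 + 1) - d.x) ** 2) / (2 * d.s ** 2))
        gy = np.exp(-((np.arange(y0, y1 + 1) - d.y) ** 2) / (2 * d.s ** 2))
        img[y0:y1 + 1, x0:x1 + 1] += (d.amplitude * contrast_scale) * np.outer(gy, gx)
    np.clip(img, -1.0, 1.0, out=img)
    return StimulusImage(img, pixel_pitch=pixel_pitch)


def render_centred(pattern: DotPattern, contrast_scale: float = 1.0,
                   pad: float = DEFAULT_CANVAS_PAD) -> tuple[StimulusImage, DotPattern]:
    """Convenience: centre a pattern on its own canvas and render it."""
    pat, shape = centre_pattern(pattern, pad)
    return render_pattern(pat, shape, contrast_scale), pat


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# trial-pair generation
# ---------------------------------------------------------------------------

def gen_trial_pair(config: GenConfig, W: float, sign: int,
                   rng: np.random.Generator) -> TrialPair:
    """Synthesize one 2AFC trial: a 64-dot standard and a 64 +/- 64W dot test.

    The test has ``round(64 (1 + sign*W))`` dots; its area follows the
    density/size condition rule (or independent random scaling in the kitchen
    sink design), and blurs/contrasts follow ``config.blur_mode`` and the
    contrast flags.
    """
    if not any(abs(W - g) < 1e-9 for g in config.w_grid):
        raise StimulusError(f"W={W} is not on the configured grid")
    if sign not in (-1, 1):
        raise StimulusError("sign must be +1 or -1")
    if config.test_always_more and sign < 0:
        raise StimulusError("this design requires the test to be more numerous")
    n_std = config.n_standard
    offset = _round_half_away(n_std * W)
    n_test = n_std + sign * offset
    if n_test <= 0:
        raise StimulusError(f"test count {n_test} is not positive")

    a0 = config.area_standard
    if config.vary_area_scale:
        area_std = a0 * rng.uniform(*config.area_scale_range)
        area_test = a0 * rng.uniform(*config.area_scale_range)
    else:
        area_std = a0
        area_test = a0 if config.condition == "density" else a0 * n_test / n_std

    lo, hi = config.blur_range
    if config.blur_mode == "equal":
        s_std: float | np.ndarray = config.blur_equal
        s_test: float | np.ndarray = config.blur_equal
    elif config.blur_mode == "unequal":
        s_std = float(rng.uniform(lo, hi))
        s_test = float(rng.uniform(lo, hi))
    else:  # per-element
        s_std = rng.uniform(lo, hi, size=n_std)
        s_test = rng.uniform(lo, hi, size=n_test)

    if config.vary_contrast:
        c_std = float(rng.uniform(*config.contrast_range))
        c_test = float(rng.uniform(*config.contrast_range))
    else:
        c_std = c_test = 1.0

    pat_std = build_dot_pattern(make_polygon(area_std, rng), n_std, s_std, rng)
    pat_test = build_dot_pattern(make_polygon(area_test, rng), n_test, s_test, rng)
    img_std, pat_std = render_centred(pat_std, c_std, config.pad)
    img_test, pat_test = render_centred(pat_test, c_test, config.pad)

    return TrialPair(
        standard_image=img_std, standard_pattern=pat_std,
        test_image=img_test, test_pattern=pat_test,
        W=W, sign=sign, n_test=n_test, condition=config.condition_tag,
        blur_std=float(np.mean(s_std)), blur_test=float(np.mean(s_test)),
        contrast_std=c_std, contrast_test=c_test)


# ---------------------------------------------------------------------------
# filtered-noise blob textures
# ---------------------------------------------------------------------------

def _dog_kernel_values(center_scale: float, surround_ratio: float = 1.6) -> np.ndarray:
    """Balanced (zero-DC) difference-of-Gaussians with unit-volume lobes."""
    ss = center_scale * surround_ratio
    r = int(math.ceil(4 * ss))
    y, x = np.mgrid[-r:r + 1, -r:r + 1]
    rr = x * x + y * y
    gc = np.exp(-rr / (2 * center_scale ** 2))
    gs = np.exp(-rr / (2 * ss ** 2))
    k = gc / gc.sum() - gs / gs.sum()
    return k - k.mean()


def gen_noise_blob_stimulus(center_scale: float, size: int,
                            rng: np.random.Generator,
                            surround_ratio: float = 1.6,
                            noise_contrast: float = 3.0,
                            noise: np.ndarray | None = None,
                            ) -> tuple[StimulusImage, StimulusImage, int]:
    """Blob texture: white pixel noise blurred with a difference-of-Gaussians
    filter, then thresholded at 1 s.d. to split it into discrete blobs.

    Returns (raw image, thresholded image, blob count).  Pixels within one
    standard deviation of the mean are set to the mean; the blob count is the
    number of 8-connected components of the surviving pixels.  The input
    noise has a fixed contrast, so increasing the filter scale genuinely
    removes contrast energy from the texture (blur is not renormalized away).
    """
    from scipy import ndimage
    from scipy.signal import fftconvolve

    if not center_scale > 0:
        raise StimulusError("center_scale must be positive")
    if size < 16:
        raise StimulusError("size too small")
    if noise is None:
        noise = noise_contrast * rng.standard_normal((size, size))
    raw = fftconvolve(noise, _dog_kernel_values(center_scale, surround_ratio),
                      mode="same")
    np.clip(raw, -1.0, 1.0, out=raw)
    mean = raw.mean()
    sd = raw.std()
    if sd == 0:
        mask = np.zeros_like(raw, dtype=bool)
    else:
        mask = np.abs(raw - mean) >= sd
    thresholded = np.where(mask, raw, mean)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    _, n_blobs = ndimage.label(mask, structure=structure)
    return (StimulusImage(raw), StimulusImage(thresholded), int(n_blobs))


# ---------------------------------------------------------------------------
# mixed two-class textures
# ---------------------------------------------------------------------------

MIXED_KINDS = ("polarity", "frequency", "contrast", "phase", "orientation", "size")


def _add_gaussian(img: np.ndarray, x: float, y: float, s: float, amp: float) -> None:
    r = int(math.ceil(4 * s))
    x0, x1 = int(x) - r, int(x) + r
    y0, y1 = int(y) - r, int(y) + r
    gx = np.exp(-((np.arange(x0, x1 + 1) - x) ** 2) / (2 * s * s))
    gy = np.exp(-((np.arange(y0, y1 + 1) - y) ** 2) / (2 * s * s))
    img[y0:y1 + 1, x0:x1 + 1] += amp * np.outer(gy, gx)


def _add_dog(img: np.ndarray, x: float, y: float, s: float, amp: float) -> None:
    ss = 1.6 * s
    r = int(math.ceil(4 * ss))
    xs = np.arange(int(x) - r, int(x) + r + 1) - x
    ys = np.arange(int(y) - r, int(y) + r + 1) - y
    rr = ys[:, None] ** 2 + xs[None, :] ** 2
    patch = np.exp(-rr / (2 * s * s)) - (s / ss) ** 2 * np.exp(-rr / (2 * ss * ss))
    img[int(y) - r:int(y) + r + 1, int(x) - r:int(x) + r + 1] += amp * patch


def _add_gabor(img: np.ndarray, x: float, y: float, sigma: float, freq: float,
               ori_deg: float, phase_deg: float, amp: float) -> None:
    r = int(math.ceil(4 * sigma))
    xs = np.arange(int(x) - r, int(x) + r + 1) - x
    ys = np.arange(int(y) - r, int(y) + r + 1) - y
    X = xs[None, :]
    Y = ys[:, None]
    th = math.radians(ori_deg)
    # carrier varies along the direction orthogonal to the bar orientation
    u = -X * math.sin(th) + Y * math.cos(th)
    env = np.exp(-(X * X + Y * Y) / (2 * sigma * sigma))
    carrier = np.cos(2 * np.pi * freq * u + math.radians(phase_deg))
    img[int(y) - r:int(y) + r + 1, int(x) - r:int(x) + r + 1] += amp * env * carrier


@dataclass
class MixedTexture:
    image: StimulusImage
    kind: str
    n_a: int
    n_b: int
    elements: list[dict] = field(default_factory=list)


def draw_mixed_total(rng: np.random.Generator, base: int = 64,
                     jitter_max: int = 21) -> int:
    """Total element count 64 + x with x uniform on 0..21 (defeats any
    single-channel total-count strategy)."""
    return base + int(rng.integers(0, jitter_max + 1))


def gen_mixed_texture(kind: str, n_a: int, n_b: int,
                      rng: np.random.Generator,
                      base_scale: float = 2.0,
                      base_contrast: float = 0.4,
                      pad: float = DEFAULT_CANVAS_PAD,
                      area_per_element: float = 50_000.0 / 64) -> MixedTexture:
    """One texture of two randomly interleaved element classes differing only
    in the named attribute: contrast polarity, spatial frequency (x2),
    contrast (x2), phase (90 deg), orientation (90 deg) or size (x2)."""
    if kind not in MIXED_KINDS:
        raise StimulusError(f"unknown mixed-texture kind {kind!r}")
    if n_a < 0 or n_b < 0 or n_a + n_b == 0:
        raise StimulusError("need non-negative class counts with n_a+n_b > 0")
    total = n_a + n_b
    area = area_per_element * total
    footprint = base_scale * (2.0 if kind in ("frequency", "size") else 1.0)
    if kind in ("orientation", "phase"):
        footprint = 1.5 * base_scale  # gabor envelope
    polygon = make_polygon(area, rng)
    excl = default_exclusion(area, total, footprint)
    pts = place_dots(polygon, total, excl, rng)
    labels = np.array(["a"] * n_a + ["b"] * n_b)
    rng.shuffle(labels)

    # canvas
    r_support = 4 * 1.6 * footprint + 2
    minx, miny = pts.min(axis=0) - r_support if total else (0, 0)
    maxx, maxy = pts.max(axis=0) + r_support
    dx, dy = pad - minx, pad - miny
    w = int(math.ceil(maxx + dx + pad)) + 1
    h = int(math.ceil(maxy + dy + pad)) + 1
    img = np.zeros((h, w))

    gabor_sigma = 1.5 * base_scale
    gabor_freq = 1.0 / (4.0 * base_scale)
    elements = []
    for (x, y), lab in zip(pts + np.array([dx, dy]), labels):
        is_a = lab == "a"
        if kind == "polarity":
            amp = -base_contrast if is_a else base_contrast  # class a = black
            _add_gaussian(img, x, y, base_scale, amp)
        elif kind == "size":
            s = base_scale if is_a else 2 * base_scale
            pol = float(rng.choice([-1.0, 1.0]))
            _add_gaussian(img, x, y, s, pol * base_contrast)
        elif kind == "frequency":
            s = base_scale if is_a else 2 * base_scale  # class a = high SF
            _add_dog(img, x, y, s, base_contrast)
        elif kind == "contrast":
            amp = base_contrast if is_a else base_contrast / 2
            pol = float(rng.choice([-1.0, 1.0]))
            _add_gaussian(img, x, y, base_scale, pol * amp)
        elif kind == "orientation":
            ori = 0.0 if is_a else 90.0  # class a = vertical bars
            _add_gabor(img, x, y, gabor_sigma, gabor_freq, ori, 0.0, base_contrast)
        else:  # phase
            ph = 0.0 if is_a else 90.0
            _add_gabor(img, x, y, gabor_sigma, gabor_freq, 0.0, ph, base_contrast)
        elements.append({"x": float(x), "y": float(y), "class": lab})
    np.clip(img, -1.0, 1.0, out=img)
    return MixedTexture(StimulusImage(img), kind, n_a, n_b, elements)


# ---------------------------------------------------------------------------
# aperture masking
# ---------------------------------------------------------------------------

def gen_aperture_pattern(B: int, rng: np.random.Generator, n_total: int = 64,
                         area: float = 50_000.0, blur: float = 2.0,
                         exclusion: float = 10.0) -> DotPattern:
    """A 64-dot pattern with exactly ``B`` black dots (the rest white) and a
    fixed exclusion zone so that dots never touch."""
    if not 0 <= B <= n_total:
        raise StimulusError("B must be between 0 and the total dot count")
    pol = np.concatenate([-np.ones(B), np.ones(n_total - B)])
    rng.shuffle(pol)
    return build_dot_pattern(make_polygon(area, rng), n_total, blur, rng,
                             exclusion=exclusion, polarities=pol)


def apply_aperture(pattern: DotPattern, radius: float,
                   pad: float = DEFAULT_CANVAS_PAD,
                   contrast_scale: float = 1.0,
                   ) -> tuple[StimulusImage, int, int]:
    """Zero the rendered pattern outside a centred circular aperture.

    Returns (masked image, visible black count, visible white count); a dot is
    visible when its centre falls inside the disc.
    """
    if radius < 0:
        raise StimulusError("radius must be >= 0")
    img, pat = render_centred(pattern, contrast_scale, pad)
    h, w = img.values.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > radius ** 2
    masked = img.values.copy()
    masked[outside] = 0.0
    n_black = n_white = 0
    for d in pat.dots:
        if (d.x - cx) ** 2 + (d.y - cy) ** 2 <= radius ** 2:
            if d.amplitude < 0:
                n_black += 1
            else:
                n_white += 1
    return StimulusImage(masked, img.pixel_pitch), n_black, n_white
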